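"""Per-contrast differential expression and sex-attribution Venn logic.

The DE rule is raw p < 0.05 together with a linear fold change > 1.3,
both strict; q-values (Benjamini-Hochberg) are always reported alongside.
The default per-gene test is a two-sample Welch t on log2 expression; a
moderated variant shrinks gene-wise variances toward a common prior by
empirical Bayes (prior df and variance fit by method of moments on the
observed variance distribution), mirroring the moderated-t family of
statistics used by limma-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix


@dataclass(frozen=True)
class Contrast:
    """Two sample groups, selected by column=value predicates within an
    optional fixed stratum."""

    name: str
    group_a: tuple            # ((column, value-or-tuple), ...)
    group_b: tuple
    stratum: tuple = ()

    @staticmethod
    def _match(design: pd.DataFrame, preds) -> np.ndarray:
        m = np.ones(len(design), dtype=bool)
        for col, val in preds:
            if isinstance(val, (tuple, list, set, frozenset)):
                m &= design[col].isin(list(val)).to_numpy()
            else:
                m &= (design[col] == val).to_numpy()
        return m

    def select(self, design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        base = self._match(design, self.stratum)
        a = base & self._match(design, self.group_a)
        b = base & self._match(design, self.group_b)
        if (a & b).any():
            raise ValueError(f"contrast {self.name}: groups overlap")
        if not a.any() or not b.any():
            raise ValueError(f"contrast {self.name}: empty group")
        return a, b


def _moments_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior.

    Under s2 ~ s0^2 * F(df, d0): E[s2] = s0^2 d0/(d0-2) and
    Var(s2)/E[s2]^2 = 2 (df + d0 - 2) / (df (d0 - 4)).
    Returns (d0, s0^2); d0 = inf when the variance ratio implies complete
    shrinkage.
    """
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1))
    if m <= 0 or v <= 0:
        return np.inf, max(m, 1e-12)
    c = v / m ** 2
    if c * df <= 2.0:
        return np.inf, m
    d0 = (2.0 * df - 4.0 + 4.0 * c * df) / (c * df - 2.0)
    if d0 <= 4.0:
        d0 = 4.0 + 1e-6
    s02 = m * (d0 - 2.0) / d0
    return d0, s02


def de_test(expr: ExpressionMatrix, design: pd.DataFrame, contrast: Contrast,
            moderated: bool = False) -> pd.DataFrame:
    """Per-gene two-sample test for one contrast.

    Returns a DataFrame indexed by gene with columns log2fc (mean_a -
    mean_b), fold_change (2**|log2fc|), t, p, q (BH) and direction.
    """
    a, b = contrast.select(design)
    ids = dict(zip(design["sample_id"], range(len(design))))
    cols = [ids[s] for s in expr.sample_ids]
    a = a[cols]
    b = b[cols]
    na, nb = int(a.sum()), int(b.sum())
    if na < 2 or nb < 2:
        raise ValueError(f"contrast {contrast.name}: need >=2 samples per group")

    xa, xb = expr.values[:, a], expr.values[:, b]
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)

    if not moderated:
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    else:
        va = xa.var(axis=1, ddof=1)
        vb = xb.var(axis=1, ddof=1)
        df = na + nb - 2
        s2 = ((na - 1) * va + (nb - 1) * vb) / df
        d0, s02 = _moments_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = 1e6
        else:
            s2_post = (df * s2 + d0 * s02) / (df + d0)
            df_total = df + d0
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "log2fc": log2fc,
        "fold_change": 2.0 ** np.abs(log2fc),
        "t": t,
        "p": p,
        "q": q,
        "direction": np.sign(log2fc),
    }, index=pd.Index(expr.gene_ids, name="gene"))


def call_de(result: pd.DataFrame, p_max: float = 0.05,
            fc_min: float = 1.3) -> pd.Series:
    """Genes passing the DE rule (p < p_max and fold change > fc_min,
    strict), returned as a direction (+1/-1) Series indexed by gene."""
    if p_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be positive")
    mask = (result["p"] < p_max) & (result["fold_change"] > fc_min)
    return result.loc[mask, "direction"]


@dataclass
class VennPartition:
    """Three-set Venn decomposition of sex-DE attribution."""

    region_counts: dict = field(default_factory=dict)  # e.g. "sex&gonadal" -> n
    pct_gonadal: float = 0.0   # % of sex-DE genes attributed to gonadal sex
    pct_genetic: float = 0.0
    n_sex: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": k, "count": v}
                for k, v in sorted(self.region_counts.items())]
        return pd.DataFrame(rows)


def attribute_sex_differences(sex_de: pd.Series, gonadal_de: pd.Series,
                              genetic_de: pd.Series,
                              require_direction_match: bool = True
                              ) -> VennPartition:
    """Attribute overall sex-DE genes to gonadal and/or genetic sex.

    All inputs are direction Series (gene -> +1/-1) from contrasts oriented
    the same way (positive = higher on the female/XX side), so direction
    consistency is simple sign equality.
    """
    s, go, ge = set(sex_de.index), set(gonadal_de.index), set(genetic_de.index)
    counts = {
        "sex_only": len(s - go - ge),
        "gonadal_only": len(go - s - ge),
        "genetic_only": len(ge - s - go),
        "sex&gonadal": len((s & go) - ge),
        "sex&genetic": len((s & ge) - go),
        "gonadal&genetic": len((go & ge) - s),
        "sex&gonadal&genetic": len(s & go & ge),
    }

    def _consistent(other: pd.Series) -> int:
        shared = s & set(other.index)
        if not require_direction_match:
            return len(shared)
        return sum(1 for g in shared if sex_de[g] == other[g])

    n_sex = len(s)
    pct_go = 100.0 * _consistent(gonadal_de) / n_sex if n_sex else 0.0
    pct_ge = 100.0 * _consistent(genetic_de) / n_sex if n_sex else 0.0
    return VennPartition(counts, pct_go, pct_ge, n_sex)


def stress_overlap(de_a, de_b) -> dict:
    """Overlap statistics between two DE gene sets from the same universe."""
    a, b = set(de_a), set(de_b)
    inter = a & b
    union = a | b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "jaccard": len(inter) / len(union) if union else 0.0,
        "pct_of_a": 100.0 * len(inter) / len(a) if a else 0.0,
        "pct_of_b": 100.0 * len(inter) / len(b) if b else 0.0,
    }
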