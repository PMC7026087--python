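"""Count filtering and log2-CPM transformation.

The preprocessing contract is deliberately minimal: genes are ranked by
their total count across *all* samples and the lowest fraction removed,
then counts are transformed to log2 counts-per-million with a small
pseudo-count, optionally followed by mean-variance precision weights
(a single-curve approximation of the voom procedure).  Library sizes are
the column sums of the *filtered* matrix, i.e. filtering precedes
normalisation.

Also hosts the shared in-memory containers (:class:`CountMatrix`,
:class:`ExpressionMatrix`) and the qPCR arbitrary-signal helper.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("XX_F", "XY_F", "XX_M", "XY_M")

#: genotype -> (gonadal_sex, genetic_sex)
GENOTYPE_MAP = {
    "XX_F": ("F", "XX"),
    "XY_F": ("F", "XY"),
    "XX_M": ("M", "XX"),
    "XY_M": ("M", "XY"),
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    gene_ids: np.ndarray          # (G,) str
    counts: np.ndarray            # (G, S) int
    sample_ids: np.ndarray        # (S,) str

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids,
                            columns=self.sample_ids)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(self.gene_ids.copy(), self.counts[:, cols],
                           np.asarray(list(sample_ids), dtype=object))


@dataclass
class ExpressionMatrix:
    """Gene x sample log2-scale expression, optionally with precision weights."""

    gene_ids: np.ndarray
    values: np.ndarray            # (G, S) float, log2 scale
    sample_ids: np.ndarray
    weights: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights shape mismatch")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        w = self.weights[:, cols] if self.weights is not None else None
        return ExpressionMatrix(self.gene_ids.copy(), self.values[:, cols],
                                np.asarray(list(sample_ids), dtype=object),
                                weights=w, provenance=dict(self.provenance))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        w = self.weights[rows, :] if self.weights is not None else None
        return ExpressionMatrix(np.asarray(list(gene_ids), dtype=object),
                                self.values[rows, :], self.sample_ids.copy(),
                                weights=w, provenance=dict(self.provenance))


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-design table and derive gonadal/genetic sex columns.

    Required columns: sample_id, genotype, stress, region.  gonadal_sex and
    genetic_sex are derived from the four-core-genotypes label when absent
    and cross-checked when present.
    """
    required = {"sample_id", "genotype", "stress", "region"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    bad = set(design["genotype"]) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotypes: {sorted(bad)}")
    bad = set(design["stress"]) - {"ctrl", "stress"}
    if bad:
        raise ValueError(f"stress column must be ctrl/stress, got {sorted(bad)}")
    design = design.copy()
    gon = design["genotype"].map(lambda g: GENOTYPE_MAP[g][0])
    gen = design["genotype"].map(lambda g: GENOTYPE_MAP[g][1])
    for col, derived in (("gonadal_sex", gon), ("genetic_sex", gen)):
        if col in design.columns:
            if not (design[col] == derived).all():
                raise ValueError(f"{col} inconsistent with genotype")
        else:
            design[col] = derived
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    return design


# ---------------------------------------------------------------------------
# filtering and transformation
# ---------------------------------------------------------------------------

def filter_low_expression(counts: CountMatrix, fraction: float = 0.25) -> CountMatrix:
    """Drop the lowest-expressed ``floor(fraction * n_genes)`` genes.

    Genes are ranked by total count over all samples; ties at the cut
    boundary are broken by gene identifier so that the lexicographically
    later gene is kept.  Surviving genes keep their input order.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_remove = int(np.floor(fraction * counts.n_genes))
    if n_remove == 0:
        return CountMatrix(counts.gene_ids.copy(), counts.counts.copy(),
                           counts.sample_ids.copy())
    totals = counts.counts.sum(axis=1)
    # ascending by (total, gene_id): the first n_remove are dropped, so at a
    # tied boundary the lexicographically earlier gene goes first
    order = np.lexsort((counts.gene_ids.astype(str), totals))
    drop = np.zeros(counts.n_genes, dtype=bool)
    drop[order[:n_remove]] = True
    keep = ~drop
    return CountMatrix(counts.gene_ids[keep], counts.counts[keep, :],
                       counts.sample_ids.copy())


def log_cpm(counts: CountMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a pseudo-count.

    value = log2((count + prior) / (libsize + 2*prior) * 1e6), the voom
    convention; library size is the post-filter column sum.
    """
    lib = counts.library_sizes().astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"all-zero library for sample(s): {list(counts.sample_ids[zero])}")
    vals = np.log2((counts.counts + prior_count)
                   / (lib[None, :] + 2.0 * prior_count) * 1e6)
    return ExpressionMatrix(
        counts.gene_ids.copy(), vals, counts.sample_ids.copy(),
        provenance={"transform": "log_cpm", "prior_count": prior_count})


def voom_weights(expr: ExpressionMatrix, counts: CountMatrix,
                 groups: np.ndarray | None = None,
                 span: float = 0.5) -> ExpressionMatrix:
    """Attach inverse-variance precision weights from the mean-variance trend.

    Fits a lowess curve of sqrt(residual standard deviation) against the
    mean log2 count per gene and evaluates it at every observation's own
    log2 count; the weight is the predicted variance to the power -1
    (i.e. fitted curve value to the -4).  Outside the fitted range the
    curve is extended flat.  With fewer than 10 genes no trend is fit and
    all weights are 1.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    vals = expr.values
    if expr.n_genes < 10:
        w = np.ones_like(vals)
        out = dataclasses.replace(expr, weights=w)
        out.provenance["weights"] = "none (fewer than 10 genes)"
        return out

    if groups is None:
        resid = vals - vals.mean(axis=1, keepdims=True)
        dof = vals.shape[1] - 1
    else:
        groups = np.asarray(groups)
        resid = vals.copy()
        n_levels = 0
        for lev in pd.unique(groups):
            m = groups == lev
            resid[:, m] -= vals[:, m].mean(axis=1, keepdims=True)
            n_levels += 1
        dof = vals.shape[1] - n_levels
    sd = np.sqrt((resid ** 2).sum(axis=1) / max(dof, 1))

    log_counts = np.log2(counts.counts + 0.5)
    x = log_counts.mean(axis=1)
    y = np.sqrt(np.maximum(sd, 1e-12))
    fit = lowess(y, x, frac=span, return_sorted=True)
    fx, fy = fit[:, 0], np.maximum(fit[:, 1], 1e-6)
    # per-observation evaluation; np.interp clamps flat outside the range
    pred = np.interp(log_counts, fx, fy)
    w = pred ** -4.0
    out = dataclasses.replace(expr, weights=w)
    out.provenance["weights"] = f"lowess sqrt-sd trend, span={span}"
    return out


def qpcr_signal(dct):
    """Arbitrary qPCR signal from a delta-Ct value: ``2**(-dct) * 10000``.

    dct is the cycle-threshold difference of the target against the
    geometric mean of the housekeeping genes; one cycle halves the signal.
    """
    return 2.0 ** (-np.asarray(dct, dtype=float)) * 10_000.0
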