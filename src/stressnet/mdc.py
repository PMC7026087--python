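"""Module differential connectivity (MDC) between stress and control.

MDC for a module is the ratio of the summed strictly-lower-triangular
adjacency over the module's genes in the stressed-sample network to the
same sum in the non-stressed network: MDC > 1 is a gain of connectivity,
MDC < 1 a loss.  Significance comes from two permutation null schemes —
shuffled samples (same genes, condition labels permuted: non-random nodes,
random connections) and shuffled genes (random equal-size gene set, real
condition split: random nodes, non-random connections) — with an add-one
two-sided p on |log MDC|, BH-adjusted across modules within each scheme;
a gain/loss call requires q < threshold under BOTH schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coexpression import AdjacencyMatrix
from .preprocess import ExpressionMatrix

SCHEMES = ("shuffled_samples", "shuffled_genes", "shuffled_values")


def _adj_sub(values: np.ndarray, beta: float, kind: str) -> np.ndarray:
    """Adjacency on a small gene-subset expression block (genes x samples)."""
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(values)
    c = np.nan_to_num(c, nan=0.0)
    zero = sd == 0
    if zero.any():
        c[zero, :] = 0.0
        c[:, zero] = 0.0
    c = np.clip(c, -1.0, 1.0)
    a = np.abs(c) ** beta if kind == "unsigned" else ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def _lower_sum(a: np.ndarray) -> float:
    return float(a[np.tril_indices(a.shape[0], k=-1)].sum())


def module_connectivity(adj: AdjacencyMatrix | np.ndarray, genes=None) -> float:
    """Sum of strictly-lower-triangular adjacency over a module's genes."""
    if isinstance(adj, AdjacencyMatrix):
        if genes is None:
            raise ValueError("genes required with an AdjacencyMatrix")
        pos = {g: i for i, g in enumerate(adj.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise ValueError(f"genes not in adjacency: {missing[:5]}")
        idx = np.array([pos[g] for g in genes])
        if idx.size < 2:
            raise ValueError("module must have at least 2 genes")
        sub = adj.weights[np.ix_(idx, idx)]
    else:
        sub = np.asarray(adj)
        if sub.shape[0] < 2:
            raise ValueError("module must have at least 2 genes")
    return _lower_sum(sub)


def _module_values(expr: ExpressionMatrix, genes) -> np.ndarray:
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    idx = np.array([pos[g] for g in genes])
    return expr.values[idx, :]


def mdc_ratio(expr_stress: ExpressionMatrix, expr_ctrl: ExpressionMatrix,
              genes, beta: float = 6.0, kind: str = "unsigned") -> float:
    """connectivity(stress) / connectivity(ctrl) on the same gene set.

    Returns nan when the control connectivity is zero (undefined ratio).
    """
    if expr_stress.n_samples < 4 or expr_ctrl.n_samples < 4:
        raise ValueError("each condition needs at least 4 samples")
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("module must have at least 2 genes")
    cs = _lower_sum(_adj_sub(_module_values(expr_stress, genes), beta, kind))
    cc = _lower_sum(_adj_sub(_module_values(expr_ctrl, genes), beta, kind))
    if cc == 0:
        return float("nan")
    return cs / cc


def mdc_permutation_test(expr_stress: ExpressionMatrix,
                         expr_ctrl: ExpressionMatrix, genes,
                         scheme: str, n_perm: int = 1000,
                         seed: int = 0, beta: float = 6.0,
                         kind: str = "unsigned") -> dict:
    """Two-sided permutation p for one module under one null scheme.

    p = (1 + #{|log MDC_null| >= |log MDC_obs|}) / (n_perm + 1).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    if n_perm < 100:
        raise ValueError("mdc permutation test needs n_perm >= 100")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    obs = mdc_ratio(expr_stress, expr_ctrl, genes, beta, kind)
    if not np.isfinite(obs) or obs <= 0:
        return {"mdc": obs, "p": float("nan"), "scheme": scheme,
                "n_perm": n_perm}
    log_obs = abs(np.log(obs))

    xs = _module_values(expr_stress, genes)
    xc = _module_values(expr_ctrl, genes)
    ns = xs.shape[1]
    pooled = np.hstack([xs, xc])
    n_tot = pooled.shape[1]

    hits = 0
    for _ in range(n_perm):
        if scheme == "shuffled_samples":
            perm = rng.permutation(n_tot)
            a = _adj_sub(pooled[:, perm[:ns]], beta, kind)
            b = _adj_sub(pooled[:, perm[ns:]], beta, kind)
            num, den = _lower_sum(a), _lower_sum(b)
        elif scheme == "shuffled_genes":
            ridx = rng.choice(len(expr_stress.gene_ids), len(genes),
                              replace=False)
            a = _adj_sub(expr_stress.values[ridx, :], beta, kind)
            b = _adj_sub(expr_ctrl.values[ridx, :], beta, kind)
            num, den = _lower_sum(a), _lower_sum(b)
        else:  # shuffled_values: permute pooled lower-triangle adjacency values
            tri_s = _adj_sub(xs, beta, kind)[np.tril_indices(len(genes), -1)]
            tri_c = _adj_sub(xc, beta, kind)[np.tril_indices(len(genes), -1)]
            both = np.concatenate([tri_s, tri_c])
            both = both[rng.permutation(both.size)]
            num, den = float(both[:tri_s.size].sum()), float(both[tri_s.size:].sum())
        if den <= 0 or num <= 0:
            hits += 1       # count degenerate null draws as extreme
            continue
        if abs(np.log(num / den)) >= log_obs:
            hits += 1
    p = (1.0 + hits) / (n_perm + 1.0)
    return {"mdc": obs, "p": p, "scheme": scheme, "n_perm": n_perm}


def mdc_analysis(expr_stress: ExpressionMatrix, expr_ctrl: ExpressionMatrix,
                 modules: dict, n_perm: int = 1000, seed: int = 0,
                 beta: float = 6.0, kind: str = "unsigned",
                 q_max: float = 0.05,
                 schemes=("shuffled_samples", "shuffled_genes")
                 ) -> pd.DataFrame:
    """Run the MDC test for every module under both schemes and classify."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, genes in sorted(modules.items()):
        genes = list(genes)
        cs = _lower_sum(_adj_sub(_module_values(expr_stress, genes), beta, kind))
        cc = _lower_sum(_adj_sub(_module_values(expr_ctrl, genes), beta, kind))
        row = {"module": name, "n_genes": len(genes),
               "connectivity_stress": cs, "connectivity_ctrl": cc,
               "mdc": cs / cc if cc > 0 else float("nan")}
        for scheme in schemes:
            res = mdc_permutation_test(
                expr_stress, expr_ctrl, genes, scheme, n_perm,
                seed=int(rng.integers(2 ** 31)), beta=beta, kind=kind)
            row[f"p_{scheme}"] = res["p"]
        rows.append(row)
    table = pd.DataFrame(rows)
    return classify_modules(table, q_max=q_max, schemes=schemes)


def classify_modules(table: pd.DataFrame, q_max: float = 0.05,
                     schemes=("shuffled_samples", "shuffled_genes")
                     ) -> pd.DataFrame:
    """BH within each scheme across modules; call gained/lost/unchanged.

    gained: mdc > 1 and q < q_max under every scheme; lost: mdc < 1 under
    the same condition; otherwise unchanged.
    """
    table = table.copy()
    sig = np.ones(len(table), dtype=bool)
    for scheme in schemes:
        p = table[f"p_{scheme}"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        table[f"q_{scheme}"] = q
        sig &= np.nan_to_num(q, nan=1.0) < q_max
    mdc = table["mdc"].to_numpy(dtype=float)
    call = np.where(~sig | ~np.isfinite(mdc), "unchanged",
                    np.where(mdc > 1.0, "gained",
                             np.where(mdc < 1.0, "lost", "unchanged")))
    table["call"] = call
    return table


def call_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Pie-chart style summary of gained/lost/unchanged proportions."""
    counts = table["call"].value_counts()
    rows = []
    for call in ("gained", "lost", "unchanged"):
        n = int(counts.get(call, 0))
        rows.append({"call": call, "n_modules": n,
                     "fraction": n / len(table) if len(table) else 0.0})
    return pd.DataFrame(rows)
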