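"""Weighted co-expression networks, module detection and preservation.

Follows the WGCNA recipe: soft-thresholded correlation adjacency,
topological overlap, average-linkage clustering of 1 - TOM with a static
cut, and a two-statistic permutation preservation Z (density and
intramodular-connectivity correlation; Z_summary is their mean, with
Z_summary > 10 flagged as highly preserved).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .preprocess import ExpressionMatrix

#: module label palette, assigned by decreasing module size (WGCNA-style)
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)
UNASSIGNED = "grey"


@dataclass
class AdjacencyMatrix:
    """Symmetric gene x gene weights in [0, 1]; diagonal is 1 by definition
    but excluded from all connectivity sums."""

    gene_ids: np.ndarray
    weights: np.ndarray
    beta: float
    kind: str = "unsigned"
    estimator: str = "pearson"

    def connectivity(self) -> np.ndarray:
        """Whole-network connectivity k_i (row sums, diagonal excluded)."""
        return self.weights.sum(axis=1) - np.diag(self.weights)


def _correlation(values: np.ndarray, estimator: str) -> np.ndarray:
    if estimator == "spearman":
        values = rankdata(values, axis=1)
    sd = values.std(axis=1)
    zero = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(values)
    c = np.nan_to_num(c, nan=0.0)
    if zero.any():
        c[zero, :] = 0.0
        c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def adjacency(expr: ExpressionMatrix, beta: float = 6.0,
              kind: str = "unsigned",
              estimator: str = "pearson") -> AdjacencyMatrix:
    """Soft-thresholded correlation adjacency.

    unsigned: |r|^beta; signed: ((1 + r)/2)^beta.  Zero-variance genes get
    zero adjacency to every other gene.
    """
    if expr.n_samples < 4:
        raise ValueError("adjacency needs at least 4 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if kind not in ("unsigned", "signed"):
        raise ValueError(f"unknown network kind {kind!r}")
    c = _correlation(expr.values, estimator)
    if kind == "unsigned":
        a = np.abs(c) ** beta
    else:
        a = ((1.0 + c) / 2.0) ** beta
    zero = expr.values.std(axis=1) == 0
    if zero.any():
        a[zero, :] = 0.0
        a[:, zero] = 0.0
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(np.asarray(expr.gene_ids, dtype=object), a,
                           beta, kind, estimator)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; R^2 is the
    squared correlation of log10(freq) vs log10(mean k) over non-empty
    bins, with the sign flipped when the slope is positive.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = idx == b
        if m.sum() == 0:
            continue
        xs.append(np.log10(k[m].mean()))
        ys.append(np.log10(m.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    r2 = float(r ** 2)
    return (-r2 if slope > 0 else r2), float(slope)


def pick_soft_threshold(expr: ExpressionMatrix,
                        candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12,
                                         14, 16, 18, 20),
                        kind: str = "unsigned",
                        estimator: str = "pearson",
                        r2_target: float = 0.8) -> tuple[float, pd.DataFrame]:
    """Smallest beta reaching scale-free fit R^2 >= target, else the best.

    Returns the chosen beta and the full fit table (beta, signed R^2,
    slope, mean/median connectivity).
    """
    if not len(candidate_betas):
        raise ValueError("no candidate betas")
    c = _correlation(expr.values, estimator)
    base = np.abs(c) if kind == "unsigned" else (1.0 + c) / 2.0
    rows = []
    for beta in candidate_betas:
        a = base ** float(beta)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"beta": float(beta), "r2_signed": r2, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(np.median(k))})
    table = pd.DataFrame(rows)
    ok = table[table["r2_signed"] >= r2_target]
    if len(ok):
        chosen = float(ok.iloc[0]["beta"])
    else:
        chosen = float(table.loc[table["r2_signed"].idxmax(), "beta"])
    return chosen, table


def topological_overlap(adj: AdjacencyMatrix) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k the connectivity (diagonal excluded); TOM_ii = 1.
    """
    a = adj.weights.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum(k[:, None], k[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModuleSet:
    """Gene -> module-colour assignment plus the clustering dendrogram."""

    gene_ids: np.ndarray
    labels: np.ndarray
    dendrogram: np.ndarray | None = None
    min_size: int = 30
    cut_height: float = 0.95

    def assignment(self) -> pd.Series:
        return pd.Series(self.labels, index=self.gene_ids, name="module")

    def modules(self) -> dict:
        out: dict = {}
        for g, lab in zip(self.gene_ids, self.labels):
            if lab != UNASSIGNED:
                out.setdefault(lab, []).append(g)
        return out


def detect_modules(tom: np.ndarray, gene_ids, min_size: int = 30,
                   cut_height: float = 0.95) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters below ``min_size`` are set to grey (unassigned); surviving
    clusters get palette colours by decreasing size.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.full(len(gene_ids), UNASSIGNED, dtype=object)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size]
    # size-rank colour assignment; ties broken by cluster id for determinism
    ordered = sorted(keep.items(), key=lambda kv: (-kv[1], kv[0]))
    for rank, (cid, _) in enumerate(ordered):
        color = (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                 else f"module{rank + 1}")
        labels[raw == cid] = color
    return ModuleSet(gene_ids, labels, z, min_size, cut_height)


@dataclass
class PreservationScore:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_perm: int = 0

    def preserved_modules(self) -> list:
        return list(self.table.loc[self.table["preserved"], "module"])


def _density(weights: np.ndarray, idx: np.ndarray) -> float:
    sub = weights[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def _conn_corr(w_ref: np.ndarray, w_test: np.ndarray,
               idx: np.ndarray) -> float:
    a = w_ref[np.ix_(idx, idx)].sum(axis=1) - 1.0
    b = w_test[np.ix_(idx, idx)].sum(axis=1) - 1.0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def module_preservation(modules: ModuleSet, expr_ref: ExpressionMatrix,
                        expr_test: ExpressionMatrix, n_perm: int = 200,
                        seed: int = 0, beta: float = 6.0,
                        kind: str = "unsigned",
                        estimator: str = "pearson") -> PreservationScore:
    """Two-statistic permutation preservation Z against random gene sets.

    density = mean off-diagonal within-module adjacency in the test
    network; connectivity = correlation of intramodular connectivity
    between reference and test networks.  Nulls are the same statistics on
    ``n_perm`` uniformly random gene sets of matching size;
    Z = (obs - mean_null) / sd_null, Z_summary their mean, preserved when
    Z_summary > 10.
    """
    if n_perm < 50:
        raise ValueError("module preservation needs n_perm >= 50")
    adj_ref = adjacency(expr_ref, beta, kind, estimator)
    adj_test = adjacency(expr_test, beta, kind, estimator)
    gene_pos = {g: i for i, g in enumerate(expr_ref.gene_ids)}
    universe = len(expr_ref.gene_ids)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sorted(modules.modules().items()):
        m = len(members)
        if m > universe:
            raise ValueError(f"module {name} larger than the gene universe")
        idx = np.array([gene_pos[g] for g in members])
        obs_d = _density(adj_test.weights, idx)
        obs_c = _conn_corr(adj_ref.weights, adj_test.weights, idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for s in range(n_perm):
            ridx = rng.choice(universe, m, replace=False)
            null_d[s] = _density(adj_test.weights, ridx)
            null_c[s] = _conn_corr(adj_ref.weights, adj_test.weights, ridx)
        zs = []
        for obs, null in ((obs_d, null_d), (obs_c, null_c)):
            sd = null.std(ddof=1)
            if sd == 0:
                warnings.warn(f"degenerate permutation null for module {name}; "
                              "Z set to 0")
                zs.append(0.0)
            else:
                zs.append((obs - null.mean()) / sd)
        z_summary = float(np.mean(zs))
        rows.append({"module": name, "n_genes": m,
                     "Z_density": float(zs[0]), "Z_connectivity": float(zs[1]),
                     "Z_summary": z_summary, "preserved": z_summary > 10.0})
    return PreservationScore(pd.DataFrame(rows), n_perm)
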