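"""Condition-specific networks, N-hop neighborhood hubs, edge export.

A per-condition network is built either from Spearman correlations with a
permutation-calibrated edge threshold, or from mutual information with
equal-frequency binning, permutation significance and data-processing-
inequality (DPI) pruning of the weakest edge in each fully connected
triangle.  A gene is a hub when its N-hop neighborhood size (NHNN — the
number of distinct nodes within N hops) is significantly above the
network average; a stress-specific hub is a hub in the stressed network
only.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import ExpressionMatrix


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _spearman_abs(values: np.ndarray) -> np.ndarray:
    ranks = rankdata(values, axis=1)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(ranks)
    c = np.nan_to_num(c, nan=0.0)
    zero = sd == 0
    if zero.any():
        c[zero, :] = 0.0
        c[:, zero] = 0.0
    np.fill_diagonal(c, 0.0)
    return np.abs(np.clip(c, -1.0, 1.0))


def _null_threshold(values: np.ndarray, score_fn, fdr: float,
                    n_null: int, rng: np.random.Generator) -> float:
    """(1 - fdr) quantile of pairwise scores after independently permuting
    every gene's samples (destroys all dependence)."""
    pool = []
    for _ in range(n_null):
        perm = rng.permuted(values, axis=1)
        s = score_fn(perm)
        pool.append(s[np.triu_indices(s.shape[0], k=1)])
    return float(np.quantile(np.concatenate(pool), 1.0 - fdr))


def _mutual_information(values: np.ndarray) -> np.ndarray:
    """Pairwise MI (nats) by equal-frequency binning, bins = floor(sqrt(n))."""
    g, n = values.shape
    bins = max(2, int(np.floor(np.sqrt(n))))
    # equal-frequency bin index per gene
    ranks = rankdata(values, axis=1, method="ordinal") - 1
    binned = (ranks * bins // n).astype(np.int64)
    mi = np.zeros((g, g))
    marg = np.zeros((g, bins))
    for i in range(g):
        marg[i] = np.bincount(binned[i], minlength=bins) / n
    for i in range(g):
        for j in range(i + 1, g):
            joint = np.zeros((bins, bins))
            np.add.at(joint, (binned[i], binned[j]), 1.0)
            joint /= n
            outer = np.outer(marg[i], marg[j])
            nz = joint > 0
            mi[i, j] = mi[j, i] = float(
                (joint[nz] * np.log(joint[nz] / outer[nz])).sum())
    return mi


def _dpi_prune(g: nx.Graph, tolerance: float = 0.1) -> nx.Graph:
    """Remove, in every fully connected triangle, the weakest edge when it
    is weaker than both others by more than ``tolerance``."""
    doomed = set()
    for a, b, c in (tuple(t) for t in
                    itertools.combinations(g.nodes, 3)):
        if not (g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)):
            continue
        edges = [(g[a][b]["score"], (a, b)), (g[b][c]["score"], (b, c)),
                 (g[a][c]["score"], (a, c))]
        edges.sort()
        weakest, mid = edges[0], edges[1]
        if weakest[0] + tolerance < mid[0]:
            doomed.add(tuple(sorted(weakest[1])))
    out = g.copy()
    out.remove_edges_from(doomed)
    return out


def build_condition_network(expr: ExpressionMatrix,
                            method: str = "correlation",
                            edge_threshold: float | None = None,
                            fdr: float = 0.01, n_null: int = 20,
                            seed: int = 0,
                            dpi_tolerance: float = 0.1) -> nx.Graph:
    """Weighted undirected network over the genes of one condition."""
    if expr.n_samples < 4:
        raise ValueError("network construction needs at least 4 samples")
    rng = np.random.default_rng(seed)
    genes = list(expr.gene_ids)
    g = nx.Graph()
    g.add_nodes_from(genes)

    if method == "correlation":
        scores = _spearman_abs(expr.values)
        thr = (edge_threshold if edge_threshold is not None else
               _null_threshold(expr.values, _spearman_abs, fdr, n_null, rng))
    elif method == "mutual_information":
        scores = _mutual_information(expr.values)
        thr = (edge_threshold if edge_threshold is not None else
               _null_threshold(expr.values, _mutual_information, fdr,
                               n_null, rng))
    else:
        raise ValueError(f"unknown network method {method!r}")

    iu = np.triu_indices(len(genes), k=1)
    for i, j in zip(*iu):
        s = scores[i, j]
        if s > thr:
            g.add_edge(genes[i], genes[j], score=float(s))
    g.graph.update(method=method, threshold=float(thr), seed=seed)
    if method == "mutual_information":
        g = _dpi_prune(g, dpi_tolerance)
        g.graph["dpi_tolerance"] = dpi_tolerance
    return g


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def nhnn(network: nx.Graph, gene, n_hops: int) -> int:
    """Number of distinct nodes within ``n_hops`` of ``gene`` (self excluded)."""
    if gene not in network:
        raise ValueError(f"gene {gene!r} not in network")
    if n_hops < 1:
        raise ValueError("n_hops must be >= 1")
    reach = nx.single_source_shortest_path_length(network, gene,
                                                  cutoff=n_hops)
    return len(reach) - 1


def identify_hubs(network: nx.Graph, n_hops: int = 2, z_min: float = 2.0,
                  method: str = "zscore", n_perm: int = 100,
                  seed: int = 0) -> pd.DataFrame:
    """Flag genes whose NHNN is significantly above the network average.

    Default criterion: z-score of NHNN across nodes > z_min, with no hubs
    when the NHNN standard deviation is zero.  The permutation alternative
    compares each node's NHNN with the pooled NHNN distribution of
    degree-preserving rewired graphs.
    """
    if network.number_of_nodes() < 10:
        raise ValueError("hub identification needs at least 10 nodes")
    nodes = sorted(network.nodes)
    vals = np.array([nhnn(network, g, n_hops) for g in nodes], dtype=float)

    if method == "zscore":
        sd = vals.std()
        if sd == 0:
            z = np.zeros_like(vals)
            hub = np.zeros(len(nodes), dtype=bool)
        else:
            z = (vals - vals.mean()) / sd
            hub = z > z_min
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pool = []
        n_edges = network.number_of_edges()
        for _ in range(n_perm):
            h = network.copy()
            if n_edges > 2:
                nx.double_edge_swap(h, nswap=2 * n_edges,
                                    max_tries=20 * n_edges + 100,
                                    seed=int(rng.integers(2 ** 31)))
            pool.extend(nhnn(h, g, n_hops) for g in h.nodes)
        pool = np.asarray(pool, dtype=float)
        sd = pool.std()
        if sd == 0:
            z = np.zeros_like(vals)
            hub = np.zeros(len(nodes), dtype=bool)
        else:
            z = (vals - pool.mean()) / sd
            hub = z > z_min
    else:
        raise ValueError(f"unknown hub method {method!r}")

    return pd.DataFrame({"nhnn": vals.astype(int), "z": z, "hub": hub},
                        index=pd.Index(nodes, name="gene"))


def stress_specific_hubs(report_stress: pd.DataFrame,
                         report_ctrl: pd.DataFrame) -> set:
    """Hubs in the stressed network that are not hubs in the control one."""
    hubs_s = set(report_stress.index[report_stress["hub"]])
    hubs_c = set(report_ctrl.index[report_ctrl["hub"]])
    return hubs_s - hubs_c


def export_edges(network: nx.Graph, score_min: float = 0.95,
                 annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Edge list with score strictly above ``score_min``; gene_a is the
    lexicographically smaller endpoint and each pair appears once."""
    rows = []
    for u, v, data in network.edges(data=True):
        s = data.get("score", 1.0)
        if s > score_min:
            a, b = sorted((str(u), str(v)))
            rows.append({"gene_a": a, "gene_b": b, "score": float(s)})
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    edges = edges.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    if annotations is not None:
        for col in annotations.columns:
            amap = annotations[col]
            edges[f"{col}_a"] = edges["gene_a"].map(amap)
            edges[f"{col}_b"] = edges["gene_b"].map(amap)
    return edges
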