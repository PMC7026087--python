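"""Rank-rank hypergeometric overlap (RRHO) between two signed rankings.

Each differential-expression result is turned into a full ranking of the
gene universe by the signed score -log10(p) * sign(effect).  For every
pair of rank thresholds (i, j) on a regular stride, the overlap
k = |top_i(A) & top_j(B)| is scored against Hypergeometric(N, i, j):
over-enriched cells store -log10 P(X >= k) (positive) and under-enriched
cells store log10 P(X <= k) (negative).  Tail probabilities are exact
sums of the hypergeometric pmf accumulated in log space, so cells at
extreme thresholds do not underflow.

With this signed single-map convention, concordant rankings produce large
positive cells in the quadrants on the concordant diagonal (up-up /
down-down, split at each list's sign-change rank), while anti-concordant
rankings produce their strongest (negative, depletion) cells in the
discordant quadrants — which is what the four-corner coherence /
anti-coherence reading of an RRHO plot keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

P_FLOOR = 1e-300
_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# ranked lists
# ---------------------------------------------------------------------------

@dataclass
class RankedList:
    """Genes ordered by descending signed score; a permutation of the
    universe.  ``midpoint`` is the number of positive-score genes, i.e. the
    rank at which the score sign changes."""

    genes: np.ndarray
    scores: np.ndarray

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def midpoint(self) -> int:
        return int((self.scores > 0).sum())


def make_ranked_list(result: pd.DataFrame) -> RankedList:
    """Signed ranking from a DE result: score = -log10(p) * direction."""
    if "p" not in result or "direction" not in result:
        raise ValueError("DE result must have p and direction columns")
    p = np.maximum(result["p"].to_numpy(dtype=float), P_FLOOR)
    score = -np.log10(p) * result["direction"].to_numpy(dtype=float)
    genes = result.index.to_numpy(dtype=object)
    order = np.lexsort((genes.astype(str), -score))
    return RankedList(genes[order], score[order])


# ---------------------------------------------------------------------------
# exact hypergeometric tails, vectorised in log space
# ---------------------------------------------------------------------------

def _hyper_logpmf(k, N, K, n):
    """Natural-log pmf of Hypergeometric(N, K, n) at k (arrays ok)."""
    return (gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
            + gammaln(N - K + 1) - gammaln(n - k + 1)
            - gammaln(N - K - n + k + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)))


def _signed_log10_cells(N: int, I: np.ndarray, J: np.ndarray,
                        K: np.ndarray) -> np.ndarray:
    """Signed -log10 tail p for each (i, j, k) cell (flat arrays).

    Positive = -log10 P(X >= k) when k is at or above expectation i*j/N,
    negative = log10 P(X <= k) otherwise.  Each needed tail is summed
    directly in log space via a segmented logsumexp.
    """
    I = I.astype(np.int64)
    J = J.astype(np.int64)
    K = K.astype(np.int64)
    m = np.minimum(I, J)
    lo = np.maximum(0, I + J - N)
    over = K * N >= I * J
    start = np.where(over, K, lo)
    end = np.where(over, m, K)
    L = (end - start + 1).astype(np.int64)

    total = int(L.sum())
    offs = np.concatenate(([0], np.cumsum(L)[:-1]))
    kk = np.repeat(start, L) + (np.arange(total) - np.repeat(offs, L))
    lp = _hyper_logpmf(kk, N, np.repeat(I, L), np.repeat(J, L))

    mx = np.maximum.reduceat(lp, offs)
    seg = np.add.reduceat(np.exp(lp - np.repeat(mx, L)), offs)
    log_tail = mx + np.log(seg)                      # natural log of tail p
    log10p = np.minimum(log_tail / _LN10, 0.0)
    log10p = np.maximum(log10p, np.log10(P_FLOOR))
    return np.where(over, -log10p, log10p)


# ---------------------------------------------------------------------------
# the map
# ---------------------------------------------------------------------------

@dataclass
class RRHOMap:
    grid: np.ndarray              # signed -log10 tail p, thresholds_a x thresholds_b
    k: np.ndarray                 # overlap counts
    thresholds_a: np.ndarray
    thresholds_b: np.ndarray
    n_genes: int
    step: int
    mid_a: int
    mid_b: int
    corrected: np.ndarray | None = None
    correction: str | None = None

    def to_frame(self, which: str = "grid") -> pd.DataFrame:
        mat = self.grid if which == "grid" else self.corrected
        return pd.DataFrame(mat, index=self.thresholds_a,
                            columns=self.thresholds_b)


def _thresholds(n: int, step: int) -> np.ndarray:
    t = np.arange(step, n + step, step, dtype=np.int64)
    return np.minimum(t, n)[: int(np.ceil(n / step))]


def rrho_map(list_a: RankedList, list_b: RankedList,
             step: int | None = None) -> RRHOMap:
    """Signed RRHO grid over all rank-threshold pairs on a regular stride."""
    if set(list_a.genes) != set(list_b.genes):
        diff = set(list_a.genes) ^ set(list_b.genes)
        raise ValueError(f"gene universes differ ({len(diff)} genes in the "
                         "symmetric difference)")
    n = list_a.n
    if step is None:
        step = max(1, n // 100)
    if n < 2 * step:
        raise ValueError("universe too small for the chosen step")

    ta = _thresholds(n, step)
    tb = _thresholds(n, step)
    M = len(ta)

    rank_b = {g: r for r, g in enumerate(list_b.genes)}   # 0-based
    rb = np.array([rank_b[g] for g in list_a.genes], dtype=np.int64)
    bin_a = np.minimum(np.arange(n) // step, M - 1)
    bin_b = np.minimum(rb // step, M - 1)
    hist = np.zeros((M, M), dtype=np.int64)
    np.add.at(hist, (bin_a, bin_b), 1)
    k = hist.cumsum(axis=0).cumsum(axis=1)

    II, JJ = np.meshgrid(ta, tb, indexing="ij")
    cells = _signed_log10_cells(n, II.ravel(), JJ.ravel(), k.ravel())
    grid = cells.reshape(M, M)
    return RRHOMap(grid, k, ta, tb, n, step,
                   list_a.midpoint, list_b.midpoint)


def correct_map(rmap: RRHOMap, method: str = "BY",
                list_a: RankedList | None = None,
                list_b: RankedList | None = None,
                n_perm: int = 100, seed: int = 0) -> RRHOMap:
    """Multiple-testing correction over the grid.

    BY: Benjamini-Yekutieli step-up across all cells on the p scale.
    permutation: family-wise max-|cell| null from ``n_perm`` seeded
    permutations of list_b (requires both ranked lists).
    """
    p = 10.0 ** (-np.abs(rmap.grid))
    sign = np.sign(rmap.grid)
    sign[sign == 0] = 1.0
    if method == "BY":
        q = multipletests(p.ravel(), method="fdr_by")[1].reshape(p.shape)
        corrected = sign * -np.log10(np.maximum(q, P_FLOOR))
        label = "BY"
    elif method == "permutation":
        if n_perm < 20:
            raise ValueError("permutation correction needs n_perm >= 20")
        if list_a is None or list_b is None:
            raise ValueError("permutation correction needs both ranked lists")
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_perm)
        for s in range(n_perm):
            perm = rng.permutation(list_b.genes)
            lb = RankedList(perm, list_b.scores)
            null_max[s] = np.abs(rrho_map(list_a, lb, rmap.step).grid).max()
        stat = np.abs(rmap.grid)
        pcorr = (1.0 + (null_max[None, None, :] >= stat[:, :, None]).sum(-1)) \
            / (n_perm + 1.0)
        corrected = sign * -np.log10(pcorr)
        label = f"permutation (n={n_perm})"
    else:
        raise ValueError(f"unknown correction method {method!r}")
    out = RRHOMap(rmap.grid, rmap.k, rmap.thresholds_a, rmap.thresholds_b,
                  rmap.n_genes, rmap.step, rmap.mid_a, rmap.mid_b,
                  corrected=corrected, correction=label)
    return out


# ---------------------------------------------------------------------------
# quadrant classification
# ---------------------------------------------------------------------------

QUADRANTS = ("up_up", "up_down", "down_up", "down_down")


@dataclass
class QuadrantSummary:
    """Per-quadrant peak |cell| and the overall coherence call."""

    peaks: dict = field(default_factory=dict)  # quadrant -> (signed cell, i, j)
    call: str = "none"                         # coherent/anti-coherent/mixed/none
    signif: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"quadrant": qd, "peak_signed_log10p": v[0],
                 "rank_a": v[1], "rank_b": v[2]}
                for qd, v in self.peaks.items()]
        return pd.DataFrame(rows)


def classify_quadrants(rmap: RRHOMap, signif: float) -> QuadrantSummary:
    """Partition the grid at the sign-change ranks and call coherence.

    The call follows the location of the map's maximum-|cell| hotspot:
    coherent if every global-maximum cell lies in a concordant quadrant
    (up-up / down-down), anti-coherent if every one lies in a discordant
    quadrant, mixed if tied maxima span both, and none when the maximum
    does not reach ``signif``.  A strong coherent signal also produces
    weaker secondary enrichment near discordant-quadrant edges (the
    complement of a hotspot), so only the global peak is diagnostic.
    """
    side_a = np.where(rmap.thresholds_a <= rmap.mid_a, "up", "down")
    side_b = np.where(rmap.thresholds_b <= rmap.mid_b, "up", "down")
    summary = QuadrantSummary(signif=signif)
    for qa in ("up", "down"):
        for qb in ("up", "down"):
            rows = side_a == qa
            cols = side_b == qb
            if not rows.any() or not cols.any():
                continue
            sub = rmap.grid[np.ix_(rows, cols)]
            flat = np.argmax(np.abs(sub))
            ri, ci = np.unravel_index(flat, sub.shape)
            summary.peaks[f"{qa}_{qb}"] = (
                float(sub[ri, ci]),
                int(rmap.thresholds_a[rows][ri]),
                int(rmap.thresholds_b[cols][ci]))
    if not summary.peaks:
        return summary
    global_max = max(abs(v[0]) for v in summary.peaks.values())
    if global_max < signif:
        return summary
    at_max = {qd for qd, v in summary.peaks.items()
              if abs(v[0]) >= global_max * (1.0 - 1e-9)}
    conc = bool(at_max & {"up_up", "down_down"})
    disc = bool(at_max & {"up_down", "down_up"})
    summary.call = ("mixed" if conc and disc
                    else "coherent" if conc else "anti-coherent")
    return summary


def bonferroni_threshold(rmap: RRHOMap, alpha: float = 0.05) -> float:
    """-log10 of the Bonferroni-at-grid-size cell-level threshold."""
    m = rmap.grid.size
    return -np.log10(alpha / m)


def plot_map(rmap: RRHOMap, path: str, which: str = "grid") -> None:
    """Heat-map of the signed grid (optional; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = rmap.grid if which == "grid" else rmap.corrected
    lim = np.abs(mat).max() or 1.0
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mat, origin="upper", cmap="RdBu_r", vmin=-lim, vmax=lim,
                   aspect="auto")
    ax.set_xlabel("rank threshold, list B")
    ax.set_ylabel("rank threshold, list A")
    fig.colorbar(im, ax=ax, label="signed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
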