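"""Dynamical features computed identically in source and latent space.

Four summaries of a series' functional-connectivity dynamics:

* **FCD** — the window-by-window matrix of Pearson correlations between
  sliding-window FC matrices (upper triangles), capturing how the FC
  pattern recurs over time.
* **Edge metastability** — temporal standard deviation of the collective
  co-fluctuation amplitude (the RSS of the edge time series), i.e. the
  variability of global synchrony.
* **Signed modularity** — constant-Potts-model (CPM) quality of the best
  Louvain bipartition of the full signed FC matrix,
  Q(gamma) = sum_{i != j} (w_ij - gamma) delta(c_i, c_j) / sum |w_ij|.
* **Functional complexity** — normalized total deviation of the FC-value
  histogram from uniform over m bins spanning [-1, 1]:
  C = 1 - (1/c_m) * sum_mu |p_mu - 1/m|,  c_m = 2 (m - 1) / m,
  so a delta distribution gives 0 and a uniform histogram gives 1.

Every function accepts any series or square matrix regardless of its
space tag, so source and latent values always come from the same code
path (feature parity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edges import EdgeSeries, rss
from .signals import SubjectSeries

__all__ = [
    "FcdMatrix",
    "Partition",
    "fcd_matrix",
    "fcd_distribution",
    "edge_metastability",
    "cpm_quality",
    "louvain_cpm",
    "modularity_signed",
    "functional_complexity",
]


@dataclass
class FcdMatrix:
    data: np.ndarray                # (n_windows, n_windows)
    window_length: int
    window_step: int

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]


@dataclass
class Partition:
    labels: np.ndarray              # community label per node, contiguous from 0
    gamma: float
    q: float

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


def fcd_matrix(series: SubjectSeries, window_length: int = 30,
               window_step: int = 3) -> FcdMatrix:
    """Sliding-window FC similarity matrix."""
    if window_step < 1:
        raise ValueError("window_step must be >= 1")
    t = series.n_frames
    if window_length > t:
        raise ValueError("window longer than the series")
    starts = np.arange(0, t - window_length + 1, window_step)
    if starts.size < 2:
        raise ValueError("fewer than 2 windows; shorten the window or step")
    n = series.n_roi
    iu = np.triu_indices(n, k=1)
    tri = np.empty((starts.size, iu[0].size))
    for k, s in enumerate(starts):
        win = series.data[:, s:s + window_length]
        tri[k] = np.corrcoef(win)[iu]
    fcd = np.corrcoef(tri)
    np.fill_diagonal(fcd, 1.0)
    return FcdMatrix(fcd, window_length, window_step)


def fcd_distribution(fcd: FcdMatrix) -> np.ndarray:
    """Upper-triangle FCD values (the quantities pooled across groups)."""
    iu = np.triu_indices(fcd.n_windows, k=1)
    return fcd.data[iu]


def edge_metastability(edges: EdgeSeries, variant: str = "rss_sd") -> float:
    """Temporal SD of the edge time series.

    ``rss_sd`` (default): population SD of the RSS trace — the
    fluctuation of global synchrony.  ``per_edge``: mean over edges of
    each edge's own temporal SD.
    """
    if edges.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if variant == "rss_sd":
        return float(np.std(rss(edges)))
    if variant == "per_edge":
        return float(np.mean(np.std(edges.data, axis=1)))
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Signed constant-Potts modularity

def cpm_quality(w: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """CPM quality of a partition on a signed weight matrix.

    Q = sum_{i != j} (w_ij - gamma) * delta(c_i, c_j) / sum_{i != j} |w_ij|.
    """
    w = np.asarray(w, dtype=float)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    num = float(np.sum((w - gamma)[same]))
    offdiag = ~np.eye(w.shape[0], dtype=bool)
    denom = float(np.sum(np.abs(w[offdiag])))
    if denom == 0.0:
        raise ValueError("all off-diagonal weights are zero")
    return num / denom


def _local_moves(b: np.ndarray, labels: np.ndarray, rng) -> bool:
    """Greedy node moves maximizing sum_{i != j} b_ij delta(c_i, c_j)."""
    n = b.shape[0]
    improved_any = False
    while True:
        improved = False
        for i in rng.permutation(n):
            k = labels.max() + 1
            member = np.zeros((n, k))
            member[np.arange(n), labels] = 1.0
            # strength of node i to each community, excluding itself
            row = b[i].copy()
            row[i] = 0.0
            comm_strength = row @ member
            current = labels[i]
            gains = comm_strength - comm_strength[current]
            best = int(np.argmax(gains))
            if gains[best] > 1e-12 and best != current:
                labels[i] = best
                improved = improved_any = True
        if not improved:
            break
        # compact labels
        _, labels[:] = np.unique(labels, return_inverse=True)
    _, labels[:] = np.unique(labels, return_inverse=True)
    return improved_any


def louvain_cpm(w: np.ndarray, gamma: float, seed: int = 0) -> Partition:
    """One Louvain run (local moves + aggregation) on the shifted matrix.

    Works directly on b = w - gamma (off-diagonal); maximizing the CPM
    numerator is community detection on b.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    b = 0.5 * (w + w.T) - gamma
    np.fill_diagonal(b, 0.0)
    rng = np.random.default_rng(seed)

    node_labels = np.arange(n)                 # community of each original node
    cur = b.copy()
    labels = np.arange(cur.shape[0])
    while True:
        moved = _local_moves(cur, labels, rng)
        node_labels = labels[node_labels]
        k = labels.max() + 1
        if not moved or k == cur.shape[0]:
            break
        member = np.zeros((cur.shape[0], k))
        member[np.arange(cur.shape[0]), labels] = 1.0
        agg = member.T @ cur @ member          # diagonal: internal weight (fixed)
        cur = agg
        labels = np.arange(k)
    _, node_labels = np.unique(node_labels, return_inverse=True)
    q = cpm_quality(w, node_labels, gamma)
    return Partition(node_labels, gamma, q)


def _best_partition(w, gamma, n_restarts, rng) -> Partition:
    best = None
    for _ in range(n_restarts):
        part = louvain_cpm(w, gamma, seed=int(rng.integers(0, 2 ** 31 - 1)))
        if best is None or part.q > best.q + 1e-15:
            best = part
    return best


def bipartition_cpm(w: np.ndarray, gamma: float, n_restarts: int = 20,
                    seed: int = 0) -> Partition:
    """Best two-community partition at a fixed gamma (constrained moves).

    Greedy node swaps between exactly two communities from random
    initializations; used when the unconstrained resolution sweep skips
    the two-community regime entirely.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    b = 0.5 * (w + w.T) - gamma
    np.fill_diagonal(b, 0.0)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        improved = True
        while improved:
            improved = False
            member = np.zeros((n, 2))
            member[np.arange(n), labels] = 1.0
            strength = b @ member          # (n, 2)
            for i in rng.permutation(n):
                cur = labels[i]
                gain = strength[i, 1 - cur] - strength[i, cur]
                if gain > 1e-12 and np.sum(labels == cur) > 1:
                    labels[i] = 1 - cur
                    # moving node i shifts every node's strength to the
                    # two communities by +-b[:, i]
                    strength[:, cur] -= b[:, i]
                    strength[:, 1 - cur] += b[:, i]
                    member[i, cur] = 0.0
                    member[i, 1 - cur] = 1.0
                    improved = True
        q = cpm_quality(w, labels, gamma)
        if best is None or q > best.q:
            _, lab = np.unique(labels, return_inverse=True)
            best = Partition(lab, gamma, q)
    return best


def modularity_signed(fc: np.ndarray, gamma_grid=None, n_restarts: int = 20,
                      n_fine: int = 10, seed: int = 0,
                      on_missing: str = "error") -> Partition:
    """Best Louvain bipartition of a signed FC under the CPM null.

    A coarse sweep over ``gamma_grid`` locates the resolution interval in
    which the optimizer returns exactly two communities; a finer sweep of
    ``n_fine`` gammas inside that interval picks the bipartition with the
    highest quality Q.

    If no grid resolution yields exactly two communities,
    ``on_missing="error"`` raises (advising a wider grid) while
    ``on_missing="constrained"`` bisects toward the community-count jump
    and, failing that, optimizes a two-community partition directly at
    the jump resolution.
    """
    fc = np.asarray(fc, dtype=float)
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("FC matrix must be symmetric")
    if gamma_grid is None:
        gamma_grid = np.arange(0.0, 1.0001, 0.05)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if gamma_grid.size < 2 or np.any(np.diff(gamma_grid) <= 0):
        raise ValueError("gamma_grid must be increasing with >= 2 values")

    rng = np.random.default_rng(seed)
    coarse = {g: _best_partition(fc, g, n_restarts, rng) for g in gamma_grid}
    bip = [g for g in gamma_grid if coarse[g].n_communities == 2]
    if not bip:
        if on_missing == "error":
            raise ValueError(
                "no resolution in the grid yields a bipartition; widen gamma_grid")
        # bisect toward the jump from < 2 to > 2 communities
        below = [g for g in gamma_grid if coarse[g].n_communities < 2]
        above = [g for g in gamma_grid if coarse[g].n_communities > 2]
        lo = max(below) if below else gamma_grid[0]
        hi = min(above) if above else gamma_grid[-1]
        for _ in range(8):
            mid = 0.5 * (lo + hi)
            part = _best_partition(fc, mid, n_restarts, rng)
            if part.n_communities == 2:
                bip = [mid]
                coarse[mid] = part
                break
            if part.n_communities < 2:
                lo = mid
            else:
                hi = mid
        if not bip:
            return bipartition_cpm(fc, 0.5 * (lo + hi), n_restarts,
                                   seed=int(rng.integers(0, 2 ** 31 - 1)))
    lo, hi = min(bip), max(bip)
    fine = np.linspace(lo, hi, n_fine)
    best = None
    for g in list(bip) + list(fine):
        part = coarse.get(g) or _best_partition(fc, g, n_restarts, rng)
        if part.n_communities == 2 and (best is None or part.q > best.q):
            best = part
    return best


def functional_complexity(fc: np.ndarray, m: int = 20) -> float:
    """Deviation of the FC-value distribution from uniform, in [0, 1]."""
    if m < 2:
        raise ValueError("m must be >= 2")
    fc = np.asarray(fc, dtype=float)
    iu = np.triu_indices(fc.shape[0], k=1)
    values = np.clip(fc[iu], -1.0, 1.0)
    counts, _ = np.histogram(values, bins=m, range=(-1.0, 1.0))
    p = counts / counts.sum()
    c_m = 2.0 * (m - 1) / m
    c = 1.0 - np.sum(np.abs(p - 1.0 / m)) / c_m
    return float(np.clip(c, 0.0, 1.0))
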