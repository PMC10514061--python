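"""Edge-centric decomposition of functional connectivity.

The edge time series of ROI pair (i, j) is the frame-wise product of the
two z-scored signals, e_ij(t) = z_i(t) * z_j(t).  Because z-scoring uses
the population SD, the time average of e_ij is *exactly* the Pearson
correlation r_ij — the decomposition is mathematically exact, not an
approximation.  The root-sum-square (RSS) of all edges at one frame
measures the instantaneous collective co-fluctuation amplitude; its
transient peaks, validated against a circular-shift null, are the
"events" whose frames alone suffice to reconstruct most of the FC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signals import SubjectSeries, zscore_rows

__all__ = [
    "EdgeSeries",
    "PeakSet",
    "edge_time_series",
    "rss",
    "circshift_null",
    "detect_peaks",
    "top_frac_peaks",
    "fc_from_frames",
    "full_fc",
    "peak_agreement",
    "agreement_curve",
]


@dataclass
class EdgeSeries:
    """Edge co-fluctuation matrix: one row per ROI pair (i < j)."""

    data: np.ndarray                # (n_edges, n_frames)
    edge_index: np.ndarray          # (n_edges, 2), pairs with i < j
    space: str = "source"

    @property
    def n_edges(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class PeakSet:
    """Event frames of one RSS trace."""

    peaks: np.ndarray               # flagged frame indices (sorted)
    excluded: np.ndarray            # frames flagged but z-excluded
    rss_trace: np.ndarray
    threshold: float
    p: float
    z_max: float

    @property
    def n_frames(self) -> int:
        return self.rss_trace.size


def edge_time_series(series: SubjectSeries) -> EdgeSeries:
    """Unwrap the Pearson correlation into per-frame edge co-fluctuations."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames")
    z = zscore_rows(series).data
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    data = z[iu] * z[ju]
    return EdgeSeries(data, np.column_stack([iu, ju]), space=series.space)


def rss(edges: EdgeSeries) -> np.ndarray:
    """Root sum square of co-fluctuations at every frame."""
    return np.sqrt(np.sum(edges.data ** 2, axis=0))


def _rss_from_z(z: np.ndarray) -> np.ndarray:
    # RSS over edges without materializing the edge matrix:
    # sum_{i<j} (z_i z_j)^2 = ((sum_i z_i^2)^2 - sum_i z_i^4) / 2
    s2 = np.sum(z ** 2, axis=0)
    s4 = np.sum(z ** 4, axis=0)
    return np.sqrt(np.maximum(0.5 * (s2 ** 2 - s4), 0.0))


def circshift_null(series: SubjectSeries, n_iter: int = 1000,
                   seed: int = 0) -> np.ndarray:
    """Circular-shift surrogate RSS sample, shape (n_iter, n_frames).

    Each iteration independently rotates every ROI row by a uniform random
    offset before recomputing the RSS: autocorrelation per row is
    approximately preserved while cross-correlations are randomized.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    z = zscore_rows(series).data
    n, t = z.shape
    rng = np.random.default_rng(seed)
    col = np.arange(t)
    out = np.empty((n_iter, t))
    for it in range(n_iter):
        shifts = rng.integers(0, t, size=n)
        rolled = z[np.arange(n)[:, None], (col[None, :] - shifts[:, None]) % t]
        out[it] = _rss_from_z(rolled)
    return out


def detect_peaks(rss_trace: np.ndarray, null_sample: np.ndarray,
                 p: float = 0.001, z_max: float = 4.5) -> PeakSet:
    """Flag event frames whose RSS exceeds the pooled null quantile.

    The threshold is the (1 - p) quantile of all null RSS values pooled
    over iterations and frames (circular shifts make frames exchangeable).
    Flagged frames whose RSS z-score relative to the empirical trace's own
    mean/SD exceeds +-z_max are moved to the excluded set.
    """
    rss_trace = np.asarray(rss_trace, dtype=float)
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    if not 0.0 < p < 0.5:
        raise ValueError("p must lie in (0, 0.5)")
    threshold = float(np.quantile(null_sample.ravel(), 1.0 - p))
    flagged = np.where(rss_trace > threshold)[0]
    mu, sd = rss_trace.mean(), rss_trace.std()
    if sd > 0:
        zscores = (rss_trace[flagged] - mu) / sd
        extreme = np.abs(zscores) > z_max
    else:
        extreme = np.zeros(flagged.size, bool)
    return PeakSet(peaks=flagged[~extreme], excluded=flagged[extreme],
                   rss_trace=rss_trace, threshold=threshold, p=p, z_max=z_max)


def top_frac_peaks(rss_trace: np.ndarray, frac: float = 0.10) -> PeakSet:
    """Alternative event selection: the top ``frac`` highest-RSS frames."""
    rss_trace = np.asarray(rss_trace, dtype=float)
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    k = max(1, int(round(frac * rss_trace.size)))
    order = np.argsort(rss_trace)[::-1][:k]
    threshold = float(rss_trace[order[-1]])
    return PeakSet(peaks=np.sort(order), excluded=np.array([], dtype=int),
                   rss_trace=rss_trace, threshold=threshold, p=frac, z_max=np.inf)


def fc_from_frames(series: SubjectSeries, frames) -> np.ndarray:
    """Pearson FC computed from a subset of frames only."""
    frames = np.asarray(frames, dtype=int)
    if frames.size < 2:
        raise ValueError("need at least 2 frames to form an FC matrix")
    sub = series.data[:, frames]
    sd = sub.std(axis=1)
    if np.any(sd == 0.0):
        raise ValueError(
            f"degenerate frame selection: zero-variance ROI rows "
            f"{np.where(sd == 0.0)[0].tolist()}")
    fc = np.corrcoef(sub)
    np.fill_diagonal(fc, 1.0)
    return fc


def full_fc(series: SubjectSeries) -> np.ndarray:
    """Full-length Pearson correlation matrix of a series."""
    return fc_from_frames(series, np.arange(series.n_frames))


def peak_agreement(peaks_a: PeakSet, peaks_b: PeakSet) -> float:
    """Fraction of event frames coinciding in two spaces.

    hits = |A intersect B|, miss = frames flagged in exactly one set;
    agreement = hits / (hits + miss), defined as 1 when both are empty.
    """
    if peaks_a.n_frames != peaks_b.n_frames:
        raise ValueError("PeakSets come from traces of unequal length")
    a, b = set(peaks_a.peaks.tolist()), set(peaks_b.peaks.tolist())
    hits = len(a & b)
    miss = len(a ^ b)
    if hits + miss == 0:
        return 1.0
    return hits / (hits + miss)


def agreement_curve(cohort, models: dict, timepoint: str = "2wk",
                    n_iter: int = 200, p: float = 0.001, z_max: float = 4.5,
                    seed: int = 0):
    """Source-vs-latent peak agreement as a function of latent dimension.

    For every subject and every latent model (keyed by dimension d), events
    are detected on the source RSS and on the latent RSS through identical
    code, and the per-subject agreement is recorded.  Consecutive
    dimensions are compared with paired t-tests.

    Returns a dict with ``dims``, ``mean_agreement``, ``per_subject``
    (dim -> array) and ``paired_tests`` (list of (d_low, d_high, t, p)).
    """
    from .latent import encode

    dims = sorted(models)
    per_subject = {d: [] for d in dims}
    rng = np.random.default_rng(seed)
    for rec in cohort.records:
        tp = "control" if rec.group == "control" else timepoint
        series = cohort.get_series(rec.subject_id, tp)
        z = zscore_rows(series)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        null_src = circshift_null(z, n_iter=n_iter, seed=sub_seed)
        src_peaks = detect_peaks(rss(edge_time_series(z)), null_src, p, z_max)
        for d in dims:
            lat = encode(models[d], z)
            null_lat = circshift_null(lat, n_iter=n_iter, seed=sub_seed)
            lat_peaks = detect_peaks(rss(edge_time_series(lat)), null_lat, p, z_max)
            per_subject[d].append(peak_agreement(src_peaks, lat_peaks))
    per_subject = {d: np.array(v) for d, v in per_subject.items()}
    means = [float(per_subject[d].mean()) for d in dims]
    tests = []
    for lo, hi in zip(dims[:-1], dims[1:]):
        t, pv = stats.ttest_rel(per_subject[hi], per_subject[lo])
        tests.append((lo, hi, float(t), float(pv)))
    return {"dims": dims, "mean_agreement": means,
            "per_subject": per_subject, "paired_tests": tests}
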