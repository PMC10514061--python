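"""Series containers, delimited-text I/O and temporal preprocessing.

A :class:`SubjectSeries` is the package's basic in-memory object: one
ROI-by-frame real matrix for one subject at one timepoint, tagged with the
sampling interval (TR, seconds) and the space it lives in (``source`` for
regional BOLD-like signals, ``latent`` for autoencoder bottleneck series).

All analyses downstream assume *population*-SD z-scoring (divide by n, not
n - 1).  This is load-bearing: it is what makes the time average of an edge
time series equal the Pearson correlation coefficient exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "SubjectSeries",
    "FormatError",
    "read_series",
    "write_series",
    "bandpass",
    "zscore_rows",
    "concatenate_for_training",
]

VALID_SPACES = ("source", "latent")


class FormatError(ValueError):
    """Raised when a series file is ragged or contains non-numeric cells."""


@dataclass
class SubjectSeries:
    """One real-valued multivariate time series.

    Parameters
    ----------
    data : ndarray, shape (n_roi, n_frames)
        Signal matrix, ROI-major (rows are regions, columns are frames).
    subject_id : str
        Subject identifier.
    timepoint : str
        Acquisition label, e.g. ``"2wk"``, ``"3mo"``, ``"1yr"`` or
        ``"control"``.
    tr : float
        Sampling interval in seconds.
    space : str
        ``"source"`` or ``"latent"``.
    """

    data: np.ndarray
    subject_id: str = ""
    timepoint: str = "control"
    tr: float = 2.0
    space: str = "source"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("series data must be 2-D (n_roi x n_frames)")
        if self.data.shape[1] < 1:
            raise ValueError("series must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite values")
        if self.space not in VALID_SPACES:
            raise ValueError(f"unknown space {self.space!r}")

    @property
    def n_roi(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, **tags) -> "SubjectSeries":
        """Return a copy carrying ``data`` and updated tags."""
        out = replace(self, **tags)
        out.data = np.asarray(data, dtype=float)
        return out


def write_series(series: SubjectSeries, path) -> None:
    """Write a series as TSV (rows = ROIs) plus a JSON tag sidecar."""
    path = Path(path)
    np.savetxt(path, series.data, delimiter="\t", fmt="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "subject_id": series.subject_id,
        "timepoint": series.timepoint,
        "tr": series.tr,
        "space": series.space,
    }))


def read_series(path) -> SubjectSeries:
    """Read a TSV matrix written by :func:`write_series`.

    Raises
    ------
    FormatError
        If rows have unequal length (the offending row is named) or a cell
        does not parse as a number (row/column named).
    """
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for r, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise FormatError(
                    f"{path}: ragged row {r} (expected {width} cells, got {len(cells)})"
                )
            parsed = []
            for c, cell in enumerate(cells):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: empty series file")
    data = np.array(rows, dtype=float)

    tags = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        tags = json.loads(sidecar.read_text())
    return SubjectSeries(data, **tags)


def bandpass(series: SubjectSeries, low_hz: float = 0.009,
             high_hz: float = 0.08, order: int = 2) -> SubjectSeries:
    """Zero-phase Butterworth band-pass, applied per ROI row.

    The default band (0.009-0.08 Hz) is the standard resting-state fMRI
    band.  The filter is applied forward-backward (``filtfilt``), so the
    effective order is doubled and the phase response is flat.
    """
    nyquist = 0.5 / series.tr
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("require 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    b, a = butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / series.tr)
    filtered = filtfilt(b, a, series.data, axis=1)
    return series.with_data(filtered)


def zscore_rows(series: SubjectSeries) -> SubjectSeries:
    """Z-score every row to mean 0 and *population* SD 1.

    Raises
    ------
    ValueError
        If a row has zero variance; the message names the ROI index.
    """
    data = series.data
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)  # ddof=0: population SD
    # relative tolerance: a constant row of large values has sd ~ eps * |mu|
    flat = np.where(sd[:, 0] <= 1e-12 * (np.abs(mu[:, 0]) + 1.0))[0]
    if flat.size:
        raise ValueError(f"zero-variance ROI rows: {flat.tolist()}")
    return series.with_data((data - mu) / sd)


def concatenate_for_training(cohort, timepoint: str = "2wk"):
    """Column-concatenate z-scored series of a cohort for embedding training.

    Controls contribute their ``control`` series; patients contribute the
    series at ``timepoint``.  Columns are ordered subject-by-subject in
    cohort record order.

    Returns
    -------
    frames : ndarray, shape (n_roi, n_frames_total)
    index_map : dict
        ``subject_id -> (start, stop)`` column slice, inverting the
        concatenation exactly.
    """
    blocks = []
    index_map = {}
    start = 0
    n_roi = None
    for rec in cohort.records:
        tp = "control" if rec.group == "control" else timepoint
        series = cohort.series[(rec.subject_id, tp)]
        if n_roi is None:
            n_roi = series.n_roi
        elif series.n_roi != n_roi:
            raise ValueError(
                f"mixed n_roi: subject {rec.subject_id} has {series.n_roi}, expected {n_roi}"
            )
        z = zscore_rows(series).data
        blocks.append(z)
        index_map[rec.subject_id] = (start, start + z.shape[1])
        start += z.shape[1]
    if not blocks:
        raise ValueError("cohort has no subjects to concatenate")
    return np.concatenate(blocks, axis=1), index_map
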