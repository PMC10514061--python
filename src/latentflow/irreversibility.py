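"""Temporal irreversibility of multivariate signals (arrow-of-time index).

For a pair of signals x, y the forward time-shifted correlation is

    C_forward(dt) = corr( x(t), y(t + dt) ),

and the reversed-evolution counterpart is the same quantity computed on
both time-reversed signals,

    C_reversal(dt) = corr( x_r(t), y_r(t + dt) ),   x_r(t) = x(T - 1 - t).

The pairwise irreversibility is I_xy = |C_forward - C_reversal| at
dt = 1 frame.  A reversible (detailed-balance) process yields I near 0;
asymmetric directed coupling drives I up, so the mean of the upper
triangle of I indexes distance from thermodynamic equilibrium.

Algebraically, C_reversal(dt) equals C_forward(dt) with the roles of x
and y swapped, hence I is symmetric with an exactly zero diagonal; the
matrix implementation exploits this and is verified against the literal
pairwise loop in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import SubjectSeries

__all__ = [
    "IrreversibilityMatrix",
    "shifted_correlation",
    "reverse_series",
    "irreversibility_matrix",
    "pairwise_irreversibility_matrix",
    "mean_irreversibility",
]


@dataclass
class IrreversibilityMatrix:
    data: np.ndarray                # (n, n), symmetric, zero diagonal
    dt: int
    space: str = "source"

    @property
    def n(self) -> int:
        return self.data.shape[0]


def shifted_correlation(x: np.ndarray, y: np.ndarray, dt: int = 1) -> float:
    """Pearson correlation of the lagged pairs (x(t), y(t + dt))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if dt < 1:
        raise ValueError("dt must be >= 1")
    if x.size <= dt or y.size <= dt:
        raise ValueError("series shorter than the shift")
    a, b = x[:-dt], y[dt:]
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("undefined correlation: constant subseries")
    return float(np.corrcoef(a, b)[0, 1])


def reverse_series(x: np.ndarray) -> np.ndarray:
    """Flip the time ordering: x_r(t) = x(T - 1 - t)."""
    return np.asarray(x)[::-1].copy()


def _lagged_corr_matrix(data: np.ndarray, dt: int) -> np.ndarray:
    """C[i, j] = corr( x_i(t), x_j(t + dt) ) for all pairs at once."""
    past = data[:, :-dt]
    future = data[:, dt:]
    t = past.shape[1]
    pz = past - past.mean(axis=1, keepdims=True)
    fz = future - future.mean(axis=1, keepdims=True)
    psd = pz.std(axis=1)
    fsd = fz.std(axis=1)
    bad = np.where((psd == 0.0) | (fsd == 0.0))[0]
    if bad.size:
        raise ValueError(f"undefined lagged correlation: constant rows {bad.tolist()}")
    return (pz / psd[:, None]) @ (fz / fsd[:, None]).T / t


def irreversibility_matrix(series: SubjectSeries, dt: int = 1) -> IrreversibilityMatrix:
    """Pairwise irreversibility I = |C_forward - C_reversal| at shift dt.

    Since reversing both series maps the lagged pair set onto itself with
    roles swapped, C_reversal = C_forward^T and I = |C_f - C_f^T|:
    symmetric with zero diagonal by construction.
    """
    if series.n_frames <= dt:
        raise ValueError("series shorter than the shift")
    cf = _lagged_corr_matrix(series.data, dt)
    i = np.abs(cf - cf.T)
    np.fill_diagonal(i, 0.0)
    return IrreversibilityMatrix(i, dt, space=series.space)


def pairwise_irreversibility_matrix(series: SubjectSeries, dt: int = 1) -> IrreversibilityMatrix:
    """Literal per-pair implementation (reference oracle for the matrix form)."""
    data = series.data
    n = data.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cf = shifted_correlation(data[i], data[j], dt)
            cr = shifted_correlation(reverse_series(data[i]),
                                     reverse_series(data[j]), dt)
            out[i, j] = abs(cf - cr)
    return IrreversibilityMatrix(out, dt, space=series.space)


def mean_irreversibility(matrix: IrreversibilityMatrix) -> float:
    """Mean of the strict upper triangle (the scalar non-equilibrium index)."""
    iu = np.triu_indices(matrix.n, k=1)
    return float(matrix.data[iu].mean())
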