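"""Banded dynamic time warping (DTW) between variable-length sequences.

The measure returned by :func:`dtw_distance` is the minimum over monotone
alignment paths of the sum of squared gaps, i.e. the squared Euclidean
distance between the aligned series.  No path-length normalization is
applied.

Pathological time dilations are prevented with a Sakoe-Chiba band.  For
sequences of unequal length the band is centred on the slope-corrected
diagonal ``j = i * (n-1)/(m-1)``; its half-width is the sample radius,
widened to ``(slope+1)/2`` when necessary so consecutive row windows always
overlap and the corners stay connected.  The sample radius is
``max(1, round_half_up(radius_s * fs))`` — at 250 Hz a 0.01 s radius gives
3 samples.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import round_half_up
from .errors import ParameterError

__all__ = ["dtw_distance", "dtw_path", "radius_to_samples"]


def radius_to_samples(radius_s: float, fs: float) -> int:
    """Band radius in samples: round-half-up with a floor of one sample."""
    if radius_s < 0:
        raise ParameterError("radius must be >= 0")
    if fs <= 0:
        raise ParameterError("fs must be positive")
    return max(1, round_half_up(radius_s * fs))


@njit(cache=True)
def _band_limits(m, n, h):
    """Per-row admissible column window [lo[i], hi[i]] of the banded DP."""
    lo = np.zeros(m, np.int64)
    hi = np.full(m, n - 1, np.int64)
    if m > 1:
        slope = (n - 1.0) / (m - 1.0)
        width = h if h > (slope + 1.0) / 2.0 else (slope + 1.0) / 2.0
        for i in range(m):
            c = i * slope
            l = int(np.ceil(c - width))
            u = int(np.floor(c + width))
            lo[i] = l if l > 0 else 0
            hi[i] = u if u < n - 1 else n - 1
    return lo, hi


@njit(cache=True)
def _cost_matrix(x, y, h):
    m = x.shape[0]
    n = y.shape[0]
    lo, hi = _band_limits(m, n, h)
    D = np.full((m, n), np.inf)
    for i in range(m):
        for j in range(lo[i], hi[i] + 1):
            gap = x[i] - y[j]
            d = gap * gap
            if i == 0 and j == 0:
                D[0, 0] = d
            else:
                best = np.inf
                if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                if i > 0 and D[i - 1, j] < best:
                    best = D[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = d + best
    return D


@njit(cache=True)
def _backtrack(D):
    """Optimal path through a filled cost matrix, corner to corner.

    Ties between predecessors break deterministically: diagonal, then
    (i-1, j), then (i, j-1).
    """
    m, n = D.shape
    buf_i = np.empty(m + n, np.int64)
    buf_j = np.empty(m + n, np.int64)
    i, j = m - 1, n - 1
    k = 0
    buf_i[k] = i
    buf_j[k] = j
    while i > 0 or j > 0:
        best = np.inf
        bi, bj = i, j
        if i > 0 and j > 0 and D[i - 1, j - 1] < best:
            best = D[i - 1, j - 1]
            bi, bj = i - 1, j - 1
        if i > 0 and D[i - 1, j] < best:
            best = D[i - 1, j]
            bi, bj = i - 1, j
        if j > 0 and D[i, j - 1] < best:
            best = D[i, j - 1]
            bi, bj = i, j - 1
        i, j = bi, bj
        k += 1
        buf_i[k] = i
        buf_j[k] = j
    return buf_i[: k + 1][::-1].copy(), buf_j[: k + 1][::-1].copy()


def _prepare(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.size == 0 or y.size == 0:
        raise ParameterError("sequences must be non-empty 1-D arrays")
    return x, y


def _halfwidth(x, y, radius_s, fs) -> int:
    if radius_s is None:
        return int(max(x.size, y.size))  # unconstrained
    return radius_to_samples(radius_s, fs)


def dtw_distance(x, y, radius_s: float | None = None, fs: float = 1.0) -> float:
    """Banded DTW measure between ``x`` and ``y``.

    ``radius_s=None`` disables the band entirely (classic unconstrained DTW).
    """
    x, y = _prepare(x, y)
    D = _cost_matrix(x, y, _halfwidth(x, y, radius_s, fs))
    d = float(D[-1, -1])
    assert np.isfinite(d), "band failed to connect corners"
    return d


def dtw_path(x, y, radius_s: float | None = None, fs: float = 1.0):
    """Distance and optimal alignment path.

    Returns ``(distance, (idx_x, idx_y))`` where the two index arrays trace
    the path from (0, 0) to (m-1, n-1) with steps in {(1,0), (0,1), (1,1)}.
    """
    x, y = _prepare(x, y)
    D = _cost_matrix(x, y, _halfwidth(x, y, radius_s, fs))
    d = float(D[-1, -1])
    assert np.isfinite(d), "band failed to connect corners"
    pi, pj = _backtrack(D)
    return d, (pi, pj)


def nearest_reference(x, references, radius_s: float | None, fs: float):
    """Index of and distances to the closest reference (1-NN under DTW)."""
    dists = np.array([dtw_distance(x, r, radius_s, fs) for r in references])
    return int(np.argmin(dists)), dists
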