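"""DTW barycenter averaging by batch stochastic subgradient descent (BS-DBA).

The barycenter of a set X of sequences is the fixed-length sequence y
minimizing the sum of DTW measures sum_{x in X} DTW(y, x), where DTW is the
squared-cost measure of :mod:`plethysym.dtw`.  The exact problem is NP-hard;
BS-DBA performs mini-batch subgradient descent: for each batch, every
barycenter sample y_k is pulled toward the data samples its optimal warping
path aligns it to,

    g_k = sum_{x in batch} sum_{(i,j) in path(y,x), i=k} 2 (y_k - x_j),

with a decreasing step eta_t = eta0 / (1 + t).  The iterate with the best
end-of-epoch objective is returned, so the recorded objective trace is
monotone non-increasing from the initialization (the medoid of X, linearly
resampled to the target length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dtw import dtw_distance, dtw_path
from .errors import ParameterError

logger = logging.getLogger("plethysym.barycenter")

__all__ = ["Barycenter", "dba_objective", "medoid_index", "resample_linear", "bs_dba"]


@dataclass
class Barycenter:
    """A DTW average sequence and the provenance of its optimization."""

    samples: np.ndarray
    objective_trace: np.ndarray  # best-so-far objective: [init, epoch 1, ...]
    seed: int = 0
    epochs: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.objective_trace = np.asarray(self.objective_trace, dtype=np.float64)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _as_arrays(X) -> list[np.ndarray]:
    out = [np.ascontiguousarray(getattr(x, "samples", x), dtype=np.float64) for x in X]
    if not out:
        raise ParameterError("sequence set is empty")
    return out


def dba_objective(y, X, radius_s: float | None, fs: float) -> float:
    """Sum of DTW measures from candidate barycenter ``y`` to every member of X."""
    arrays = _as_arrays(X)
    y = np.ascontiguousarray(getattr(y, "samples", y), dtype=np.float64)
    return float(sum(dtw_distance(y, x, radius_s, fs) for x in arrays))


def medoid_index(X, radius_s: float | None, fs: float) -> int:
    """Member of X minimizing the DBA objective over the whole set."""
    arrays = _as_arrays(X)
    best_i, best_obj = 0, np.inf
    for i, cand in enumerate(arrays):
        obj = 0.0
        for x in arrays:
            obj += dtw_distance(cand, x, radius_s, fs)
            if obj >= best_obj:
                break
        if obj < best_obj:
            best_i, best_obj = i, obj
    return best_i


def resample_linear(x, length: int) -> np.ndarray:
    """Linear-interpolation resampling to a fixed number of samples."""
    x = np.asarray(getattr(x, "samples", x), dtype=np.float64)
    if length < 2:
        raise ParameterError("resample length must be >= 2")
    if x.size == 1:
        return np.full(length, x[0])
    return np.interp(np.linspace(0.0, x.size - 1.0, length),
                     np.arange(x.size, dtype=np.float64), x)


def bs_dba(X, L_samples: int | None, radius_s: float | None, fs: float,
           batch_size: int = 32, epochs: int = 5,
           eta0: float | None = None, seed: int = 0) -> Barycenter:
    """Batch stochastic DBA barycenter of a sequence set.

    Parameters
    ----------
    X : sequence of 1-D arrays (or objects with ``.samples``)
    L_samples : target barycenter length; ``None`` falls back to the rounded
        average member duration.
    batch_size, epochs : mini-batch size (clamped to [1, len(X)] with a
        warning) and number of passes over X.
    eta0 : initial step size; default ``1 / (2 * batch_size)`` so a batch
        gradient step is an average pull of unit weight per member.
    seed : controls the per-epoch shuffles.
    """
    arrays = _as_arrays(X)
    n = len(arrays)
    if L_samples is None:
        L_samples = int(round(float(np.mean([a.size for a in arrays]))))
    if L_samples < 2:
        raise ParameterError("L_samples must be >= 2")
    if batch_size < 1 or batch_size > n:
        clamped = min(max(batch_size, 1), n)
        logger.warning("batch_size %d clamped to %d", batch_size, clamped)
        batch_size = clamped
    if eta0 is None:
        eta0 = 1.0 / (2.0 * batch_size)

    if n == 1:
        y = resample_linear(arrays[0], L_samples)
        return Barycenter(y, np.array([dba_objective(y, arrays, radius_s, fs)]),
                          seed=seed, epochs=0)

    med = medoid_index(arrays, radius_s, fs)
    y = resample_linear(arrays[med], L_samples)
    best = y.copy()
    best_obj = dba_objective(y, arrays, radius_s, fs)
    trace = [best_obj]

    rng = np.random.default_rng(seed)
    t = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = order[start:start + batch_size]
            g = np.zeros(L_samples)
            for idx in batch:
                x = arrays[idx]
                _, (pi, pj) = dtw_path(y, x, radius_s, fs)
                np.add.at(g, pi, 2.0 * (y[pi] - x[pj]))
            y = y - (eta0 / (1.0 + t)) * g
            t += 1
        obj = dba_objective(y, arrays, radius_s, fs)
        if obj < best_obj:
            best_obj = obj
            best = y.copy()
        trace.append(best_obj)
    return Barycenter(best, np.array(trace), seed=seed, epochs=epochs)
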