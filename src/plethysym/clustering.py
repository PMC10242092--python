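"""DTW K-Means over z-normalized variable-length phase sequences.

Training sequences are z-normalized (zero mean, unit population variance) so
clustering sees only shape, not amplitude offset or scale.  K-Means++ picks
the initial references, assignment uses banded DTW, and centroids are
refreshed with BS-DBA.  The iteration budget is fixed (no convergence test).
After fitting, clusters are relabelled in increasing order of mean member
duration: letters A.. for inspiration, digits 0.. for expiration, so a later
symbol always means a longer average phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .barycenter import bs_dba, resample_linear
from .config import EXP_SYMBOLS, INSP_SYMBOLS
from .dtw import dtw_distance
from .errors import ParameterError
from .segmentation import PhaseSequence

logger = logging.getLogger("plethysym.clustering")

__all__ = ["NormalizedSequence", "ClusterModel", "znormalize",
           "kmeanspp_init", "fit_kmeans"]


@dataclass
class NormalizedSequence:
    """A z-normalized sequence plus a handle on its source phase sequence."""

    samples: np.ndarray
    source: PhaseSequence | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.samples = np.ascontiguousarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        if self.source is not None:
            return self.source.duration_s
        return float(self.samples.size)


def znormalize(x, source: PhaseSequence | None = None) -> NormalizedSequence:
    """Center to zero mean and scale to unit population variance.

    Invariant to amplitude offset and positive scaling:
    znormalize(a*x + b) == znormalize(x) for a > 0.  A zero-variance input
    returns the all-zeros sequence flagged degenerate (it carries no shape).
    """
    arr = np.asarray(getattr(x, "samples", x), dtype=np.float64)
    if source is None and isinstance(x, PhaseSequence):
        source = x
    if arr.size < 2:
        raise ParameterError("z-normalization requires length >= 2")
    mu = arr.mean()
    sd = arr.std()  # population (1/n) convention, fixed for determinism
    if sd == 0.0 or not np.isfinite(sd):
        logger.debug("degenerate zero-variance sequence")
        return NormalizedSequence(np.zeros_like(arr), source, degenerate=True)
    return NormalizedSequence((arr - mu) / sd, source)


@dataclass
class ClusterModel:
    """Fitted references for one phase, ordered by mean member duration."""

    phase: str                       # "inspiration" | "expiration"
    references: list                 # K arrays of length L_samples
    labels: list                     # K symbols, bijective with clusters
    assignments: np.ndarray          # cluster index per training sequence
    mean_durations: np.ndarray       # seconds, non-decreasing in label order
    within_distances: list           # per-cluster member->centroid DTW values
    radius_s: float | None
    fs: float
    seed: int
    inertia_history: list = field(default_factory=list)
    train_sequences: list = field(default_factory=list)  # NormalizedSequence

    @property
    def K(self) -> int:
        return len(self.references)

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "references": [np.asarray(r).tolist() for r in self.references],
            "labels": list(self.labels),
            "assignments": np.asarray(self.assignments).tolist(),
            "mean_durations": np.asarray(self.mean_durations).tolist(),
            "within_distances": [np.asarray(w).tolist() for w in self.within_distances],
            "radius_s": self.radius_s,
            "fs": self.fs,
            "seed": self.seed,
            "inertia_history": [list(map(float, pair)) for pair in self.inertia_history],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            phase=d["phase"],
            references=[np.asarray(r, dtype=np.float64) for r in d["references"]],
            labels=list(d["labels"]),
            assignments=np.asarray(d["assignments"], dtype=np.int64),
            mean_durations=np.asarray(d["mean_durations"], dtype=np.float64),
            within_distances=[np.asarray(w, dtype=np.float64) for w in d["within_distances"]],
            radius_s=d["radius_s"],
            fs=d["fs"],
            seed=d["seed"],
            inertia_history=[tuple(p) for p in d.get("inertia_history", [])],
        )


def _symbols_for(phase: str, K: int) -> list[str]:
    pool = INSP_SYMBOLS if phase == "inspiration" else EXP_SYMBOLS
    if K > len(pool):
        raise ParameterError(f"no symbols left for K={K} {phase} clusters")
    return list(pool[:K])


def kmeanspp_init(X: list[NormalizedSequence], K: int,
                  radius_s: float | None, fs: float, seed: int,
                  L_samples: int) -> list[np.ndarray]:
    """K-Means++ seeding under the DTW measure.

    The first center is uniform-random; each next center is drawn with
    probability proportional to the DTW measure (the squared-cost distance)
    to its nearest already-chosen center.  Chosen members are resampled to
    the reference length.
    """
    n = len(X)
    if n < K:
        raise ParameterError(f"need at least K={K} sequences, got {n}")
    rng = np.random.default_rng(seed)
    arrays = [x.samples for x in X]
    chosen = [int(rng.integers(n))]
    d2 = np.array([dtw_distance(a, arrays[chosen[0]], radius_s, fs) for a in arrays])
    while len(chosen) < K:
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a center: uniform among unchosen
            unchosen = [i for i in range(n) if i not in chosen]
            idx = int(unchosen[rng.integers(len(unchosen))])
        else:
            idx = int(rng.choice(n, p=d2 / total))
        chosen.append(idx)
        d_new = np.array([dtw_distance(a, arrays[idx], radius_s, fs) for a in arrays])
        d2 = np.minimum(d2, d_new)
    return [resample_linear(arrays[i], L_samples) for i in chosen]


def fit_kmeans(X: list[NormalizedSequence], K: int, radius_s: float | None,
               fs: float, n_iter: int = 10, L_samples: int | None = None,
               seed: int = 0, phase: str = "inspiration",
               dba_batch_size: int = 32, dba_epochs: int = 5) -> ClusterModel:
    """Fit K references by alternating DTW assignment and BS-DBA updates.

    Runs exactly ``n_iter`` iterations (fixed budget).  Degenerate
    (zero-variance) sequences are excluded from training with a warning.
    An empty cluster is reseeded with the globally farthest sequence.
    """
    kept = [x for x in X if not x.degenerate]
    if len(kept) < len(X):
        logger.warning("excluded %d degenerate sequences from training",
                       len(X) - len(kept))
    n = len(kept)
    if n < K:
        raise ParameterError(f"need at least K={K} non-degenerate sequences, got {n}")
    if L_samples is None:
        L_samples = int(round(float(np.mean([x.samples.size for x in kept]))))

    ss = np.random.SeedSequence(seed)
    init_seed, *dba_seeds_root = [int(s) for s in ss.generate_state(2)]
    dba_ss = np.random.SeedSequence(dba_seeds_root[0])

    arrays = [x.samples for x in kept]
    centers = kmeanspp_init(kept, K, radius_s, fs, init_seed, L_samples)
    assignments = None
    inertia_history: list[tuple[float, float]] = []

    def distance_matrix():
        D = np.empty((n, K))
        for i, a in enumerate(arrays):
            for k in range(K):
                D[i, k] = dtw_distance(a, centers[k], radius_s, fs)
        return D

    dba_children = dba_ss.spawn(n_iter * K)
    for it in range(n_iter):
        D = distance_matrix()
        new_assign = np.argmin(D, axis=1)  # ties -> lowest cluster index
        new_inertia = float(D[np.arange(n), new_assign].sum())
        prev_inertia = (float(D[np.arange(n), assignments].sum())
                        if assignments is not None else new_inertia)
        inertia_history.append((prev_inertia, new_inertia))
        assignments = new_assign

        # reseed empty clusters with the globally farthest sequence
        for k in range(K):
            if not np.any(assignments == k):
                far = int(np.argmax(D[np.arange(n), assignments]))
                centers[k] = resample_linear(arrays[far], L_samples)
                assignments[far] = k
                logger.warning("reseeded empty cluster %d with sequence %d", k, far)

        for k in range(K):
            members = [arrays[i] for i in np.flatnonzero(assignments == k)]
            bary = bs_dba(members, L_samples, radius_s, fs,
                          batch_size=dba_batch_size, epochs=dba_epochs,
                          seed=int(dba_children[it * K + k].generate_state(1)[0] % (2**31)))
            centers[k] = bary.samples

    # final assignment against the final centroids
    D = distance_matrix()
    assignments = np.argmin(D, axis=1)
    final_inertia = float(D[np.arange(n), assignments].sum())
    inertia_history.append((final_inertia, final_inertia))

    durations = np.array([x.duration_s for x in kept])
    mean_dur = np.array([
        durations[assignments == k].mean() if np.any(assignments == k) else np.inf
        for k in range(K)
    ])
    order = np.argsort(mean_dur, kind="stable")
    remap = np.empty(K, dtype=np.int64)
    remap[order] = np.arange(K)
    references = [centers[k] for k in order]
    assignments = remap[assignments]
    mean_dur = mean_dur[order]
    within = [D[np.flatnonzero(assignments == k), order[k]] for k in range(K)]

    return ClusterModel(
        phase=phase,
        references=references,
        labels=_symbols_for(phase, K),
        assignments=assignments,
        mean_durations=mean_dur,
        within_distances=within,
        radius_s=radius_s,
        fs=fs,
        seed=seed,
        inertia_history=inertia_history,
        train_sequences=kept,
    )
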