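"""Respiratory cycle segmentation from nasal airflow.

Boundary detection does not run on the raw flow (noisy, corrupted by
coughing/sniffing artefacts) but on the lung volume obtained by numerical
integration of the flow.  Integration accumulates any sensor offset into a
linear trend, which is removed by subtracting the least-squares line; the
residual volume trace satisfies sum(v) = 0 and sum(t*v) = 0 exactly.

Inspiration starts are local minima of the volume (lungs empty), expiration
starts are the maximum between two consecutive minima (lungs full).  Minima
are prominence-filtered, with the prominence evaluated inside a sliding
window; plateau minima resolve to their earliest sample.  Cycles whose
inspiration or expiration duration falls outside [min_dur, max_dur] are
discarded whole, and the discarded spans are kept so that downstream
symbolization can mark them as unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError, ValidationError
from .signal_io import Recording


@dataclass
class VolumeTrace:
    """Detrended lung volume in mL (arbitrary zero)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)


@dataclass
class CycleSegmentation:
    """Per-cycle boundary triples (sample indices) plus discarded spans.

    ``t_in[k] < t_out[k] < t_end[k]`` for every retained cycle k, and cycles
    are in increasing time order; ``t_end[k]`` is the start of the next
    detected inspiration.  ``discarded`` holds (start, end) sample spans of
    cycles removed by the duration bounds.
    """

    t_in: np.ndarray
    t_out: np.ndarray
    t_end: np.ndarray
    fs: float
    discarded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_in = np.asarray(self.t_in, dtype=np.int64)
        self.t_out = np.asarray(self.t_out, dtype=np.int64)
        self.t_end = np.asarray(self.t_end, dtype=np.int64)
        if not (self.t_in.size == self.t_out.size == self.t_end.size):
            raise ValidationError("t_in/t_out/t_end must have equal length")
        if self.t_in.size:
            if not (np.all(self.t_in < self.t_out) and np.all(self.t_out < self.t_end)):
                raise ValidationError("cycle boundaries must strictly alternate")
            if not np.all(np.diff(self.t_in) > 0):
                raise ValidationError("cycles must be in increasing time order")

    @property
    def n_cycles(self) -> int:
        return int(self.t_in.size)

    def to_frame(self) -> pd.DataFrame:
        """Boundary table in seconds (cycle_index, t_in_s, t_out_s, t_next_in_s)."""
        return pd.DataFrame({
            "cycle_index": np.arange(self.n_cycles),
            "t_in_s": self.t_in / self.fs,
            "t_out_s": self.t_out / self.fs,
            "t_next_in_s": self.t_end / self.fs,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PhaseSequence:
    """One inspiration or expiration segment of raw airflow (mL/s)."""

    samples: np.ndarray
    phase: str  # "inspiration" | "expiration"
    start_index: int
    source_id: str
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.phase not in ("inspiration", "expiration"):
            raise ValidationError(f"bad phase {self.phase!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def integrate_detrended(rec: Recording) -> VolumeTrace:
    """Lung volume: running integral of the flow with the OLS line removed.

    v_t = sum_{u<=t} s_u / fs - (a*t + b), with (a, b) the least-squares
    line of the cumulative sum, so that sum(v) = 0 and sum(t*v) = 0.
    The 1/fs factor converts the sample sum into mL.
    """
    cum = np.cumsum(rec.samples) / rec.fs
    n = cum.size
    t = np.arange(n, dtype=np.float64)
    tc = t - t.mean()
    denom = float(tc @ tc)
    slope = float(tc @ cum) / denom if denom > 0 else 0.0
    intercept = float(cum.mean()) - slope * float(t.mean())
    return VolumeTrace(cum - (slope * t + intercept), rec.fs)


def detect_boundaries(vol: VolumeTrace, prominence: float, window_s: float,
                      min_dur_s: float, max_dur_s: float) -> CycleSegmentation:
    """Detect inspiration/expiration start indices on a volume trace.

    Local minima of ``vol`` with at least ``prominence`` (evaluated within a
    ``window_s`` sliding window) become inspiration starts; the first maximum
    of ``vol`` between consecutive minima becomes the expiration start.
    Cycles violating the duration bounds are dropped whole and recorded in
    ``discarded``.
    """
    if prominence <= 0 or window_s <= 0 or min_dur_s <= 0 or max_dur_s <= 0:
        raise ParameterError("detection parameters must be positive")
    if min_dur_s >= max_dur_s:
        raise ParameterError("min_dur_s must be < max_dur_s")
    if window_s < 2.0 / vol.fs:
        raise ParameterError("window_s shorter than two samples")

    v = vol.samples
    wlen = max(2, int(round(window_s * vol.fs)))
    # plateau_size=(1, None) exposes left_edges: plateau minima resolve to
    # their earliest sample, which keeps detection deterministic.
    peaks, props = find_peaks(-v, prominence=prominence, wlen=wlen,
                              plateau_size=(1, None))
    minima = props["left_edges"].astype(np.int64)
    if minima.size < 2:
        return CycleSegmentation(np.empty(0), np.empty(0), np.empty(0), vol.fs)

    min_n = min_dur_s * vol.fs
    max_n = max_dur_s * vol.fs
    t_in, t_out, t_end, discarded = [], [], [], []
    for a, b in zip(minima[:-1], minima[1:]):
        j = a + 1 + int(np.argmax(v[a + 1:b]))  # earliest maximum between minima
        ti_n = j - a
        te_n = b - j
        if min_n <= ti_n <= max_n and min_n <= te_n <= max_n:
            t_in.append(a)
            t_out.append(j)
            t_end.append(b)
        else:
            discarded.append((int(a), int(b)))
    return CycleSegmentation(np.array(t_in), np.array(t_out), np.array(t_end),
                             vol.fs, discarded)


def segment_recording(rec: Recording, prominence: float, window_s: float,
                      min_dur_s: float, max_dur_s: float) -> CycleSegmentation:
    """Convenience wrapper: integrate, detrend and detect in one call."""
    return detect_boundaries(integrate_detrended(rec), prominence, window_s,
                             min_dur_s, max_dur_s)


def split_phases(rec: Recording, seg: CycleSegmentation):
    """Cut the raw airflow into inspiration and expiration sequences.

    Half-open convention: inspiration k is samples [t_in[k], t_out[k]) and
    expiration k is [t_out[k], t_end[k]), so concatenating the phases of one
    cycle reproduces the recording span exactly.  Returns equal-length lists.
    """
    if seg.n_cycles and seg.t_end[-1] > rec.n_samples:
        raise ValidationError("segmentation extends beyond the recording")
    if abs(seg.fs - rec.fs) > 1e-9:
        raise ValidationError("segmentation and recording sampling rates differ")
    inspirations, expirations = [], []
    for a, j, b in zip(seg.t_in, seg.t_out, seg.t_end):
        inspirations.append(PhaseSequence(rec.samples[a:j], "inspiration",
                                          int(a), rec.subject_id, rec.fs))
        expirations.append(PhaseSequence(rec.samples[j:b], "expiration",
                                         int(j), rec.subject_id, rec.fs))
    return inspirations, expirations
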