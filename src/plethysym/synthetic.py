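"""Synthetic airflow generator with ground-truth labels.

Emulates murine nasal airflow as a concatenation of labelled cycle
archetypes (~0.3 s cycles): inspiration shapes are a half-sine, a biphasic
double-lobed inflow, or a delayed inflow with a pre-inspiratory pause;
expiration shapes are a half-sine or a post-inspiratory pause of graded
duration followed by the outflow.  Per-cycle random time warping, additive
white noise and a slow sinusoidal baseline drift model the distortions the
method must absorb.  Expiration amplitude is balanced so every cycle's net
volume is ~0 (air in equals air out), which keeps the integrated volume
trace bounded.

A half-expiration lead-in and half-inspiration lead-out are prepended/
appended so that the first and last true cycle boundaries are interior
volume extrema and therefore detectable; pads carry no ground-truth label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import PipelineConfig
from .errors import ParameterError
from .segmentation import PhaseSequence, segment_recording, split_phases
from .signal_io import Recording

logger = logging.getLogger("plethysym.synthetic")

__all__ = ["CycleArchetype", "GroundTruth", "default_archetypes",
           "archetype_trio", "generate_recording", "generate_cohort",
           "subsample_training", "noise_sd_for_snr", "matched_symbol_accuracy"]

_INSP_KINDS = ("half_sine", "biphasic", "delayed")
_EXP_KINDS = ("half_sine", "post_insp_pause")


@dataclass(frozen=True)
class CycleArchetype:
    """One labelled respiratory cycle shape.

    ``insp_shape``/``exp_shape`` are (kind, parameter) pairs; the parameter
    is the gap/pause fraction of the phase duration, in [0, 1).
    """

    name: str
    insp_shape: tuple = ("half_sine", 0.0)
    exp_shape: tuple = ("half_sine", 0.0)
    Ti: float = 0.12       # inspiration duration (s)
    Te: float = 0.18       # expiration duration (s)
    amplitude: float = 1.5  # peak inspiratory flow (mL/s)

    def __post_init__(self) -> None:
        ik, ip = self.insp_shape
        ek, ep = self.exp_shape
        if ik not in _INSP_KINDS or ek not in _EXP_KINDS:
            raise ParameterError(f"unknown shape kind in archetype {self.name}")
        if not (0.0 <= ip < 1.0 and 0.0 <= ep < 1.0):
            raise ParameterError("pause/gap fractions must be in [0, 1)")
        if self.Ti <= 0 or self.Te <= 0 or self.amplitude <= 0:
            raise ParameterError("Ti, Te and amplitude must be positive")

    @property
    def insp_class(self) -> str:
        return f"{self.insp_shape[0]}:{self.insp_shape[1]:g}"

    @property
    def exp_class(self) -> str:
        return f"{self.exp_shape[0]}:{self.exp_shape[1]:g}"


@dataclass
class GroundTruth:
    """Exact per-cycle boundaries and archetype labels of a generated recording."""

    cycles: pd.DataFrame  # cycle_index, archetype, insp_class, exp_class, t_in_s, t_out_s, t_end_s
    subject_id: str
    group: str
    phase: str

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def to_csv(self, path) -> None:
        self.cycles.to_csv(path, index=False)


def default_archetypes() -> dict[str, CycleArchetype]:
    """A small vocabulary covering the shape families the method targets:
    sinusoidal short cycles, biphasic inspirations, pre-inspiratory pauses
    and post-inspiratory pauses of graded duration."""
    specs = {
        "A0": (("half_sine", 0.0), ("half_sine", 0.0), 0.10, 0.14),
        "B0": (("half_sine", 0.0), ("half_sine", 0.0), 0.14, 0.18),
        "C0": (("biphasic", 0.25), ("half_sine", 0.0), 0.16, 0.16),
        "D2": (("biphasic", 0.45), ("post_insp_pause", 0.35), 0.18, 0.24),
        "E4": (("delayed", 0.40), ("post_insp_pause", 0.60), 0.20, 0.32),
    }
    return {name: CycleArchetype(name, i, e, ti, te)
            for name, (i, e, ti, te) in specs.items()}


def archetype_trio() -> dict[str, CycleArchetype]:
    """Three archetypes with pairwise-distinct inspiration AND expiration
    shapes — the standard recovery benchmark (K=3 per phase)."""
    return {
        "A0": CycleArchetype("A0", ("half_sine", 0.0), ("half_sine", 0.0), 0.11, 0.15),
        "C2": CycleArchetype("C2", ("biphasic", 0.35), ("post_insp_pause", 0.35), 0.16, 0.22),
        "E4": CycleArchetype("E4", ("delayed", 0.35), ("post_insp_pause", 0.60), 0.18, 0.30),
    }


#: Residual flow through a quasi-closed airway during a pause or gap, as a
#: fraction of the archetype amplitude.  A pause is never a perfect seal;
#: the small leak also keeps the volume trace strictly monotone through the
#: pause, so cycle boundaries stay well defined under noise.
PAUSE_LEAK = 0.08

#: Attenuation of the flow envelope inside a biphasic inspiration's dip.
#: Unlike a pause (quasi-closed airway), the dip reflects impaired but
#: ongoing inflow, so substantially more air keeps moving through it.
BIPHASIC_DIP = 0.2


def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def _render_insp(shape: tuple, n: int, amplitude: float) -> np.ndarray:
    kind, p = shape
    leak = PAUSE_LEAK * amplitude
    if kind == "half_sine":
        return amplitude * _half_sine(n)
    if kind == "delayed":
        n_pause = int(round(p * n))
        n_act = max(2, n - n_pause)
        return np.concatenate([np.full(n - n_act, leak),
                               amplitude * _half_sine(n_act)])
    # biphasic: a half-sine whose middle window is attenuated to the leak
    # level, so the air enters in two lobes around a low-flow dip
    y = amplitude * _half_sine(n)
    n_gap = int(round(p * n))
    a = (n - n_gap) // 2
    y[a:a + n_gap] *= BIPHASIC_DIP
    return y


def _render_exp(shape: tuple, n: int, amplitude: float) -> np.ndarray:
    kind, p = shape
    if kind == "half_sine":
        return -amplitude * _half_sine(n)
    n_pause = int(round(p * n))
    n_act = max(2, n - n_pause)
    return np.concatenate([np.full(n - n_act, -PAUSE_LEAK * amplitude),
                           -amplitude * _half_sine(n_act)])


def _render_cycle(arch: CycleArchetype, fs: float, warp_i: float, warp_e: float):
    n_i = max(2, int(round(arch.Ti * (1.0 + warp_i) * fs)))
    n_e = max(2, int(round(arch.Te * (1.0 + warp_e) * fs)))
    insp = _render_insp(arch.insp_shape, n_i, arch.amplitude)
    exp = _render_exp(arch.exp_shape, n_e, arch.amplitude)
    # balance amplitudes so inspired volume equals expired volume exactly
    exp *= insp.sum() / abs(exp.sum())
    return insp, exp


def generate_recording(archetype_sequence: list[CycleArchetype], fs: float = 250.0,
                       noise_sd: float = 0.0, drift_amp: float = 0.0,
                       drift_freq_hz: float = 0.05, warp_pct: float = 0.0,
                       seed: int = 0, pad: bool = True,
                       subject_id: str = "sim", group: str = "sim",
                       phase: str = "pre") -> tuple[Recording, GroundTruth]:
    """Concatenate archetype cycles into a labelled synthetic recording.

    Each cycle's Ti/Te are independently warped by a uniform factor in
    [1-warp_pct, 1+warp_pct]; white Gaussian noise (``noise_sd`` mL/s) and a
    slow sinusoidal baseline drift are then added to the flow.
    """
    if not archetype_sequence:
        raise ParameterError("archetype_sequence is empty")
    if not 0.0 <= warp_pct < 0.5:
        raise ParameterError("warp_pct must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    pos = 0
    if pad:
        lead = _render_exp(archetype_sequence[0].exp_shape,
                           max(2, int(round(archetype_sequence[0].Te * fs))),
                           archetype_sequence[0].amplitude)
        chunks.append(lead)
        pos = lead.size
    rows = []
    for k, arch in enumerate(archetype_sequence):
        wi, we = rng.uniform(-warp_pct, warp_pct, size=2) if warp_pct else (0.0, 0.0)
        insp, exp = _render_cycle(arch, fs, wi, we)
        rows.append((k, arch.name, arch.insp_class, arch.exp_class,
                     pos / fs, (pos + insp.size) / fs,
                     (pos + insp.size + exp.size) / fs))
        chunks.append(insp)
        chunks.append(exp)
        pos += insp.size + exp.size
    if pad:
        tail = _render_insp(archetype_sequence[-1].insp_shape,
                            max(2, int(round(archetype_sequence[-1].Ti * fs))),
                            archetype_sequence[-1].amplitude)
        chunks.append(tail)
    samples = np.concatenate(chunks)
    n = samples.size
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, n)
    if drift_amp > 0:
        t = np.arange(n) / fs
        samples = samples + drift_amp * np.sin(
            2.0 * np.pi * drift_freq_hz * t + rng.uniform(0.0, 2.0 * np.pi))
    truth = GroundTruth(
        pd.DataFrame(rows, columns=["cycle_index", "archetype", "insp_class",
                                    "exp_class", "t_in_s", "t_out_s", "t_end_s"]),
        subject_id, group, phase)
    rec = Recording(samples, fs, subject_id, group, phase)
    return rec, truth


def noise_sd_for_snr(archetypes, snr_db: float, fs: float = 250.0) -> float:
    """Noise standard deviation giving the requested SNR against one clean
    pass through the archetype vocabulary."""
    seq = list(archetypes.values()) if isinstance(archetypes, dict) else list(archetypes)
    rec, _ = generate_recording(seq, fs=fs, pad=False)
    rms = float(np.sqrt(np.mean(rec.samples ** 2)))
    return rms * 10.0 ** (-snr_db / 20.0)


def generate_cohort(n_per_group: int, mixtures: dict[str, dict[str, float]],
                    archetypes: dict[str, CycleArchetype] | None = None,
                    cycles_per_recording: int = 60, fs: float = 250.0,
                    noise_sd: float = 0.0, drift_amp: float = 0.0,
                    warp_pct: float = 0.0, seed: int = 0,
                    phase: str = "pre") -> list[tuple[Recording, GroundTruth]]:
    """Simulate a cohort: ``n_per_group`` recordings per group, each cycle's
    archetype drawn from the group's mixture over archetype names."""
    if archetypes is None:
        archetypes = default_archetypes()
    for g, mix in mixtures.items():
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ParameterError(f"mixture for group {g!r} does not sum to 1")
        unknown = set(mix) - set(archetypes)
        if unknown:
            raise ParameterError(f"mixture for group {g!r} names unknown archetypes {unknown}")
    ss = np.random.SeedSequence(seed)
    out = []
    for g, mix in mixtures.items():
        names = sorted(mix)
        probs = np.array([mix[a] for a in names])
        for i in range(n_per_group):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            drawn = rng.choice(len(names), size=cycles_per_recording, p=probs)
            seq = [archetypes[names[k]] for k in drawn]
            rec, truth = generate_recording(
                seq, fs=fs, noise_sd=noise_sd, drift_amp=drift_amp,
                warp_pct=warp_pct, seed=int(child.generate_state(1)[0] % (2 ** 31)),
                subject_id=f"{g}-{i + 1}", group=g, phase=phase)
            out.append((rec, truth))
    return out


def subsample_training(recordings: list[Recording], cycles_per_recording: int,
                       config: PipelineConfig | None = None):
    """Evenly-in-time cycle subsampling into per-phase training sets.

    Each recording is segmented, its cycles ranked by inspiration start
    time, and the cycles nearest to an even time grid over the recording
    span are selected (all cycles when fewer are available).  Returns
    (inspirations, expirations) with one member of each per selected cycle.
    """
    if config is None:
        config = PipelineConfig()
    insp_out: list[PhaseSequence] = []
    exp_out: list[PhaseSequence] = []
    for rec in recordings:
        seg = segment_recording(rec, config.prominence, config.window_s,
                                config.min_dur_s, config.max_dur_s)
        insp, exp = split_phases(rec, seg)
        C = seg.n_cycles
        if C == 0:
            continue
        m = cycles_per_recording
        if C <= m:
            if C < m:
                logger.info("recording %s has %d < %d cycles; taking all",
                            rec.subject_id, C, m)
            idx = np.arange(C)
        else:
            t = seg.t_in / seg.fs
            grid = np.linspace(t[0], t[-1], m)
            pos = np.clip(np.searchsorted(t, grid), 0, C - 1)
            left = np.clip(pos - 1, 0, C - 1)
            pos = np.where(np.abs(t[left] - grid) <= np.abs(t[pos] - grid), left, pos)
            # enforce strictly increasing picks (feasible since m <= C)
            for i in range(1, m):
                if pos[i] <= pos[i - 1]:
                    pos[i] = pos[i - 1] + 1
            for i in range(m - 1, -1, -1):
                cap = C - 1 - (m - 1 - i)
                if pos[i] > cap:
                    pos[i] = cap
            idx = pos.astype(np.int64)
        insp_out.extend(insp[i] for i in idx)
        exp_out.extend(exp[i] for i in idx)
    return insp_out, exp_out


def matched_symbol_accuracy(true_labels, pred_labels) -> float:
    """Per-cycle accuracy after optimally matching predicted symbols to
    ground-truth classes (Hungarian assignment on the contingency table).

    Predicted outliers never match any true class.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.size != pred_labels.size or true_labels.size == 0:
        raise ParameterError("label vectors must be non-empty and equal length")
    tvals = np.unique(true_labels)
    pvals = np.unique(pred_labels)
    from .config import OUTLIER

    table = np.zeros((tvals.size, pvals.size))
    for i, tv in enumerate(tvals):
        for j, pv in enumerate(pvals):
            if pv == OUTLIER:
                continue  # outliers never count as correct
            table[i, j] = np.sum((true_labels == tv) & (pred_labels == pv))
    ri, ci = linear_sum_assignment(-table)
    return float(table[ri, ci].sum() / true_labels.size)
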