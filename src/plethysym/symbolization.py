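"""Symbolization of recordings against fitted reference shapes.

Each segmented cycle receives a two-character symbol: a letter for the
inspiration shape and a digit for the expiration shape, assigned by 1-NN
DTW against the cluster references.  A phase whose distance to its nearest
reference exceeds that reference's alpha-quantile threshold (estimated on
the within-cluster training distances) is gated out as an outlier; cycles
discarded at segmentation by the duration bounds are likewise emitted as
outlier spans so that the symbolic timeline covers the whole recording.
A combined cycle symbol is an outlier if either of its phases is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterModel, znormalize
from .config import OUTLIER, PipelineConfig
from .dtw import nearest_reference
from .errors import ParameterError
from .segmentation import (CycleSegmentation, integrate_detrended,
                           detect_boundaries, split_phases)
from .signal_io import Recording

logger = logging.getLogger("plethysym.symbolization")

__all__ = ["ThresholdSet", "SymbolicRecording", "fit_thresholds",
           "classify_sequences", "symbolize", "compute_descriptors",
           "save_models", "load_models"]

_COLUMNS = ["cycle_index", "t_in_s", "t_out_s", "t_end_s",
            "insp_symbol", "exp_symbol", "insp_dist", "exp_dist", "outlier"]


@dataclass
class ThresholdSet:
    """Per-reference outlier thresholds: alpha-quantile of training distances."""

    thresholds: dict
    alpha: float


@dataclass
class SymbolicRecording:
    """Per-cycle symbols with timing, the substrate for RC maps and bar codes."""

    cycles: pd.DataFrame
    subject_id: str
    group: str
    phase: str
    fs: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# subject_id={self.subject_id}\n")
            fh.write(f"# group={self.group}\n")
            fh.write(f"# phase={self.phase}\n")
            fh.write(f"# fs={self.fs!r}\n")
            self.cycles.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SymbolicRecording":
        meta = {}
        n_header = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                n_header += 1
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
        df = pd.read_csv(path, skiprows=n_header,
                         dtype={"insp_symbol": str, "exp_symbol": str})
        return cls(df, meta.get("subject_id", "unknown"), meta.get("group", "unknown"),
                   meta.get("phase", "pre"), float(meta.get("fs", 1.0)))


def fit_thresholds(model: ClusterModel, alpha: float) -> ThresholdSet:
    """Per-cluster outlier threshold: empirical alpha-quantile (linear
    interpolation between order statistics) of the within-cluster training
    distances."""
    if not 0.0 < alpha <= 1.0:
        raise ParameterError("alpha must be in (0, 1]")
    thresholds = {}
    for label, dists in zip(model.labels, model.within_distances):
        dists = np.asarray(dists, dtype=np.float64)
        if dists.size == 0:
            thresholds[label] = 0.0
            continue
        thresholds[label] = float(np.quantile(dists, alpha, method="linear"))
    return ThresholdSet(thresholds, alpha)


def classify_sequences(sequences, model: ClusterModel,
                       thresholds: ThresholdSet | None = None):
    """1-NN DTW labels and distances for z-normalized sequences.

    Returns (labels, distances); a label is :data:`OUTLIER` when the
    sequence is degenerate or its nearest distance exceeds that reference's
    threshold.
    """
    labels, distances = [], []
    for z in sequences:
        if getattr(z, "degenerate", False):
            labels.append(OUTLIER)
            distances.append(np.nan)
            continue
        k, dists = nearest_reference(z.samples, model.references,
                                     model.radius_s, model.fs)
        d = float(dists[k])
        label = model.labels[k]
        if thresholds is not None and d > thresholds.thresholds[label]:
            label = OUTLIER
        labels.append(label)
        distances.append(d)
    return labels, distances


def symbolize(rec: Recording, insp_model: ClusterModel, exp_model: ClusterModel,
              insp_thresholds: ThresholdSet, exp_thresholds: ThresholdSet,
              config: PipelineConfig) -> SymbolicRecording:
    """Segment a recording and assign a two-character symbol to every cycle.

    Each phase sequence is z-normalized and matched to its nearest reference
    by banded DTW; duration-discarded cycles become outlier spans.
    """
    vol = integrate_detrended(rec)
    seg = detect_boundaries(vol, config.prominence, config.window_s,
                            config.min_dur_s, config.max_dur_s)
    rows = []
    if seg.n_cycles == 0 and not seg.discarded:
        logger.warning("recording %s: no respiratory cycles detected", rec.subject_id)
    else:
        insp, exp = split_phases(rec, seg)
        insp_z = [znormalize(p) for p in insp]
        exp_z = [znormalize(p) for p in exp]
        insp_labels, insp_d = classify_sequences(insp_z, insp_model, insp_thresholds)
        exp_labels, exp_d = classify_sequences(exp_z, exp_model, exp_thresholds)
        for k in range(seg.n_cycles):
            outlier = insp_labels[k] == OUTLIER or exp_labels[k] == OUTLIER
            rows.append((seg.t_in[k] / rec.fs, seg.t_out[k] / rec.fs,
                         seg.t_end[k] / rec.fs, insp_labels[k], exp_labels[k],
                         insp_d[k], exp_d[k], outlier))
        for a, b in seg.discarded:
            rows.append((a / rec.fs, np.nan, b / rec.fs,
                         OUTLIER, OUTLIER, np.nan, np.nan, True))
    rows.sort(key=lambda r: r[0])
    df = pd.DataFrame(rows, columns=_COLUMNS[1:])
    df.insert(0, "cycle_index", np.arange(len(df)))
    return SymbolicRecording(df, rec.subject_id, rec.group, rec.phase, rec.fs)


def compute_descriptors(rec: Recording, seg: CycleSegmentation) -> pd.DataFrame:
    """Classical per-cycle ventilation descriptors.

    Ti/Te are the phase durations in seconds; NIV/NEV the inhaled/exhaled
    nasal volumes in mL (rectangle-rule integral of the flow over the phase).
    """
    insp, exp = split_phases(rec, seg)
    return pd.DataFrame({
        "cycle_index": np.arange(seg.n_cycles),
        "Ti": (seg.t_out - seg.t_in) / seg.fs,
        "Te": (seg.t_end - seg.t_out) / seg.fs,
        "NIV": [float(p.samples.sum() / p.fs) for p in insp],
        "NEV": [float(abs(p.samples.sum()) / p.fs) for p in exp],
    })


def fit_models(insp_phases, exp_phases, config: PipelineConfig,
               seed: int | None = None):
    """Fit the inspiration and expiration reference models independently.

    Takes raw :class:`PhaseSequence` training sets (e.g. from
    ``synthetic.subsample_training``), z-normalizes them, runs DTW K-Means
    per phase and estimates the outlier thresholds.  Returns
    (insp_model, exp_model, insp_thresholds, exp_thresholds).
    """
    from .clustering import fit_kmeans

    if seed is None:
        seed = config.seed
    s_in, s_ex = (int(s % (2 ** 31))
                  for s in np.random.SeedSequence(seed).generate_state(2))
    insp_model = fit_kmeans(
        [znormalize(p) for p in insp_phases], config.k_insp, config.sc_radius_s,
        config.fs, config.kmeans_iters, config.ref_length_samples, s_in,
        "inspiration", config.dba_batch_size, config.dba_epochs)
    exp_model = fit_kmeans(
        [znormalize(p) for p in exp_phases], config.k_exp, config.sc_radius_s,
        config.fs, config.kmeans_iters, config.ref_length_samples, s_ex,
        "expiration", config.dba_batch_size, config.dba_epochs)
    return (insp_model, exp_model,
            fit_thresholds(insp_model, config.alpha),
            fit_thresholds(exp_model, config.alpha))


def save_models(path, insp_model: ClusterModel, exp_model: ClusterModel,
                insp_thresholds: ThresholdSet, exp_thresholds: ThresholdSet,
                config: PipelineConfig) -> None:
    """Serialize the fitted model bundle to JSON so symbolization of new
    recordings needs no refit."""
    bundle = {
        "insp_model": insp_model.to_dict(),
        "exp_model": exp_model.to_dict(),
        "insp_thresholds": {"alpha": insp_thresholds.alpha,
                            "thresholds": insp_thresholds.thresholds},
        "exp_thresholds": {"alpha": exp_thresholds.alpha,
                           "thresholds": exp_thresholds.thresholds},
        "config": config.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)


def load_models(path):
    """Inverse of :func:`save_models`.

    Returns (insp_model, exp_model, insp_thresholds, exp_thresholds, config).
    """
    with open(path) as fh:
        bundle = json.load(fh)
    return (
        ClusterModel.from_dict(bundle["insp_model"]),
        ClusterModel.from_dict(bundle["exp_model"]),
        ThresholdSet(bundle["insp_thresholds"]["thresholds"],
                     bundle["insp_thresholds"]["alpha"]),
        ThresholdSet(bundle["exp_thresholds"]["thresholds"],
                     bundle["exp_thresholds"]["alpha"]),
        PipelineConfig.from_dict(bundle["config"]),
    )
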