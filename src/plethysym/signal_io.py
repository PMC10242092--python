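"""Airflow recording container and I/O.

A :class:`Recording` is a uniformly sampled nasal-airflow trace in mL/s
(positive during inspiration, negative during expiration) plus the metadata
needed downstream: sampling rate, subject id, group label (e.g. genotype)
and experimental phase (pre/post stressor).

Two neutral container formats are supported:

* CSV — two columns ``time,flow``; metadata in leading comment lines of the
  form ``# key=value`` (keys ``fs``, ``subject_id``, ``group``, ``phase``,
  optionally ``t0``).
* HDF5 — one group per recording holding a ``flow`` dataset, with the same
  metadata as group attributes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, ParameterError, ValidationError

#: Declared vocabulary for the experimental phase label.
PHASES = ("pre", "post")


@dataclass
class Recording:
    """A single-channel airflow recording with metadata.

    Attributes
    ----------
    samples : ndarray
        Airflow in mL/s, positive during inspiration.
    fs : float
        Sampling rate in Hz.
    subject_id, group, phase : str
        Recording metadata; ``phase`` must be one of :data:`PHASES`.
    t0 : float
        Acquisition start time in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    group: str = "unknown"
    phase: str = "pre"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not self.group:
            raise ValidationError("group must be non-empty")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds (t0-offset)."""
        return self.t0 + np.arange(self.n_samples) / self.fs


_META_KEYS = ("fs", "subject_id", "group", "phase", "t0")


def write_recording(rec: Recording, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a recording as CSV or HDF5 (format inferred from extension)."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs={rec.fs!r}\n")
            fh.write(f"# subject_id={rec.subject_id}\n")
            fh.write(f"# group={rec.group}\n")
            fh.write(f"# phase={rec.phase}\n")
            fh.write(f"# t0={rec.t0!r}\n")
            fh.write("time,flow\n")
            t = rec.time()
            for ti, si in zip(t, rec.samples):
                fh.write(f"{float(ti)!r},{float(si)!r}\n")
    else:
        with h5py.File(path, "a") as h5:
            if rec.subject_id in h5:
                del h5[rec.subject_id]
            grp = h5.create_group(rec.subject_id)
            grp.create_dataset("flow", data=rec.samples)
            grp.attrs["fs"] = rec.fs
            grp.attrs["subject_id"] = rec.subject_id
            grp.attrs["group"] = rec.group
            grp.attrs["phase"] = rec.phase
            grp.attrs["t0"] = rec.t0


def read_recording(path: str | os.PathLike, format: str | None = None,
                   group_name: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        If the file lacks the ``fs`` metadata or the expected layout.
    ValidationError
        If the stored samples violate Recording invariants.
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        meta: dict[str, str] = {}
        n_header = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                n_header += 1
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
        if "fs" not in meta:
            raise FormatError(f"{path}: missing 'fs' metadata header")
        try:
            df = pd.read_csv(path, skiprows=n_header)
        except Exception as exc:  # pragma: no cover - pandas error passthrough
            raise FormatError(f"{path}: unreadable CSV body: {exc}") from exc
        if "flow" not in df.columns:
            raise FormatError(f"{path}: missing 'flow' column")
        return Recording(
            samples=df["flow"].to_numpy(dtype=np.float64),
            fs=float(meta["fs"]),
            subject_id=meta.get("subject_id", "unknown"),
            group=meta.get("group", "unknown"),
            phase=meta.get("phase", "pre"),
            t0=float(meta.get("t0", 0.0)),
        )
    with h5py.File(path, "r") as h5:
        if group_name is None:
            names = sorted(h5.keys())
            if not names:
                raise FormatError(f"{path}: empty HDF5 file")
            group_name = names[0]
        if group_name not in h5:
            raise FormatError(f"{path}: no group {group_name!r}")
        grp = h5[group_name]
        if "flow" not in grp:
            raise FormatError(f"{path}: group {group_name!r} lacks a 'flow' dataset")
        if "fs" not in grp.attrs:
            raise FormatError(f"{path}: group {group_name!r} lacks an 'fs' attribute")
        return Recording(
            samples=np.asarray(grp["flow"], dtype=np.float64),
            fs=float(grp.attrs["fs"]),
            subject_id=str(grp.attrs.get("subject_id", group_name)),
            group=str(grp.attrs.get("group", "unknown")),
            phase=str(grp.attrs.get("phase", "pre")),
            t0=float(grp.attrs.get("t0", 0.0)),
        )


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Decimate a recording to ``target_fs`` with a zero-phase anti-alias filter.

    The decimation factor ``fs/target_fs`` must be an integer.  A zero-phase
    FIR low-pass is applied before decimation so that cycle boundaries are
    not shifted by filter group delay.  Output length is ``floor(n/q)``.
    """
    if target_fs <= 0:
        raise ParameterError("target_fs must be positive")
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ParameterError(
            f"fs={rec.fs} is not an integer multiple of target_fs={target_fs}")
    if q == 1:
        return replace(rec, samples=rec.samples.copy())
    # polyphase FIR decimation is zero-phase; line-extension padding keeps
    # edges free of filter start-up transients (constants stay constant)
    out = signal.resample_poly(rec.samples, 1, q, padtype="line")
    out = out[: rec.n_samples // q]
    return replace(rec, samples=out, fs=target_fs)


def _infer_format(path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "hdf"):
            raise ParameterError(f"unknown format {format!r}")
        return format
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        return "csv"
    if ext in (".h5", ".hdf", ".hdf5"):
        return "hdf"
    raise ParameterError(f"cannot infer format from extension {ext!r}")
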