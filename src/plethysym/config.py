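"""Pipeline configuration.

All tunable hyperparameters of the method live in :class:`PipelineConfig`.
The defaults are the operating point used throughout the package: cycle
detection bounds chosen for murine breathing (cycles of roughly 0.3 s),
five reference shapes per phase, a narrow Sakoe-Chiba corridor (0.01 s)
that only absorbs small time dilations, and a 0.95 outlier quantile.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError

logging.getLogger("plethysym").addHandler(logging.NullHandler())

#: Symbols assigned to inspiration clusters, in increasing mean-duration order.
INSP_SYMBOLS = "ABCDEFGHIJKLM"
#: Symbols assigned to expiration clusters, in increasing mean-duration order.
EXP_SYMBOLS = "0123456789"
#: Symbol used for unclassified / gated-out cycles.
OUTLIER = "OUT"

#: Fixed inspiration palette for K=5 (red -> yellow, darker = shorter).
INSP_PALETTE_5 = ("#ff0000", "#ff4000", "#ff8000", "#ffbf00", "#ffff00")
#: Fixed expiration palette for K=5 (blue -> green, darker = shorter).
EXP_PALETTE_5 = ("#0000ff", "#0040df", "#0080bf", "#00bf9f", "#00ff80")
#: Colour of outlier spans in bar codes.
OUTLIER_COLOR = "#d0d0d0"


def round_half_up(x: float) -> int:
    """Deterministic round-half-up (0.5 always rounds away from zero for x>=0)."""
    import math

    return int(math.floor(x + 0.5))


@dataclass
class PipelineConfig:
    """Hyperparameters of the full pipeline.

    Units are physical: seconds for durations and the warping radius, mL for
    the volume prominence, Hz for the sampling rate.
    """

    fs: float = 250.0                 # working sampling rate (Hz)
    prominence: float = 0.03          # volume-peak prominence (mL)
    window_s: float = 2.0             # prominence evaluation window (s)
    min_dur_s: float = 0.05           # minimum inspiration/expiration duration (s)
    max_dur_s: float = 2.0            # maximum inspiration/expiration duration (s)
    k_insp: int = 5                   # inspiration clusters
    k_exp: int = 5                    # expiration clusters
    kmeans_iters: int = 10            # fixed K-Means iteration budget
    sc_radius_s: float = 0.01         # Sakoe-Chiba radius (s)
    ref_length_s: float = 0.2         # reference sequence length (s)
    alpha: float = 0.95               # outlier quantile threshold
    dba_batch_size: int = 32          # BS-DBA mini-batch size
    dba_epochs: int = 5               # BS-DBA epochs per centroid update
    seed: int = 0                     # master seed

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.min_dur_s >= self.max_dur_s:
            raise ParameterError("min_dur_s must be < max_dur_s")
        if not 0.0 < self.alpha <= 1.0:
            raise ParameterError("alpha must be in (0, 1]")
        if self.k_insp < 1 or self.k_exp < 1:
            raise ParameterError("cluster counts must be >= 1")

    @property
    def ref_length_samples(self) -> int:
        """Reference length in samples (0.2 s at 250 Hz -> 50)."""
        return round_half_up(self.ref_length_s * self.fs)

    @property
    def sc_radius_samples(self) -> int:
        """Band radius in samples, round-half-up with a floor of 1 sample.

        At 250 Hz a 0.01 s radius gives round(2.5) = 3 samples.
        """
        return max(1, round_half_up(self.sc_radius_s * self.fs))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ParameterError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)
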