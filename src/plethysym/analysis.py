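"""Referent-cycle time distributions and group comparison maps.

The unit of observation is the per-subject percentage of *classified* time
spent in each referent cycle (letter, digit).  Group differences are tested
cell-by-cell with a two-sided Mann-Whitney U test and controlled for
multiple testing across the K1 x K2 cells with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import OUTLIER
from .errors import ParameterError
from .symbolization import SymbolicRecording

logger = logging.getLogger("plethysym.analysis")

__all__ = ["RCDistribution", "TestMap", "rc_distribution",
           "marginal_profiles", "compare_groups"]


@dataclass
class RCDistribution:
    """K1 x K2 matrix: percent of classified time per referent cycle."""

    matrix: np.ndarray
    insp_labels: list
    exp_labels: list
    subject_id: str = "unknown"
    group: str = "unknown"
    phase: str = "pre"
    outlier_time_fraction: float = 0.0
    all_outliers: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.insp_labels),
                            columns=list(self.exp_labels))


@dataclass
class TestMap:
    """Per-cell Mann-Whitney p-values with BH-FDR adjustment."""

    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    insp_labels: list
    exp_labels: list
    level: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, li), (j, lj) in itertools.product(enumerate(self.insp_labels),
                                                  enumerate(self.exp_labels)):
            rows.append((li, lj, self.raw_p[i, j], self.adjusted_p[i, j],
                         bool(self.rejected[i, j])))
        return pd.DataFrame(rows, columns=["insp_symbol", "exp_symbol",
                                           "raw_p", "adjusted_p", "rejected"])


def rc_distribution(sym: SymbolicRecording, insp_labels, exp_labels) -> RCDistribution:
    """Percent of classified time per (letter, digit) referent cycle.

    Cell (i, j) = 100 * (duration of cycles symbolized (letter_i, digit_j))
    / (duration of all classified cycles).  Outlier time is reported
    separately as a fraction of the total covered time.  A recording whose
    cycles are all outliers yields the zero matrix with ``all_outliers`` set.
    """
    if sym.n_cycles == 0:
        raise ParameterError("empty symbolic recording")
    df = sym.cycles
    dur = (df["t_end_s"] - df["t_in_s"]).to_numpy()
    classified = (~df["outlier"].astype(bool)).to_numpy()
    total_time = float(dur.sum())
    outlier_fraction = float(dur[~classified].sum() / total_time) if total_time else 0.0

    matrix = np.zeros((len(insp_labels), len(exp_labels)))
    ctime = float(dur[classified].sum())
    if ctime == 0.0:
        logger.warning("recording %s: all cycles are outliers", sym.subject_id)
        return RCDistribution(matrix, list(insp_labels), list(exp_labels),
                              sym.subject_id, sym.group, sym.phase,
                              outlier_fraction, all_outliers=True)
    insp_idx = {s: i for i, s in enumerate(insp_labels)}
    exp_idx = {s: j for j, s in enumerate(exp_labels)}
    for li, lj, d, ok in zip(df["insp_symbol"], df["exp_symbol"], dur, classified):
        if ok:
            matrix[insp_idx[str(li)], exp_idx[str(lj)]] += d
    matrix = 100.0 * matrix / ctime
    return RCDistribution(matrix, list(insp_labels), list(exp_labels),
                          sym.subject_id, sym.group, sym.phase, outlier_fraction)


def marginal_profiles(dist: RCDistribution):
    """Inspiration (row-sum) and expiration (column-sum) time profiles.

    Each marginal sums to 100 over a fully classified recording; these are
    the values plotted on the per-phase polar charts.
    """
    return dist.matrix.sum(axis=1), dist.matrix.sum(axis=0)


def _cell_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        logger.debug("constant cell in both groups; p = 1")
        return 1.0
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    # exact null distribution for small samples without ties, tie-corrected
    # normal approximation otherwise
    if max(a.size, b.size) < 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def _cell_pvalue_paired(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)


def compare_groups(group_a: list[RCDistribution], group_b: list[RCDistribution],
                   level: float = 0.05, paired: bool = False) -> TestMap:
    """Cell-wise two-sample comparison of referent-cycle time distributions.

    Per cell, a two-sided Mann-Whitney U test on the per-subject percentages
    (or a Wilcoxon signed-rank test when ``paired``), followed by
    Benjamini-Hochberg adjustment across all cells; a cell is rejected when
    its adjusted p-value is at or below ``level``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ParameterError("each group needs at least 2 subjects")
    ref = group_a[0]
    K1, K2 = ref.matrix.shape
    A = np.stack([d.matrix for d in group_a])
    B = np.stack([d.matrix for d in group_b])
    if A.shape[1:] != (K1, K2) or B.shape[1:] != (K1, K2):
        raise ParameterError("distributions have mismatched shapes")
    if paired and A.shape[0] != B.shape[0]:
        raise ParameterError("paired comparison requires equal group sizes")

    raw = np.ones((K1, K2))
    for i in range(K1):
        for j in range(K2):
            if paired:
                raw[i, j] = _cell_pvalue_paired(A[:, i, j], B[:, i, j])
            else:
                raw[i, j] = _cell_pvalue(A[:, i, j], B[:, i, j])
    _, adj, _, _ = multipletests(raw.ravel(), alpha=level, method="fdr_bh")
    adjusted = adj.reshape(K1, K2)
    rejected = adjusted <= level
    return TestMap(raw, adjusted, rejected, list(ref.insp_labels),
                   list(ref.exp_labels), level)
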