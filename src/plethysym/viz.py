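"""Graphical summaries: referent-cycle map, RC heat maps, polar profiles
and per-subject bar codes.

All renderers are pure functions of their inputs and return matplotlib
figures; the data behind every figure is also available as arrays/frames so
figures can be regenerated or exported as CSV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import matplotlib
import matplotlib.pyplot as plt
import numpy as np

from .analysis import RCDistribution, TestMap, marginal_profiles
from .config import (EXP_PALETTE_5, INSP_PALETTE_5, OUTLIER, OUTLIER_COLOR)
from .errors import ParameterError
from .symbolization import SymbolicRecording

__all__ = ["ReferentCycleExemplar", "find_exemplars", "referent_cycle_map",
           "rc_heatmap", "capped_matrix", "polar_profiles", "barcode",
           "barcode_segments", "insp_palette", "exp_palette"]


def insp_palette(K: int) -> list[str]:
    """Red-to-yellow ramp; darker = shorter mean inspiration."""
    if K == 5:
        return list(INSP_PALETTE_5)
    cmap = matplotlib.colormaps["autumn"]
    return [matplotlib.colors.to_hex(cmap(x)) for x in np.linspace(0, 1, K)]


def exp_palette(K: int) -> list[str]:
    """Blue-to-green ramp; darker = shorter mean expiration."""
    if K == 5:
        return list(EXP_PALETTE_5)
    cmap = matplotlib.colormaps["winter"]
    return [matplotlib.colors.to_hex(cmap(x)) for x in np.linspace(0, 1, K)]


@dataclass
class ReferentCycleExemplar:
    """The training cycle closest (summed DTW) to both of its references."""

    insp_label: str
    exp_label: str
    insp_samples: np.ndarray  # raw airflow, mL/s
    exp_samples: np.ndarray
    fs: float
    total_distance: float

    def flow(self) -> np.ndarray:
        return np.concatenate([self.insp_samples, self.exp_samples])

    def volume(self) -> np.ndarray:
        return np.cumsum(self.flow()) / self.fs


def find_exemplars(insp_labels, exp_labels, insp_dists, exp_dists,
                   insp_phases, exp_phases, fs: float) -> dict:
    """Select, per (letter, digit) class, the cycle with the smallest
    cumulative DTW distance (inspiration + expiration) to its references.

    Inputs are parallel per-cycle lists: assigned labels, distances to the
    assigned reference, and the raw :class:`PhaseSequence` pair.  Cycles
    with an outlier phase are ignored; classes with no member are absent
    from the returned dict.
    """
    n = len(insp_labels)
    if not (n == len(exp_labels) == len(insp_dists) == len(exp_dists)
            == len(insp_phases) == len(exp_phases)):
        raise ParameterError("per-cycle inputs must have equal length")
    best: dict[tuple, ReferentCycleExemplar] = {}
    for k in range(n):
        li, lj = insp_labels[k], exp_labels[k]
        if li == OUTLIER or lj == OUTLIER:
            continue
        total = float(insp_dists[k]) + float(exp_dists[k])
        key = (li, lj)
        if key not in best or total < best[key].total_distance:
            best[key] = ReferentCycleExemplar(
                li, lj, np.asarray(insp_phases[k].samples),
                np.asarray(exp_phases[k].samples), fs, total)
    return best


def referent_cycle_map(exemplars: dict, insp_labels, exp_labels,
                       mode: str = "flow"):
    """K1 x K2 grid of exemplar cycles (rows: inspirations, columns:
    expirations, both in increasing mean-duration order).  Empty classes
    render as annotated blank cells."""
    if mode not in ("flow", "volume"):
        raise ParameterError("mode must be 'flow' or 'volume'")
    K1, K2 = len(insp_labels), len(exp_labels)
    ipal = insp_palette(K1)
    epal = exp_palette(K2)
    fig, axes = plt.subplots(K1, K2, figsize=(2.0 * K2, 1.5 * K1),
                             squeeze=False)
    for (i, li), (j, lj) in itertools.product(enumerate(insp_labels),
                                              enumerate(exp_labels)):
        ax = axes[i][j]
        ax.set_xticks([])
        ax.set_yticks([])
        if i == 0:
            ax.set_title(str(lj), fontsize=9)
        if j == 0:
            ax.set_ylabel(str(li), rotation=0, labelpad=12, fontsize=9)
        ex = exemplars.get((li, lj))
        if ex is None:
            ax.annotate("no cycle", (0.5, 0.5), xycoords="axes fraction",
                        ha="center", va="center", fontsize=7, color="grey")
            continue
        ni = ex.insp_samples.size
        y = ex.flow() if mode == "flow" else ex.volume()
        t = np.arange(y.size) / ex.fs
        ax.plot(t[:ni + 1], y[:ni + 1], color=ipal[i], lw=1.2)
        ax.plot(t[ni:], y[ni:], color=epal[j], lw=1.2)
        ax.axhline(0.0, color="0.8", lw=0.5, zorder=0)
    fig.suptitle(f"Referent cycle map ({mode})")
    fig.tight_layout()
    return fig


def capped_matrix(dists, cap: float = 20.0) -> np.ndarray:
    """Display matrix of one or several RC distributions: subject matrices
    are averaged elementwise first, then truncated at ``cap`` percent."""
    if cap <= 0:
        raise ParameterError("cap must be positive")
    if isinstance(dists, RCDistribution):
        dists = [dists]
    M = np.mean([d.matrix for d in dists], axis=0)
    return np.minimum(M, cap)


def rc_heatmap(dists, cap: float = 20.0, title: str | None = None):
    """Heat map of percent time per referent cycle, display-capped.

    Returns ``(fig, display_matrix)``.
    """
    if isinstance(dists, RCDistribution):
        first = dists
        dists = [dists]
    else:
        first = dists[0]
    M = capped_matrix(dists, cap)
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * M.shape[1], 1.0 + 0.6 * M.shape[0]))
    im = ax.imshow(M, cmap="viridis", vmin=0.0, vmax=cap)
    ax.set_xticks(range(M.shape[1]), [str(s) for s in first.exp_labels])
    ax.set_yticks(range(M.shape[0]), [str(s) for s in first.insp_labels])
    ax.set_xlabel("expiration")
    ax.set_ylabel("inspiration")
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            ax.text(j, i, f"{M[i, j]:.0f}", ha="center", va="center",
                    fontsize=7, color="w")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="% of classified time")
    fig.tight_layout()
    return fig, M


def polar_profiles(dist_pre, dist_post=None, title: str | None = None):
    """Conjoint polar plots of the per-phase time profiles.

    One axis per reference sequence; the pre polygon is drawn in blue and,
    when given, the post polygon in red.
    """
    pre_i, pre_e = marginal_profiles(dist_pre)
    post = marginal_profiles(dist_post) if dist_post is not None else None
    fig, axes = plt.subplots(1, 2, figsize=(8, 4),
                             subplot_kw={"projection": "polar"})
    for ax, vals, labels, which in (
            (axes[0], pre_i, dist_pre.insp_labels, "inspiration"),
            (axes[1], pre_e, dist_pre.exp_labels, "expiration")):
        theta = np.linspace(0, 2 * np.pi, len(vals), endpoint=False)
        closed = np.concatenate([theta, theta[:1]])
        ax.plot(closed, np.concatenate([vals, vals[:1]]), color="tab:blue",
                label="pre")
        if post is not None:
            pvals = post[0] if which == "inspiration" else post[1]
            ax.plot(closed, np.concatenate([pvals, pvals[:1]]),
                    color="tab:red", label="post")
        ax.set_xticks(theta, [str(s) for s in labels])
        ax.set_title(which, fontsize=10)
    axes[1].legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def barcode_segments(sym: SymbolicRecording):
    """Rectangle lists behind the bar-code figure.

    Returns (insp_segments, exp_segments); each segment is
    ``(t_start_s, width_s, symbol)``.  Outlier cycles contribute one
    full-cycle segment per track, so the tracks cover the whole symbolized
    span.
    """
    insp_segments, exp_segments = [], []
    for row in sym.cycles.itertuples():
        if bool(row.outlier) or not np.isfinite(row.t_out_s):
            insp_segments.append((row.t_in_s, row.t_end_s - row.t_in_s, OUTLIER))
            exp_segments.append((row.t_in_s, row.t_end_s - row.t_in_s, OUTLIER))
        else:
            insp_segments.append((row.t_in_s, row.t_out_s - row.t_in_s,
                                  str(row.insp_symbol)))
            exp_segments.append((row.t_out_s, row.t_end_s - row.t_out_s,
                                 str(row.exp_symbol)))
    return insp_segments, exp_segments


def barcode(sym: SymbolicRecording, insp_labels=None, exp_labels=None,
            injection_span_s: tuple | None = None):
    """Two-track timeline of a symbolized recording.

    The upper track shows inspirations, the lower expirations; rectangle
    width is the phase duration, colour the assigned reference, light grey
    an outlier span.  ``injection_span_s`` blanks out the stressor-injection
    interval in white.
    """
    if sym.n_cycles == 0:
        raise ParameterError("empty symbolic recording")
    if insp_labels is None:
        insp_labels = sorted({s for s in sym.cycles["insp_symbol"] if s != OUTLIER})
    if exp_labels is None:
        exp_labels = sorted({s for s in sym.cycles["exp_symbol"] if s != OUTLIER})
    icol = dict(zip(insp_labels, insp_palette(max(len(insp_labels), 1))))
    ecol = dict(zip(exp_labels, exp_palette(max(len(exp_labels), 1))))
    insp_seg, exp_seg = barcode_segments(sym)
    fig, ax = plt.subplots(figsize=(10, 1.6))
    ax.broken_barh([(t, w) for t, w, _ in insp_seg], (1.05, 0.9),
                   facecolors=[icol.get(s, OUTLIER_COLOR) for _, _, s in insp_seg])
    ax.broken_barh([(t, w) for t, w, _ in exp_seg], (0.05, 0.9),
                   facecolors=[ecol.get(s, OUTLIER_COLOR) for _, _, s in exp_seg])
    if injection_span_s is not None:
        ax.axvspan(*injection_span_s, color="white", zorder=3)
    ax.set_yticks([0.5, 1.5], ["exp", "insp"])
    ax.set_xlabel("time (s)")
    ax.set_title(f"{sym.subject_id} ({sym.group}, {sym.phase})", fontsize=9)
    fig.tight_layout()
    return fig


def test_map_figure(tm: TestMap):
    """Render a comparison map: rejected cells black, adjusted p-values
    printed in every cell."""
    K1, K2 = tm.raw_p.shape
    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * K2, 1.0 + 0.7 * K1))
    ax.imshow(tm.rejected.astype(float), cmap="gray_r", vmin=0, vmax=1)
    ax.set_xticks(range(K2), [str(s) for s in tm.exp_labels])
    ax.set_yticks(range(K1), [str(s) for s in tm.insp_labels])
    for i in range(K1):
        for j in range(K2):
            ax.text(j, i, f"{tm.adjusted_p[i, j]:.2f}", ha="center",
                    va="center", fontsize=7,
                    color="w" if tm.rejected[i, j] else "k")
    ax.set_xlabel("expiration")
    ax.set_ylabel("inspiration")
    fig.tight_layout()
    return fig
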