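"""Diagnostic plots: segmentation overlays and confusion matrices."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_segmentation", "plot_confusion", "plot_importance"]


def plot_segmentation(omega_series, intervals, dt, speed_threshold=None, ax=None):
    """Speed statistic with detected movement intervals shaded.

    Outward intervals are shaded differently from returns, mirroring the
    standard segmentation diagnostic.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    t = np.arange(len(omega_series)) * dt
    ax.plot(t, omega_series, lw=0.8, color="k")
    for iv in intervals:
        color = "tab:purple" if iv.role == "outward" else "tab:blue"
        ax.axvspan(iv.start * dt, iv.end * dt, color=color, alpha=0.3)
    if speed_threshold is not None:
        ax.axhline(speed_threshold, ls="--", color="tab:red", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("combined speed (m/s)")
    return ax


def plot_confusion(report, normalized=True, ax=None):
    """Heat map of the (optionally row-normalized) confusion matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    matrix = report.normalized_confusion() if normalized else report.confusion
    im = ax.imshow(matrix.to_numpy(), cmap="Blues", vmin=0)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    plt.colorbar(im, ax=ax)
    return ax


def plot_importance(report, ax=None):
    """Bar chart of OOB permutation importances, ranked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    ranked = report.ranked()
    ax.barh(range(len(ranked)), ranked.to_numpy()[::-1])
    ax.set_yticks(range(len(ranked)), list(ranked.index)[::-1], fontsize=7)
    ax.set_xlabel("summed OOB error increase")
    return ax
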