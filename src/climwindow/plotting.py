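"""Heat-map views of a sliding-window model set.

Both plots draw from the serialized model-set table alone (no refitting),
so figures always agree with the CSV output: a dAICc landscape over
(window end, window start), and confidence-set membership shading with the
C statistic in the legend.  Axes are offsets in days before the adjusted
date, so the cell (end 50, start 100) is the window 50-100 days back.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import c_statistic, confidence_set

__all__ = ["plot_delta", "plot_weights"]


def _frame(modelset) -> pd.DataFrame:
    return modelset.frame if hasattr(modelset, "frame") else modelset


def _grid(frame: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    smin, smax = int(frame.window_end.min()), int(frame.window_start.max())
    size = smax - smin + 1
    z = np.full((size, size), np.nan)  # rows: start, cols: end
    z[frame.window_start.to_numpy() - smin, frame.window_end.to_numpy() - smin] = \
        frame[column].to_numpy(dtype=float)
    offs = np.arange(smin, smax + 1)
    return offs, offs, z


def plot_delta(modelset, ax=None):
    """Lower-triangular dAICc heat map with the best window annotated."""
    import matplotlib.pyplot as plt

    frame = _frame(modelset)
    ends, starts, z = _grid(frame, "delta_aicc")
    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(ends, starts, z, shading="nearest", cmap="viridis")
    ax.figure.colorbar(mesh, ax=ax, label=r"$\Delta$AICc")
    best = frame.loc[frame.delta_aicc.idxmin()]
    ax.plot(best.window_end, best.window_start, "o", mfc="none", mec="red", ms=12,
            label=f"best ({int(best.window_start)}, {int(best.window_end)})")
    ax.set_xlabel("window end (days before reference)")
    ax.set_ylabel("window start (days before reference)")
    ax.legend(loc="lower right")
    return ax


def plot_weights(modelset, levels=(0.95, 0.5, 0.25), ax=None, boxplot_panel: bool = False):
    """Confidence-set membership map; shading = smallest set containing the cell.

    With boxplot_panel=True a second axis summarizes the spread of window
    start/end offsets inside the 95% set.
    """
    import matplotlib.pyplot as plt

    frame = _frame(modelset).copy()
    levels = sorted(levels, reverse=True)
    membership = np.zeros(len(frame))
    for rank, level in enumerate(levels, start=1):
        cs = confidence_set(modelset, level)
        membership[:len(cs)] = rank  # confidence sets are nested prefixes
    frame["membership"] = membership
    ends, starts, z = _grid(frame, "membership")
    axes = None
    if ax is None:
        if boxplot_panel:
            fig, (ax, ax2) = plt.subplots(1, 2, figsize=(10, 4))
            axes = ax2
        else:
            _, ax = plt.subplots()
    cmap = plt.get_cmap("Blues", len(levels) + 1)
    mesh = ax.pcolormesh(ends, starts, z, shading="nearest", cmap=cmap,
                         vmin=-0.5, vmax=len(levels) + 0.5)
    cbar = ax.figure.colorbar(mesh, ax=ax, ticks=range(len(levels) + 1))
    cbar.ax.set_yticklabels(["outside"] + [f"{int(lv * 100)}%" for lv in levels])
    c = c_statistic(modelset, max(levels))
    ax.set_title(f"C = {c:.1f}% of windows in the {int(max(levels) * 100)}% set")
    ax.set_xlabel("window end (days before reference)")
    ax.set_ylabel("window start (days before reference)")
    if boxplot_panel and axes is not None:
        cs = confidence_set(modelset, max(levels))
        axes.boxplot([cs.window_start, cs.window_end], tick_labels=["start", "end"])
        axes.set_ylabel("offset (days before reference)")
        axes.set_title(f"{int(max(levels) * 100)}% set window bounds")
    return ax
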