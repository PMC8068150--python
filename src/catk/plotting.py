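"""Optional figure helpers (raster plot, correlation overlay, bubble map).

All functions draw on a supplied or fresh matplotlib Axes and return it;
callers decide about saving. These are conveniences for inspection, not part
of the numerical contract.
"""
from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .network_analysis import CorrelationResult
from .peak_detection import PeakTrain
from .roi_detection import ROIMap


def raster_plot(trains: Sequence[PeakTrain], ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Event raster: one row per ROI, a tick per super-threshold frame."""
    if ax is None:
        _, ax = plt.subplots()
    for row, train in enumerate(trains):
        frames = np.nonzero(train.pf)[0]
        ax.vlines(frames, row + 0.6, row + 1.4, linewidth=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("ROI")
    ax.set_yticks(range(1, len(trains) + 1), [t.roi_id for t in trains])
    return ax


def correlation_graph(
    rois: ROIMap,
    correlation: CorrelationResult,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """ROI centroids with a line for every super-threshold correlation edge."""
    if ax is None:
        _, ax = plt.subplots()
    centroids = {roi.id: roi.centroid_xy for roi in rois.rois}
    xs = [c[0] for c in centroids.values()]
    ys = [c[1] for c in centroids.values()]
    ax.scatter(xs, ys, s=18, zorder=2)
    for id_a, id_b, r in correlation.edges:
        (xa, ya), (xb, yb) = centroids[id_a], centroids[id_b]
        ax.plot([xa, xb], [ya, yb], linewidth=1.2 * r, alpha=0.7, zorder=1)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.invert_yaxis()
    return ax


def bubble_map(st_table: pd.DataFrame, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Spatio-temporal activity map: dot per ROI, colored by mean active
    time, sized by number of active frames. Inactive ROIs appear hollow."""
    if ax is None:
        _, ax = plt.subplots()
    active = st_table.dropna(subset=["mean_active_s"])
    quiet = st_table[st_table["mean_active_s"].isna()]
    if len(active):
        sc = ax.scatter(
            active["x"], active["y"],
            c=active["mean_active_s"],
            s=12 + 6 * active["n_active_frames"],
            cmap="viridis", zorder=2,
        )
        plt.colorbar(sc, ax=ax, label="mean active time (s)")
    if len(quiet):
        ax.scatter(quiet["x"], quiet["y"], facecolors="none", edgecolors="gray", s=14)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.invert_yaxis()
    return ax
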