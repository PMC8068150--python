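"""Population-level activity analysis.

Pairs of ROIs whose activity is strongly Pearson-correlated (r >= 0.7 by
default) are proposed as functionally connected; population spike statistics
(cumulative spike count, peaks per active cell) summarize culture activity
over time, and the spatio-temporal map attaches timing statistics to ROI
centroids to visualize how activity spreads through a culture.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .peak_detection import PeakTrain
from .roi_detection import ROIMap


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations plus the super-threshold edge list.

    ``basis`` records which signal was correlated: the binary peak trains
    ("pf", the default — correlating detected activity) or the dF/F0 traces
    ("dff").
    """

    matrix: np.ndarray
    edges: List[Tuple[int, int, float]]  # (roi_id_i, roi_id_j, r)
    threshold: float
    basis: str
    roi_ids: List[int]


def correlate_activity(
    signals: Sequence[np.ndarray],
    threshold: float = 0.7,
    basis: str = "pf",
    roi_ids: Optional[Sequence[int]] = None,
) -> CorrelationResult:
    """Pairwise Pearson correlation of per-ROI signals.

    Zero-variance (constant) signals cannot be correlated; their r is
    defined as 0 against everything and they never contribute edges. Edges
    are the unordered pairs with r >= threshold.
    """
    arrays = [np.asarray(s, dtype=np.float64) for s in signals]
    if len(arrays) < 2:
        raise InvalidParameterError("need at least two ROIs to correlate")
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) > 1:
        raise InvalidInputError(f"signals of unequal lengths {sorted(lengths)}")
    if roi_ids is None:
        roi_ids = list(range(1, len(arrays) + 1))
    roi_ids = [int(i) for i in roi_ids]

    data = np.vstack(arrays)
    stds = data.std(axis=1)
    nondegenerate = stds > 0
    R = data.shape[0]
    matrix = np.zeros((R, R), dtype=np.float64)
    idx = np.nonzero(nondegenerate)[0]
    if idx.size >= 2:
        sub = np.corrcoef(data[idx])
        matrix[np.ix_(idx, idx)] = sub
    elif idx.size == 1:
        matrix[idx[0], idx[0]] = 1.0
    if idx.size >= 2:
        # numerical guard: clip into [-1, 1]
        matrix = np.clip(matrix, -1.0, 1.0)

    edges = []
    for i in range(R):
        if not nondegenerate[i]:
            continue
        for j in range(i + 1, R):
            if not nondegenerate[j]:
                continue
            r = matrix[i, j]
            if r >= threshold:
                edges.append((roi_ids[i], roi_ids[j], float(r)))
    return CorrelationResult(
        matrix=matrix, edges=edges, threshold=float(threshold),
        basis=basis, roi_ids=roi_ids,
    )


def cumulative_spike_count(trains: Sequence[PeakTrain], n_frames: Optional[int] = None) -> np.ndarray:
    """Per-frame cumulative number of spike onsets summed over all ROIs."""
    if not trains:
        raise InvalidParameterError("need at least one peak train")
    lengths = {t.pf.shape[0] for t in trains}
    if len(lengths) > 1:
        raise InvalidInputError(f"peak trains of unequal lengths {sorted(lengths)}")
    T = lengths.pop() if n_frames is None else int(n_frames)
    per_frame = np.zeros(T, dtype=np.int64)
    for train in trains:
        for onset in train.events:
            if onset < T:
                per_frame[onset] += 1
    return np.cumsum(per_frame)


def peaks_per_active_cell(
    trains: Sequence[PeakTrain],
    window: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Average peaks per active cell, per frame, over a half-open window.

    An active cell is an ROI with at least one spike onset inside the
    analyzed window. Each frame's value is the fraction of active cells
    whose pf is 1 at that frame (0 everywhere if no cell is active).
    """
    if not trains:
        raise InvalidParameterError("need at least one peak train")
    T = trains[0].pf.shape[0]
    if window is None:
        window = (0, T)
    start, stop = int(window[0]), int(window[1])
    if not 0 <= start < stop <= T:
        raise InvalidParameterError(f"window [{start}, {stop}) invalid for T = {T}")
    active = [t for t in trains if any(start <= e < stop for e in t.events)]
    if not active:
        return np.zeros(stop - start, dtype=np.float64)
    counts = np.zeros(stop - start, dtype=np.float64)
    for train in trains:
        counts += train.pf[start:stop]
    return counts / len(active)


def spatiotemporal_map(
    rois: ROIMap,
    trains: Sequence[PeakTrain],
    rate_hz: float,
) -> pd.DataFrame:
    """Activity-timing table per ROI, anchored at the ROI centroids.

    Columns: roi_id, x, y, first_active_s, mean_active_s, n_active_frames.
    The mean active time is the mean time of all super-threshold frames; a
    culture whose activity sweeps across the field shows a spatial gradient
    in this value. ROIs with no activity carry NaN times (never 0).
    """
    if rate_hz <= 0:
        raise InvalidParameterError("rate_hz must be > 0")
    by_id = {t.roi_id: t for t in trains}
    rows = []
    for roi in sorted(rois.rois, key=lambda r: r.id):
        train = by_id.get(roi.id)
        record = {
            "roi_id": roi.id,
            "x": roi.centroid_xy[0],
            "y": roi.centroid_xy[1],
            "first_active_s": np.nan,
            "mean_active_s": np.nan,
            "n_active_frames": 0,
        }
        if train is not None:
            frames = np.nonzero(train.pf)[0]
            if frames.size:
                record["first_active_s"] = frames[0] / rate_hz
                record["mean_active_s"] = float(frames.mean()) / rate_hz
                record["n_active_frames"] = int(frames.size)
        rows.append(record)
    return pd.DataFrame(
        rows,
        columns=["roi_id", "x", "y", "first_active_s", "mean_active_s", "n_active_frames"],
    )
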