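"""Per-ROI raw traces and their conversion to dF/F0.

The raw trace of an ROI is the per-frame mean intensity over its pixels.
Normalization removes two nuisance levels: the camera/medium background floor
``Fmin`` (estimated from the darkest pixels of the first frame) and the
cell's slowly varying resting fluorescence, tracked by ``Flow[n]`` — the mean
of the lowest q% of the trailing K-frame window. Then::

    F0[n]     = Flow[n] - Fmin
    dF/F0[n]  = (Fraw[n] - F0[n]) / F0[n]

The raw numerator is used as-is (no background subtraction), so the trace of
a resting cell sits at a small constant offset ~ Fmin / F0 rather than at
zero; peak detection operates on deviations and is insensitive to that
offset.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import numpy as np

from .errors import DegenerateBaselineError, InvalidInputError, InvalidParameterError
from .io_frames import FrameStack
from .roi_detection import ROIMap


@dataclass
class RawTrace:
    """Per-frame mean intensity over one ROI's pixels."""

    roi_id: int
    f_raw: np.ndarray


@dataclass
class DFFTrace:
    """Normalized trace with its provenance (Fraw, Flow, F0, Fmin, K, q).

    ``warmup_frames`` marks how many leading frames used a shorter-than-K
    effective window while the trailing buffer filled.
    """

    roi_id: int
    dff: np.ndarray
    f0: np.ndarray
    f_low: np.ndarray
    f_min: float
    f_raw: np.ndarray
    k_window: int
    q_percent: float
    warmup_frames: int


def estimate_background(first_frame: np.ndarray) -> float:
    """Background floor Fmin: mean of the 1% lowest-valued pixels of the
    first frame (at least one pixel)."""
    values = np.asarray(first_frame, dtype=np.float64).ravel()
    if values.size == 0:
        raise InvalidInputError("empty frame")
    n_lowest = max(1, math.floor(0.01 * values.size))
    lowest = np.partition(values, n_lowest - 1)[:n_lowest]
    return float(lowest.mean())


def extract_raw_traces(stack: FrameStack, rois: ROIMap) -> List[RawTrace]:
    """One trace per ROI (ascending id): per-frame mean over the ROI pixels."""
    T, L, W = stack.shape
    if rois.labels.shape != (L, W):
        raise InvalidInputError(
            f"ROI map shape {rois.labels.shape} does not match frames {(L, W)}"
        )
    traces = []
    for roi in sorted(rois.rois, key=lambda r: r.id):
        rows = roi.pixels[:, 0]
        cols = roi.pixels[:, 1]
        traces.append(RawTrace(roi_id=roi.id, f_raw=stack.frames[:, rows, cols].mean(axis=1)))
    return traces


def sliding_low_percentile(f_raw: np.ndarray, k_window: int, q_percent: float) -> np.ndarray:
    """Flow[n]: mean of the lowest q% of the trailing window ending at n.

    The window holds the w = min(n+1, K) most recent samples; the lowest
    max(1, floor(q/100 * w)) of them are averaged. Early frames therefore use
    a shorter effective window until K samples have accumulated.
    """
    T = f_raw.shape[0]
    f_low = np.empty(T, dtype=np.float64)
    for n in range(T):
        w = min(n + 1, k_window)
        m = max(1, math.floor(q_percent / 100.0 * w))
        window = f_raw[n - w + 1 : n + 1]
        f_low[n] = np.partition(window, m - 1)[:m].mean()
    return f_low


def compute_dff(trace: RawTrace, f_min: float, k_window: int, q_percent: float) -> DFFTrace:
    """Convert a raw trace to dF/F0 with a sliding lowest-q% baseline.

    Raises :class:`DegenerateBaselineError` if F0 = Flow - Fmin is <= 0 at
    any frame, which signals an overestimated background floor.
    """
    if k_window < 1:
        raise InvalidParameterError("k_window must be >= 1")
    if not 0 < q_percent < 50:
        raise InvalidParameterError("q_percent must lie in (0, 50)")
    if f_min < 0:
        raise InvalidParameterError("f_min must be >= 0")
    f_raw = np.asarray(trace.f_raw, dtype=np.float64)
    f_low = sliding_low_percentile(f_raw, k_window, q_percent)
    f0 = f_low - f_min
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        raise DegenerateBaselineError(trace.roi_id, int(bad[0]), float(f0[bad[0]]))
    dff = (f_raw - f0) / f0
    return DFFTrace(
        roi_id=trace.roi_id,
        dff=dff,
        f0=f0,
        f_low=f_low,
        f_min=float(f_min),
        f_raw=f_raw,
        k_window=int(k_window),
        q_percent=float(q_percent),
        warmup_frames=min(k_window - 1, f_raw.shape[0]),
    )
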