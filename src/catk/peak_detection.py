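"""Calcium-spike detection with a robust sliding Z-score.

Each frame's dF/F0 sample is compared against the mean and sample standard
deviation of a trailing window of a peak-dampened copy of the trace
(``Fbuff``). During a detected peak, Fbuff is low-pass filtered
(``jin * dff[n] + (1 - jin) * Fbuff[n-1]``) so spikes do not inflate the
local mean/SD estimates; otherwise it simply copies the trace. The standard
deviation is floored at ``1/(10 * th_z)`` so a perfectly flat trace cannot
divide by zero (and cannot fire).

Detection is causal and sequential: the Z-score at frame n uses the Lf
buffered samples strictly before n. The first Lf frames are warm-up and
never fire.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import InvalidParameterError, TraceTooShortError
from .signal_extraction import DFFTrace


@dataclass(frozen=True)
class ZScoreParams:
    """Sliding Z-score parameters: window Lf (frames), threshold ThZ and
    peak-smoothing factor jin in [0, 1]."""

    lf_window: int
    th_z: float
    jin: float

    def __post_init__(self) -> None:
        if self.lf_window < 2:
            raise InvalidParameterError("lf_window must be >= 2 (sample SD needs 2 points)")
        if self.th_z <= 0:
            raise InvalidParameterError("th_z must be > 0 for a finite SD floor 1/(10*th_z)")
        if not 0 <= self.jin <= 1:
            raise InvalidParameterError("jin must lie in [0, 1]")

    @property
    def sd_floor(self) -> float:
        return 1.0 / (10.0 * self.th_z)


@dataclass
class Block:
    """A maximal run of super-threshold frames (both endpoints inclusive)."""

    start_frame: int
    end_frame: int
    duration_s: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class PeakTrain:
    """Detection output for one ROI.

    ``pf`` is the binary peak array; ``z``, ``mu`` and ``sd`` hold, per frame,
    the Z-score and the window statistics it was computed from (NaN during
    warm-up); ``fbuff`` is the peak-dampened buffer; ``events`` are the onset
    frames (rising edges of pf) and ``blocks`` the maximal super-threshold
    runs with durations in seconds.
    """

    roi_id: int
    pf: np.ndarray
    z: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    fbuff: np.ndarray
    events: List[int]
    blocks: List[Block]
    rate_hz: float


def _runs(pf: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of ones as (start, end) inclusive pairs."""
    padded = np.concatenate([[0], pf.astype(np.int8), [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_peaks(
    dff: Union[DFFTrace, np.ndarray],
    params: ZScoreParams,
    rate_hz: float,
    roi_id: Optional[int] = None,
) -> PeakTrain:
    """Run the robust sliding Z-score over one dF/F0 trace.

    Requires T >= Lf + 1 so at least one frame follows the warm-up window.
    """
    if isinstance(dff, DFFTrace):
        x = np.asarray(dff.dff, dtype=np.float64)
        roi_id = dff.roi_id if roi_id is None else roi_id
    else:
        x = np.asarray(dff, dtype=np.float64)
        roi_id = 0 if roi_id is None else roi_id
    if rate_hz <= 0:
        raise InvalidParameterError("rate_hz must be > 0")
    T = x.shape[0]
    lf = params.lf_window
    if T <= lf:
        raise TraceTooShortError(f"trace length {T} <= window Lf = {lf}")

    floor = params.sd_floor
    jin = params.jin
    th_z = params.th_z
    pf = np.zeros(T, dtype=np.uint8)
    z = np.full(T, np.nan)
    mu = np.full(T, np.nan)
    sd = np.full(T, np.nan)
    fbuff = np.empty(T, dtype=np.float64)
    fbuff[:lf] = x[:lf]

    # running sums over the trailing Lf buffered samples; refreshed
    # periodically to keep float drift negligible
    s = float(fbuff[:lf].sum())
    ss = float(np.dot(fbuff[:lf], fbuff[:lf]))
    for n in range(lf, T):
        if (n - lf) % 512 == 511:
            window = fbuff[n - lf : n]
            s = float(window.sum())
            ss = float(np.dot(window, window))
        mean = s / lf
        var = (ss - lf * mean * mean) / (lf - 1)
        sigma = np.sqrt(var) if var > 0 else 0.0
        if sigma < floor:
            sigma = floor
        zn = (x[n] - mean) / sigma
        mu[n] = mean
        sd[n] = sigma
        z[n] = zn
        if zn > th_z:
            pf[n] = 1
            fbuff[n] = jin * x[n] + (1.0 - jin) * fbuff[n - 1]
        else:
            fbuff[n] = x[n]
        old = fbuff[n - lf]
        new = fbuff[n]
        s += new - old
        ss += new * new - old * old

    events = [int(a) for a, _ in _runs(pf)]
    blocks = [Block(a, b, (b - a + 1) / rate_hz) for a, b in _runs(pf)]
    return PeakTrain(
        roi_id=roi_id, pf=pf, z=z, mu=mu, sd=sd, fbuff=fbuff,
        events=events, blocks=blocks, rate_hz=rate_hz,
    )


def block_peaks(train: PeakTrain, rate_hz: Optional[float] = None):
    """Block mode: every maximal run of super-threshold frames with its
    duration, plus the ROI's mean block duration (None if no blocks).

    Measuring whole blocks rather than only spike onsets is what allows the
    duration of calcium elevation to be quantified at slow acquisition rates.
    """
    rate = train.rate_hz if rate_hz is None else rate_hz
    if rate <= 0:
        raise InvalidParameterError("rate_hz must be > 0")
    blocks = [Block(a, b, (b - a + 1) / rate) for a, b in _runs(train.pf)]
    mean_duration = float(np.mean([b.duration_s for b in blocks])) if blocks else None
    return blocks, mean_duration


@dataclass
class DurationSummary:
    """Spike-duration statistics over the ROIs that display spikes."""

    per_roi_mean_s: dict
    mean_s: Optional[float]
    max_s: Optional[float]
    n_active_rois: int


def spike_duration_summary(trains: Sequence[PeakTrain]) -> DurationSummary:
    """Summarize block durations over all ROIs displaying calcium spikes.

    Only ROIs with at least one block contribute. The population mean is the
    mean of the per-ROI mean durations; the maximum is over all individual
    blocks. ROIs without spikes simply do not appear (no error).
    """
    if not trains:
        raise InvalidParameterError("spike_duration_summary needs at least one train")
    per_roi = {}
    max_s = None
    for train in trains:
        blocks, mean_duration = block_peaks(train)
        if not blocks:
            continue
        per_roi[train.roi_id] = mean_duration
        longest = max(b.duration_s for b in blocks)
        max_s = longest if max_s is None else max(max_s, longest)
    mean_s = float(np.mean(list(per_roi.values()))) if per_roi else None
    return DurationSummary(
        per_roi_mean_s=per_roi, mean_s=mean_s, max_s=max_s, n_active_rois=len(per_roi)
    )
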