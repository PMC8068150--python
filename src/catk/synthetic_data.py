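"""Synthetic calcium-imaging movies with known ground truth.

The generator emulates the signal regime the analysis chain targets: somata
as isotropic Gaussian blobs with per-cell resting fluorescence on a nonzero
background floor, calcium transients with a fast linear rise and slow
exponential decay, and additive Gaussian read noise clipped at zero. Every
other module can therefore be tested against planted cell positions, spike
times and true dF/F0 without any downloaded data.

The pixel model for frame n is::

    I[n] = Fmin_bg + sum_c F0_c * (1 + dff_c[n]) * exp(-r_c^2 / (2 sigma^2)) + noise

so at a cell center the peak fluorescence increment of a transient is
``F0_c * amplitude``. The default scene (64 x 64 px, 300 frames at 1 Hz,
7 cells of blob sigma 3 px, resting F0 100 on background 10 — i.e. pixel
SNR ~ 20, an ordinary fluorescence recording) plants transients whose peak
center-pixel increment is five times the pixel noise SD (amplitude 0.25,
noise sigma 5): clearly but not trivially detectable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, PlacementError
from .io_frames import FrameStack
from .peak_detection import PeakTrain
from .roi_detection import ROIMap


@dataclass
class SceneSpec:
    """Scene description for :func:`generate_movie`.

    ``spike_times`` plants explicit per-cell onset frames; when None, onsets
    are drawn per frame at ``spike_rate_per_frame`` with a refractory gap of
    one full transient so planted events never overlap. Events are only
    scheduled from ``schedule_start`` on, leaving a quiescent lead-in during
    which the sliding baseline and Z-score windows warm up.
    """

    width: int = 64
    length: int = 64
    n_frames: int = 300
    rate_hz: float = 1.0
    n_cells: int = 7
    cell_radius_sigma: float = 3.0
    cell_spacing_min: float = 15.0
    resting_f0: float = 100.0
    background_f_min: float = 10.0
    amplitude: float = 0.25
    rise_frames: int = 2
    decay_tau_frames: float = 4.0
    spike_rate_per_frame: float = 0.008
    spike_times: Optional[List[List[int]]] = None
    schedule_start: int = 30
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.length, self.n_frames, self.n_cells) < 1:
            raise InvalidParameterError("width, length, n_frames, n_cells must be >= 1")
        if self.rate_hz <= 0 or self.cell_radius_sigma <= 0:
            raise InvalidParameterError("rate_hz and cell_radius_sigma must be > 0")
        if self.background_f_min >= self.resting_f0:
            raise InvalidParameterError("background_f_min must be below resting_f0")
        if self.background_f_min < 0 or self.noise_sigma < 0:
            raise InvalidParameterError("background and noise must be >= 0")
        if self.amplitude < 0 or self.rise_frames < 1 or self.decay_tau_frames <= 0:
            raise InvalidParameterError("invalid transient kinetics")
        if self.spike_rate_per_frame < 0:
            raise InvalidParameterError("spike_rate_per_frame must be >= 0")
        if self.spike_times is not None and len(self.spike_times) != self.n_cells:
            raise InvalidParameterError("spike_times must list one onset list per cell")

    @property
    def cell_radius_px(self) -> float:
        """Nominal visible cell radius: two blob standard deviations."""
        return 2.0 * self.cell_radius_sigma

    @property
    def refractory_frames(self) -> int:
        """Minimum gap between consecutive onsets: one full transient."""
        return self.rise_frames + math.ceil(4 * self.decay_tau_frames)


@dataclass
class GroundTruth:
    """Planted scene truth: where the cells are and when they fired."""

    centers_xy: np.ndarray  # (n_cells, 2) of (x, y)
    radius_px: float
    spike_onsets: List[List[int]]
    dff_true: np.ndarray  # (n_cells, n_frames)
    f_min: float
    resting_f0: np.ndarray  # (n_cells,)

    def to_cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": np.arange(len(self.centers_xy)),
                "x": self.centers_xy[:, 0],
                "y": self.centers_xy[:, 1],
                "radius_px": self.radius_px,
                "resting_f0": self.resting_f0,
                "n_spikes": [len(s) for s in self.spike_onsets],
            }
        )

    def to_spikes_frame(self) -> pd.DataFrame:
        rows = [
            {"cell": c, "onset_frame": onset}
            for c, onsets in enumerate(self.spike_onsets)
            for onset in onsets
        ]
        return pd.DataFrame(rows, columns=["cell", "onset_frame"])


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Best-candidate (Mitchell) placement with restarts.

    Purely sequential random placement jams well below the packing capacity;
    picking, for each cell, the candidate farthest from the existing cells
    spreads the configuration and reliably reaches the requested count.
    """
    margin = 2.0 * spec.cell_radius_sigma
    if spec.width - 2 * margin <= 0 or spec.length - 2 * margin <= 0:
        raise PlacementError("frame too small for the requested cell size")
    for _restart in range(100):
        centers: List[np.ndarray] = []
        ok = True
        for _ in range(spec.n_cells):
            candidates = np.column_stack(
                [
                    rng.uniform(margin, spec.width - margin, size=64),
                    rng.uniform(margin, spec.length - margin, size=64),
                ]
            )
            if centers:
                existing = np.vstack(centers)
                dists = np.linalg.norm(
                    candidates[:, None, :] - existing[None, :, :], axis=2
                ).min(axis=1)
                best = int(np.argmax(dists))
                if dists[best] < spec.cell_spacing_min:
                    ok = False
                    break
                centers.append(candidates[best])
            else:
                centers.append(candidates[0])
        if ok and len(centers) == spec.n_cells:
            return np.vstack(centers)
    raise PlacementError(
        f"could not place {spec.n_cells} cells at spacing "
        f">= {spec.cell_spacing_min} px in {spec.width}x{spec.length}"
    )


def _draw_onsets(spec: SceneSpec, rng: np.random.Generator) -> List[List[int]]:
    if spec.spike_times is not None:
        for onsets in spec.spike_times:
            for onset in onsets:
                if not 0 <= onset < spec.n_frames:
                    raise InvalidParameterError(f"spike onset {onset} outside [0, {spec.n_frames})")
        return [sorted(int(o) for o in onsets) for onsets in spec.spike_times]
    last_allowed = spec.n_frames - spec.rise_frames - 1
    onsets_per_cell = []
    for _ in range(spec.n_cells):
        onsets: List[int] = []
        n = spec.schedule_start
        while n <= last_allowed:
            if rng.random() < spec.spike_rate_per_frame:
                onsets.append(n)
                n += spec.refractory_frames
            else:
                n += 1
        onsets_per_cell.append(onsets)
    return onsets_per_cell


def _transient_profile(spec: SceneSpec, n_frames: int) -> np.ndarray:
    """Unit-amplitude transient: linear rise then exponential decay."""
    rise = np.arange(1, spec.rise_frames + 1) / spec.rise_frames
    n_decay = min(
        n_frames, math.ceil(spec.decay_tau_frames * math.log(1e3))  # decay to 1e-3
    )
    decay = np.exp(-np.arange(1, n_decay + 1) / spec.decay_tau_frames)
    return np.concatenate([rise, decay])


def generate_movie(spec: SceneSpec) -> tuple:
    """Render a movie and its ground truth; bit-reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    centers = _place_cells(spec, rng)
    onsets = _draw_onsets(spec, rng)

    T = spec.n_frames
    dff_true = np.zeros((spec.n_cells, T), dtype=np.float64)
    profile = spec.amplitude * _transient_profile(spec, T)
    for c, cell_onsets in enumerate(onsets):
        for onset in cell_onsets:
            span = min(profile.shape[0], T - onset)
            dff_true[c, onset : onset + span] += profile[:span]

    ys = np.arange(spec.length, dtype=np.float64)[:, None]
    xs = np.arange(spec.width, dtype=np.float64)[None, :]
    blobs = np.empty((spec.n_cells, spec.length, spec.width), dtype=np.float64)
    for c, (cx, cy) in enumerate(centers):
        blobs[c] = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * spec.cell_radius_sigma**2))

    resting = np.full(spec.n_cells, float(spec.resting_f0))
    # frames = background + sum_c F0_c (1 + dff_c[n]) blob_c + noise, clipped at 0
    gains = resting[None, :] * (1.0 + dff_true.T)  # (T, n_cells)
    movie = spec.background_f_min + np.tensordot(gains, blobs, axes=(1, 0))
    if spec.noise_sigma > 0:
        movie += rng.normal(0.0, spec.noise_sigma, size=movie.shape)
    np.clip(movie, 0.0, None, out=movie)

    stack = FrameStack(
        frames=movie,
        bit_depth=16,
        acquisition_rate_hz=spec.rate_hz,
        frame_range=(0, T),
    )
    truth = GroundTruth(
        centers_xy=centers,
        radius_px=spec.cell_radius_px,
        spike_onsets=onsets,
        dff_true=dff_true,
        f_min=float(spec.background_f_min),
        resting_f0=resting,
    )
    return stack, truth


@dataclass
class DetectionScore:
    """Recall/precision of cells and spikes against the planted truth.

    Undefined ratios (e.g. precision with zero detections) are None.
    """

    cell_recall: Optional[float]
    cell_precision: Optional[float]
    spike_recall: Optional[float]
    spike_precision: Optional[float]
    n_true_cells: int
    n_detected_cells: int
    n_matched_cells: int
    n_true_spikes: int
    n_detected_spikes: int
    n_matched_spikes: int


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def score_detection(
    truth: GroundTruth,
    rois: ROIMap,
    trains: Sequence[PeakTrain],
    spike_tolerance_frames: int = 2,
) -> DetectionScore:
    """Match detections to the planted truth.

    A planted cell is matched (greedily, one-to-one, nearest first) to a
    detected ROI whose centroid lies within one cell radius of its center.
    A planted spike is matched if a detected onset in the matched ROI falls
    within +-``spike_tolerance_frames`` of its onset (one-to-one, nearest
    first). Recall is over all planted cells/spikes; precision over all
    detections.
    """
    centers = truth.centers_xy
    rois_sorted = sorted(rois.rois, key=lambda r: r.id)
    pairs = []
    for ci, center in enumerate(centers):
        for rj, roi in enumerate(rois_sorted):
            d = math.hypot(roi.centroid_xy[0] - center[0], roi.centroid_xy[1] - center[1])
            if d <= truth.radius_px:
                pairs.append((d, ci, rj))
    pairs.sort()
    cell_of_roi: dict = {}
    roi_of_cell: dict = {}
    for _, ci, rj in pairs:
        if ci in roi_of_cell or rj in cell_of_roi:
            continue
        roi_of_cell[ci] = rj
        cell_of_roi[rj] = ci

    trains_by_id = {t.roi_id: t for t in trains}
    n_true_spikes = sum(len(o) for o in truth.spike_onsets)
    n_detected_spikes = sum(len(t.events) for t in trains)
    n_matched_spikes = 0
    for ci, rj in roi_of_cell.items():
        train = trains_by_id.get(rois_sorted[rj].id)
        if train is None:
            continue
        event_pairs = []
        for oi, onset in enumerate(truth.spike_onsets[ci]):
            for ei, event in enumerate(train.events):
                gap = abs(event - onset)
                if gap <= spike_tolerance_frames:
                    event_pairs.append((gap, oi, ei))
        event_pairs.sort()
        used_onsets: set = set()
        used_events: set = set()
        for _, oi, ei in event_pairs:
            if oi in used_onsets or ei in used_events:
                continue
            used_onsets.add(oi)
            used_events.add(ei)
            n_matched_spikes += 1

    return DetectionScore(
        cell_recall=_ratio(len(roi_of_cell), len(centers)),
        cell_precision=_ratio(len(roi_of_cell), len(rois_sorted)),
        spike_recall=_ratio(n_matched_spikes, n_true_spikes),
        spike_precision=_ratio(n_matched_spikes, n_detected_spikes),
        n_true_cells=len(centers),
        n_detected_cells=len(rois_sorted),
        n_matched_cells=len(roi_of_cell),
        n_true_spikes=n_true_spikes,
        n_detected_spikes=n_detected_spikes,
        n_matched_spikes=n_matched_spikes,
    )
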