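"""ROI detection on the averaged, contrast-stretched image.

Somata appear as bright blobs; a difference-of-Gaussians (DoG) band-pass
filter with widths ``sigma_a < sigma_b`` enhances them, pixels whose response
exceeds ``th_dog`` form boundary/body masks, and each 8-connected component —
with its enclosed holes filled — becomes one region of interest (ROI).

With ``sigma_b = 1.6 * sigma_a`` the DoG approximates the Laplacian-of-
Gaussian edge operator, which motivates the default threshold
``th_dog = 0.002 * sigma_b / sigma_a``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import measure

from .errors import InvalidInputError, InvalidParameterError, UnsupportedFormatError
from .params import AnalysisParams


@dataclass(frozen=True)
class DoGParams:
    """Blob-detector parameters: Gaussian widths (px) and response threshold."""

    sigma_a: float
    sigma_b: float
    th_dog: float

    def __post_init__(self) -> None:
        if self.sigma_a <= 0:
            raise InvalidParameterError("sigma_a must be > 0")
        if self.sigma_b <= self.sigma_a:
            raise InvalidParameterError("sigma_b must exceed sigma_a")
        if self.th_dog <= 0:
            raise InvalidParameterError("th_dog must be > 0")

    @property
    def kernel_len(self) -> int:
        """Length of the truncated 1-D kernel at sigma_b: 2*ceil(3*sigma_b)+1."""
        return 2 * math.ceil(3 * self.sigma_b) + 1

    @classmethod
    def from_params(cls, params: AnalysisParams) -> "DoGParams":
        return cls(params.sigma_a, params.sigma_b, params.th_dog)


@dataclass
class ROI:
    """One detected region: a label, its pixels and derived geometry."""

    id: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    centroid_xy: Tuple[float, float]  # (x, y) = (col, row)
    area: int


@dataclass
class ROIMap:
    """Labelled segmentation: 0 = background, k >= 1 = ROI k."""

    labels: np.ndarray
    rois: List[ROI] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "ROIMap":
        labels = np.asarray(labels)
        rois = []
        for label_value in np.unique(labels):
            if label_value == 0:
                continue
            rows, cols = np.nonzero(labels == label_value)
            rois.append(
                ROI(
                    id=int(label_value),
                    pixels=np.column_stack([rows, cols]),
                    centroid_xy=(float(cols.mean()), float(rows.mean())),
                    area=int(rows.size),
                )
            )
        return cls(labels=labels, rois=rois)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Truncated, normalized 1-D Gaussian kernel.

    The kernel extends to +-ceil(3*sigma) offsets (a Gaussian is nearly zero
    beyond three standard deviations), giving an odd length 2*ceil(3*sigma)+1,
    and is renormalized to sum 1 so blurring is mean-preserving.
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    radius = math.ceil(3 * sigma)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    kernel = np.exp(-(x**2) / (2.0 * sigma**2))
    return kernel / kernel.sum()


def _separable_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    # edge-replicated padding ("nearest") so blobs at borders keep support
    kernel = gaussian_kernel(sigma)
    out = ndi.convolve1d(image, kernel, axis=1, mode="nearest")
    return ndi.convolve1d(out, kernel, axis=0, mode="nearest")


def dog_filter(image: np.ndarray, params: DoGParams) -> np.ndarray:
    """Separable difference-of-Gaussians response.

    Two separable blurs (four 1-D convolutions in total) replace the two
    dense 2-D convolutions: ``D = I * G(sigma_a) - I * G(sigma_b)``. The
    image is implicitly padded by edge replication so the response covers
    every pixel, including sides and corners.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InvalidInputError("dog_filter expects a 2-D image")
    return _separable_blur(image, params.sigma_a) - _separable_blur(image, params.sigma_b)


def detect_rois(image: np.ndarray, params: DoGParams, min_area: int = 4) -> ROIMap:
    """Segment ROIs from a [0, 1] image.

    Pixels with DoG response strictly above ``th_dog`` form the boundary
    mask; each 8-connected component is taken with its enclosed holes filled
    (a bright ring around a dimmer soma interior still yields one solid ROI).
    Components with filled area below ``min_area`` are dropped. Labels are
    assigned in raster-scan order of each component's first pixel so output
    is deterministic.
    """
    response = dog_filter(image, params)
    mask = response > params.th_dog
    components = measure.label(mask, connectivity=2)  # 8-connectivity
    out = np.zeros(mask.shape, dtype=np.int32)
    next_id = 1
    # measure.label assigns ids in raster order of first encounter already;
    # iterate in that order and renumber after the area filter.
    for comp_id in range(1, components.max() + 1):
        comp = components == comp_id
        rows, cols = np.nonzero(comp)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        crop = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
        crop[1:-1, 1:-1] = comp[r0:r1, c0:c1]
        filled = ndi.binary_fill_holes(crop)[1:-1, 1:-1]
        if int(filled.sum()) < min_area:
            continue
        target = out[r0:r1, c0:c1]
        target[filled & (target == 0)] = next_id
        next_id += 1
    return ROIMap.from_labels(out)


def suggest_parameters(
    acquisition_rate_hz: float,
    expected_cell_radius_px: float,
    expected_spike_duration_s: float = 20.0,
) -> AnalysisParams:
    """Initial parameter estimates from acquisition rate and cell size.

    ``sigma_a`` tracks the expected soma radius, clamped to the 3-10 px range
    where the band-pass matches typical fluorescence brightness gradients;
    ``sigma_b = 1.6 * sigma_a`` (Laplacian-of-Gaussian regime) and
    ``th_dog = 0.002 * sigma_b / sigma_a``. The baseline window K and the
    Z-score window Lf must contain at least one full calcium transient, so
    both scale with expected spike duration times frame rate — tens of frames
    around 1 Hz, hundreds around 10 Hz. q, th_z and jin default to the
    midpoints of their recommended ranges (15%, 3.0, 0.15).
    """
    if acquisition_rate_hz <= 0 or expected_cell_radius_px <= 0:
        raise InvalidParameterError("rate and radius hints must be > 0")
    if expected_spike_duration_s <= 0:
        raise InvalidParameterError("expected_spike_duration_s must be > 0")
    sigma_a = float(np.clip(expected_cell_radius_px, 3.0, 10.0))
    sigma_b = 1.6 * sigma_a
    th_dog = 0.002 * (sigma_b / sigma_a)
    frames_per_spike = expected_spike_duration_s * acquisition_rate_hz
    window = max(10, math.ceil(1.25 * frames_per_spike))
    return AnalysisParams(
        sigma_a=sigma_a,
        sigma_b=sigma_b,
        th_dog=th_dog,
        k_window=window,
        q_percent=15.0,
        lf_window=window,
        th_z=3.0,
        jin=0.15,
        rate_hz=acquisition_rate_hz,
    )


def load_roi_mask(path, expected_shape: Optional[Tuple[int, int]] = None) -> ROIMap:
    """Load an externally supplied label mask (16-bit TIFF, 0 = background).

    Label values are preserved, so a curated mask keeps its ROI numbering.
    """
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise UnsupportedFormatError(f"ROI mask {path} is not a single 2-D label image")
    if expected_shape is not None and tuple(labels.shape) != tuple(expected_shape):
        raise InvalidParameterError(
            f"ROI mask shape {labels.shape} does not match stack frame shape {expected_shape}"
        )
    return ROIMap.from_labels(labels.astype(np.int32))


def save_roi_mask(roi_map: ROIMap, path) -> None:
    """Write a label mask as 16-bit TIFF (0 = background, k = ROI k)."""
    labels = np.asarray(roi_map.labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise InvalidInputError("more than 65535 ROI labels cannot be stored as 16-bit")
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
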