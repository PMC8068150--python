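"""Loading, averaging and exporting fluorescence movies.

A movie is a multi-page grayscale TIFF stack (8- or 16-bit). Intensities are
promoted to float64 on load; the original integer precision survives only as
``bit_depth`` metadata. Coordinates are 0-based and row-major, the frame index
is 0-based, and frame ranges are half-open ``[first, last)``.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError, InvalidParameterError, UnsupportedFormatError


@dataclass
class FrameStack:
    """T frames of L x W nonnegative intensities plus acquisition metadata.

    ``frames`` has shape (T, L, W): L rows (image length/height) by W columns
    (image width), following the usual row-major image convention.
    """

    frames: np.ndarray
    bit_depth: int
    acquisition_rate_hz: float
    frame_range: Tuple[int, int]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise InvalidInputError(f"frames must be (T, L, W) with T,L,W >= 1, got {self.frames.shape}")
        if np.any(self.frames < 0):
            raise InvalidInputError("intensities must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise UnsupportedFormatError(f"bit depth {self.bit_depth} not supported (8 or 16)")
        if self.acquisition_rate_hz <= 0:
            raise InvalidParameterError("acquisition_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape


def load_tiff_stack(
    path,
    frame_range: Optional[Tuple[int, int]] = None,
    acquisition_rate_hz: float = 1.0,
) -> FrameStack:
    """Load a grayscale multi-page TIFF as a :class:`FrameStack`.

    Parameters
    ----------
    path
        Path to a multi-page TIFF with uniform frame size.
    frame_range
        Optional half-open ``(first, last)`` pair selecting a frame subset,
        e.g. ``(75, 183)`` to analyse only the tail of a recording.
    acquisition_rate_hz
        Frames per second of the recording (TIFF rarely stores this reliably,
        so it is supplied by the caller).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            n_pages = len(tif.pages)
            shapes = {tif.pages[i].shape for i in range(n_pages)}
            dtypes = {np.dtype(tif.pages[i].dtype) for i in range(n_pages)}
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc

    if any(len(s) != 2 for s in shapes):
        raise UnsupportedFormatError(f"{path}: non-grayscale (multi-channel) pages")
    if len(shapes) > 1:
        raise UnsupportedFormatError(f"{path}: pages of mixed sizes {sorted(shapes)}")
    if len(dtypes) > 1:
        raise UnsupportedFormatError(f"{path}: pages of mixed dtypes")
    dtype = dtypes.pop()
    if dtype == np.uint8:
        bit_depth = 8
    elif dtype == np.uint16:
        bit_depth = 16
    else:
        raise UnsupportedFormatError(f"{path}: dtype {dtype} not supported (uint8/uint16)")

    if frame_range is None:
        first, last = 0, n_pages
    else:
        first, last = int(frame_range[0]), int(frame_range[1])
        if not 0 <= first < last <= n_pages:
            raise InvalidParameterError(
                f"frame_range [{first}, {last}) empty or outside [0, {n_pages})"
            )
    data = tifffile.imread(path, key=range(first, last))
    if data.ndim == 2:  # single selected page
        data = data[None, :, :]
    return FrameStack(
        frames=data.astype(np.float64),
        bit_depth=bit_depth,
        acquisition_rate_hz=acquisition_rate_hz,
        frame_range=(first, last),
    )


def save_tiff_stack(stack: FrameStack, path) -> None:
    """Write a stack back to a multi-page grayscale TIFF at its bit depth."""
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    limit = np.iinfo(dtype).max
    data = np.clip(np.rint(stack.frames), 0, limit).astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")


def average_frames(stack: FrameStack) -> np.ndarray:
    """Per-pixel arithmetic mean over frames: the static image used for
    ROI detection."""
    return stack.frames.mean(axis=0)


def contrast_stretch(image: np.ndarray) -> np.ndarray:
    """Affinely map an image onto [0, 1]: (I - min) / (max - min).

    A constant image maps to all zeros (a flat field carries no edges for
    the DoG detector anyway, and this avoids 0/0).
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise InvalidInputError("contrast_stretch requires finite pixel values")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def export_traces_csv(traces: Sequence, peaks: Sequence, path) -> None:
    """Export per-ROI traces and peak trains as a long-format CSV.

    One row per (roi, frame): ``roi_id, frame, f_raw, dff, z_score, peak_flag``.
    ``traces`` are :class:`~catk.signal_extraction.DFFTrace` and ``peaks`` the
    matching :class:`~catk.peak_detection.PeakTrain` objects in the same order.
    An empty ROI set yields a header-only file.
    """
    if len(traces) != len(peaks):
        raise InvalidInputError(f"{len(traces)} traces but {len(peaks)} peak trains")
    lengths = {len(t.dff) for t in traces}
    if len(lengths) > 1:
        raise InvalidInputError(f"ragged traces of lengths {sorted(lengths)}")
    frames_list = []
    for trace, train in zip(traces, peaks):
        if trace.roi_id != train.roi_id:
            raise InvalidInputError(
                f"trace/peak ROI mismatch: {trace.roi_id} vs {train.roi_id}"
            )
        T = len(trace.dff)
        frames_list.append(
            pd.DataFrame(
                {
                    "roi_id": np.full(T, trace.roi_id, dtype=np.int64),
                    "frame": np.arange(T, dtype=np.int64),
                    "f_raw": trace.f_raw,
                    "dff": trace.dff,
                    "z_score": train.z,
                    "peak_flag": train.pf.astype(np.int64),
                }
            )
        )
    columns = ["roi_id", "frame", "f_raw", "dff", "z_score", "peak_flag"]
    if frames_list:
        table = pd.concat(frames_list, ignore_index=True)
    else:
        table = pd.DataFrame(columns=columns)
    table.to_csv(path, index=False, lineterminator="\n")


def read_traces_csv(path) -> pd.DataFrame:
    """Read a trace CSV written by :func:`export_traces_csv`."""
    return pd.read_csv(path)
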