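"""End-to-end analysis: load -> average+stretch -> detect (or load mask) ->
extract -> dF/F0 -> peaks -> network/maps, with CSV outputs and a manifest
that suffices to reproduce the run byte-for-byte.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import CatkError
from .io_frames import FrameStack, average_frames, contrast_stretch, export_traces_csv, load_tiff_stack
from .network_analysis import CorrelationResult, correlate_activity, spatiotemporal_map
from .params import AnalysisParams
from .peak_detection import PeakTrain, ZScoreParams, detect_peaks, spike_duration_summary
from .roi_detection import DoGParams, ROIMap, detect_rois, load_roi_mask, save_roi_mask
from .signal_extraction import DFFTrace, compute_dff, estimate_background, extract_raw_traces


class StageError(CatkError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


@dataclass
class PipelineResult:
    """In-memory results of one analysis run."""

    rois: ROIMap
    f_min: float
    traces: List[DFFTrace]
    trains: List[PeakTrain]
    correlation: Optional[CorrelationResult]
    spatiotemporal: pd.DataFrame
    params: AnalysisParams


def analyze(stack: FrameStack, params: AnalysisParams, roi_map: Optional[ROIMap] = None) -> PipelineResult:
    """Run the full chain on an in-memory stack.

    When ``roi_map`` is supplied (externally curated mask), ROI detection is
    skipped and traces are extracted for the given labels.
    """
    if roi_map is None:
        image = contrast_stretch(average_frames(stack))
        roi_map = detect_rois(image, DoGParams.from_params(params), min_area=params.min_area)
    f_min = estimate_background(stack.frames[0])
    raw_traces = extract_raw_traces(stack, roi_map)
    traces = [compute_dff(t, f_min, params.k_window, params.q_percent) for t in raw_traces]
    zparams = ZScoreParams(params.lf_window, params.th_z, params.jin)
    trains = [detect_peaks(t, zparams, stack.acquisition_rate_hz) for t in traces]
    correlation = None
    if len(trains) >= 2:
        if params.basis == "pf":
            signals = [t.pf.astype(np.float64) for t in trains]
        else:
            signals = [t.dff for t in traces]
        correlation = correlate_activity(
            signals,
            threshold=params.correlation_threshold,
            basis=params.basis,
            roi_ids=[t.roi_id for t in trains],
        )
    st_map = spatiotemporal_map(roi_map, trains, stack.acquisition_rate_hz)
    return PipelineResult(
        rois=roi_map, f_min=f_min, traces=traces, trains=trains,
        correlation=correlation, spatiotemporal=st_map, params=params,
    )


def _write_outputs(result: PipelineResult, out_dir: Path, created: List[Path]) -> None:
    def register(name: str) -> Path:
        path = out_dir / name
        created.append(path)
        return path

    roi_rows = [
        {
            "roi_id": roi.id,
            "centroid_x": roi.centroid_xy[0],
            "centroid_y": roi.centroid_xy[1],
            "area_px": roi.area,
        }
        for roi in sorted(result.rois.rois, key=lambda r: r.id)
    ]
    pd.DataFrame(roi_rows, columns=["roi_id", "centroid_x", "centroid_y", "area_px"]).to_csv(
        register("rois.csv"), index=False, lineterminator="\n"
    )
    save_roi_mask(result.rois, register("roi_mask.tif"))
    export_traces_csv(result.traces, result.trains, register("traces.csv"))

    block_rows = [
        {
            "roi_id": train.roi_id,
            "start_frame": block.start_frame,
            "end_frame": block.end_frame,
            "duration_s": block.duration_s,
        }
        for train in result.trains
        for block in train.blocks
    ]
    pd.DataFrame(block_rows, columns=["roi_id", "start_frame", "end_frame", "duration_s"]).to_csv(
        register("peaks.csv"), index=False, lineterminator="\n"
    )

    if result.correlation is not None:
        ids = result.correlation.roi_ids
        pd.DataFrame(result.correlation.matrix, index=ids, columns=ids).to_csv(
            register("correlation.csv"), index_label="roi_id", lineterminator="\n"
        )
        pd.DataFrame(
            result.correlation.edges, columns=["roi_id_a", "roi_id_b", "r"]
        ).to_csv(register("edges.csv"), index=False, lineterminator="\n")

    result.spatiotemporal.to_csv(register("spatiotemporal.csv"), index=False, lineterminator="\n")


def run_pipeline(
    stack_path,
    params: AnalysisParams,
    out_dir,
    mask_path=None,
    acquisition_rate_hz: Optional[float] = None,
) -> PipelineResult:
    """File-level driver: analyse ``stack_path`` and write all CSV outputs
    plus ``manifest.json`` into ``out_dir``.

    Identical inputs and parameters produce byte-identical outputs. On
    failure the partially written outputs of this run are removed and a
    :class:`StageError` names the failing stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: List[Path] = []
    rate = acquisition_rate_hz if acquisition_rate_hz is not None else params.rate_hz

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            for path in created:
                path.unlink(missing_ok=True)
            raise StageError(name, exc) from exc

    stack = stage("load", load_tiff_stack, stack_path, frame_range=params.frame_range,
                  acquisition_rate_hz=rate)
    roi_map = None
    if mask_path is not None:
        roi_map = stage("load_mask", load_roi_mask, mask_path, stack.frames.shape[1:])
    result = stage("analyze", analyze, stack, params, roi_map)
    stage("export", _write_outputs, result, out_dir, created)

    manifest = {
        "catk_version": __version__,
        "stack_path": str(Path(stack_path).resolve()),
        "mask_path": str(Path(mask_path).resolve()) if mask_path is not None else None,
        "acquisition_rate_hz": rate,
        "params": result.params.to_dict(),
    }
    manifest_path = out_dir / "manifest.json"
    created.append(manifest_path)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return result


def run_from_manifest(manifest_path, out_dir) -> PipelineResult:
    """Replay a run from its manifest (closure: the manifest suffices)."""
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    params = AnalysisParams.from_dict(manifest["params"])
    return run_pipeline(
        manifest["stack_path"],
        params,
        out_dir,
        mask_path=manifest["mask_path"],
        acquisition_rate_hz=manifest["acquisition_rate_hz"],
    )
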