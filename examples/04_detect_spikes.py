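"""Detect calcium spikes with the robust sliding Z-score.

Each dF/F0 sample is compared to the mean/SD of the previous Lf frames of a
peak-dampened buffer; the SD is floored at 1/(10 ThZ). Blocks (maximal runs
of super-threshold frames) measure how long calcium stays elevated.
"""
from catk import (
    AnalysisParams, SceneSpec, analyze, generate_movie, spike_duration_summary,
)

stack, truth = generate_movie(SceneSpec(n_cells=6, seed=42))
result = analyze(stack, AnalysisParams())

for train, onsets in zip(result.trains, truth.spike_onsets):
    print(f"  ROI {train.roi_id}: detected onsets {train.events}")
print(f"planted onsets per cell: {truth.spike_onsets}")

summary = spike_duration_summary(result.trains)
print(f"{summary.n_active_rois} active ROIs, mean spike duration "
      f"{summary.mean_s:.1f} s, max {summary.max_s:.1f} s")
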