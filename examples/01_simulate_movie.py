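"""Render a synthetic calcium-imaging movie with known ground truth.

The scene plants Gaussian-blob somata with resting fluorescence on a nonzero
background, schedules calcium transients (linear rise, exponential decay)
and adds read noise. The printed summary lists what was planted — the
reference against which the analysis chain can be scored.
"""
from catk import SceneSpec, generate_movie

spec = SceneSpec(n_cells=6, seed=42)
stack, truth = generate_movie(spec)

print(f"movie: {stack.n_frames} frames of {stack.shape[2]}x{stack.shape[1]} px "
      f"at {stack.acquisition_rate_hz} Hz")
print(f"background floor: {truth.f_min} fluorescence units")
print(truth.to_cells_frame().to_string(index=False))
print(f"total planted spikes: {sum(len(s) for s in truth.spike_onsets)}")
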