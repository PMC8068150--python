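# Methods

This note documents the models and numerical choices behind `catk`: what
each stage assumes, which parameters matter, what the synthetic generator
does and does not emulate, and the known limitations a user should weigh
before trusting numbers from real recordings.

## ROI detection

The detector assumes somata appear in the time-averaged image as roughly
isotropic bright blobs of radius ~3–10 px on a darker background. The
averaged image is contrast-stretched with the global min/max (a constant
image maps to all zeros — a flat field carries no structure and this avoids
0/0). The DoG response is computed as four 1-D convolutions (row and column
pass per σ) rather than two dense 2-D convolutions; both orderings are
mathematically identical for separable kernels, and the equivalence is
enforced by test against a dense-convolution oracle at 1e-10.

Numerical choices:

- **Kernel truncation.** 1-D kernels extend to ±⌈3σ⌉ (length 2⌈3σ⌉+1) and
  are renormalized to sum 1, keeping blurs mean-preserving despite the
  truncation. Beyond three standard deviations a Gaussian contributes
  ~0.3% of its mass, below any threshold in play here.
- **Border padding** is edge replication. Zero padding would fabricate a
  bright-to-dark step at every border and ring the detector; replication
  leaves a flat (featureless) extension.
- **Threshold and fill.** The mask is `D > Th_DoG` with strict inequality.
  Each 8-connected component is filled (complement flood fill from the
  border), so a bright annulus around a dimmer interior yields one solid
  ROI. Components below `min_area` (default 4 px) are dropped: 1–2 px
  components are noise, not cells. Labels are assigned in raster order of
  each component's first pixel so outputs are reproducible run to run.
- **Parameter heuristics.** `suggest_parameters` clamps σa to [3, 10] px
  from the cell-radius hint, sets σb = 1.6 σa and Th_DoG = 0.002 σb/σa,
  and sizes both sliding windows (K, L_f) as 1.25 × expected spike duration
  × frame rate with a floor of 10 frames; q = 15%, Th_Z = 3.0, j_in = 0.15
  are the midpoints of their recommended ranges. The spike-duration hint
  defaults to 20 s, a typical slow transient in immature cultures.

Known limitation: cells that overlap or touch produce merged ROIs — the
detector finds edges, and merged blobs share one boundary. No declumping is
attempted. Empirically (and enforced by test), blobs whose centers are
≥ 4σb apart never merge at default thresholds.

## Signal extraction

`F_min` estimation assumes the first frame contains a representative sample
of cell-free background. It averages the ⌊1% of pixels⌋ (at least one)
with the lowest values. Two caveats follow directly from the estimator:

- In noisy footage the darkest 1% are the *noise minima* of the background,
  so `F_min` is biased low — with zero-clipped noise it can reach 0. The
  bias shifts ΔF/F0 by a constant and does not move spike detection, which
  responds to deviations, not levels.
- If `F_min` is instead *over*-estimated (dense fields with no clean
  background), `F0 = F_low − F_min` can hit zero; `compute_dff` then raises
  a `DegenerateBaselineError` naming the ROI and frame rather than emitting
  infinities.

The sliding baseline takes, at frame n, the trailing window of the
`w = min(n+1, K)` most recent samples and averages its
`max(1, ⌊q/100·w⌋)` lowest values. During the first K−1 frames the
effective window is shorter (the trace records this as `warmup_frames`);
the alternative — emitting no baseline before frame K — would discard the
opening of short recordings. Selection uses `np.partition`; any algorithm
equivalent to a full sort gives identical values.

The ΔF/F0 numerator uses `F_raw` as recorded, without subtracting `F_min`,
while the denominator's `F0` is background-subtracted. A resting trace
therefore sits at a small constant offset ≈ `F_min/F0` above zero instead
of at zero. The offset is constant per ROI and harmless downstream; the
alternative convention (subtracting `F_min` from the numerator too) would
remove it and rescale amplitudes by `F0/(F0+F_min−F_min_est)`.

Accuracy note: the lowest-q% statistic is biased below the true resting
level by roughly 1.5× the trace noise SD (order statistics of the window),
which inflates measured transient amplitudes by about `1.5σ_noise/A`. For
ROI-averaged traces, where averaging suppresses pixel noise, this is a
few percent; it is the accuracy floor of percentile baselines generally.

## Spike detection

Detection is causal and strictly sequential. At frame n the Z-score uses
the mean and sample SD (divisor L_f − 1) of the L_f buffered samples
`F_buff[n−L_f .. n−1]` — the most recent window that excludes the current
sample. The first L_f frames are warm-up: they never fire and seed the
buffer with the raw trace. A trace must be at least L_f + 1 frames long.

- **SD floor.** `SD_f` is clamped below at `1/(10·Th_Z)`. Besides
  preventing division by zero on flat traces, the floor sets an absolute
  sensitivity limit: with the floor active, a deviation must exceed
  `Th_Z/(10·Th_Z) = 0.1` ΔF/F0 units to fire, whatever the noise. This is
  what keeps the false-positive rate near zero on clean traces; when trace
  noise exceeds the floor, the detector's false-positive rate is set by
  the t-like tails of the window statistics instead (~0.5% of frames at
  Th_Z = 3, which is why thresholds of 5 are common practice for long
  recordings).
- **Peak damping.** During a detected peak the buffer is low-pass filtered
  with factor j_in, so spikes only weakly contaminate the window
  statistics. j_in = 1 disables damping (buffer = trace); j_in = 0 freezes
  the buffer at its pre-peak value for the peak's duration. Sustained
  plateaus lasting a sizable fraction of L_f are nonetheless absorbed
  eventually: the damped samples entering the window raise µ_f and SD_f
  until Z drops below threshold. A 5-frame unit step with L_f = 10,
  Th_Z = 5, j_in = 0.2 fires on exactly its first three frames — block
  durations of long plateaus are underestimates, onsets are exact.
- **Window indexing.** The published recurrence this implements is usually
  written with a window prefactor 1/L_f; the implementation uses exactly
  the L_f samples preceding n so that prefactor and window length agree.
- **Events vs blocks.** An event is the rising edge of the binary peak
  array (the onset frame); a block is a maximal super-threshold run with
  duration `run length / rate`. Block durations are the right statistic at
  slow acquisition (0.1–0.25 Hz), where a "spike" spans several frames and
  its duration, not its count, carries the physiology.

## Network analysis

Pearson correlation is computed on the binary peak trains by default —
after peak detection, "activity" is the train — with a switch to correlate
ΔF/F0 traces instead. Zero-variance signals have no defined correlation;
they are reported as r = 0 against everything (including themselves) and
never form edges. Edges use `r ≥ threshold` (default 0.7) with no
multiple-testing correction: the cutoff is a screening heuristic, not a
significance claim. An "active cell" is an ROI with at least one onset in
the analyzed window; peaks-per-active-cell divides the number of ROIs
super-threshold at a frame by the number of active cells, landing in
[0, 1]. The spatio-temporal map reports, per ROI, the first and mean time
of super-threshold frames; inactive ROIs carry nulls, never zeros.

## Synthetic movies

The generator emulates the signal regime the chain targets, not microscopy
physics. Each frame is

    background + Σ_cells F0_c · (1 + ΔF/F0_true[c, n]) · exp(−r²/2σ²) + noise

with isotropic Gaussian somata, per-cell resting level, linear-rise /
exponential-decay transients, and i.i.d. Gaussian noise clipped at zero.
Defaults (64×64 px, 300 frames at 1 Hz, 7 cells of blob σ 3 px, resting
F0 = 100 on background 10, noise σ = 5, amplitude 0.25, rise 2 frames,
decay τ 4 frames) describe an ordinary recording at pixel SNR 20 whose
transients peak at five times the pixel noise SD. Events follow a
per-frame Bernoulli schedule (rate 0.008) with a one-transient refractory
gap, starting after frame 30 so the sliding windows warm up on quiescent
data. Cell placement uses best-candidate sampling with a minimum spacing
(default 15 px) so planted blobs are individually resolvable; placement
restarts rather than silently dropping cells.

What the generator does **not** emulate — and what passing tests therefore
do not establish for real data: photobleaching and baseline drift, motion,
optical PSF and out-of-focus light, Poisson (signal-dependent) photon
noise, overlapping or non-isotropic cells, neurites, and correlated
background fluctuations. End-to-end recovery numbers from synthetic movies
certify the algorithm chain, not robustness to these artifacts.

`score_detection` matches planted cells to detected ROIs greedily by
centroid distance within one cell radius (one-to-one), then matches spike
onsets within ±2 frames inside matched cells. Recall is over everything
planted; precision over everything detected; undefined ratios (no
detections) are reported as nulls.

## Problem sizes

The test suite and the acceptance script use 64×64 × 300-frame scenes
(twenty seeds for recovery statistics, ten for slow-rate durations),
128×128 images for convolution-oracle checks, and 1000 random traces for
the recurrence-equivalence check; together they certify every numerical
contract in well under two minutes on one core, which keeps the whole
verification loop cheap enough to run on every change.
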