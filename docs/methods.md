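# Methods

## The measurement problem

At a glutamatergic synapse, a single presynaptic action potential releases a
quantum of transmitter with probability `p_r`. Optical quantal analysis
estimates `p_r` by imaging the postsynaptic spine with a high-affinity Ca²⁺
indicator: each released quantum evokes an all-or-none spine Ca²⁺ transient
(EPSCaT), so `p_r` is the proportion of stimulation trials showing a
detected transient. This package implements the complete analysis chain —
line-scan records to ΔF/F traces, traces to all-or-none event calls, calls
to binomial `p_r` estimates — together with a synthetic line-scan generator
that provides ground truth for validating every stage.

## Trace extraction

A line-scan record is a spatial-pixel × line matrix sampled at the line
rate (default 500 lines/s, 200 lines = 400 ms per trial). Raw fluorescence
per line is the unweighted mean over the ROI pixels; normalization follows

    ΔF/F = (F − F_baseline) / (F_baseline − F_background)

with `F_baseline` the mean ROI fluorescence over the pre-stimulus baseline
window (default: scan start to the first stimulus) and `F_background` the
mean over the background ROI across the whole scan (a per-line background
is available via `background_per_line=True`, but the whole-scan mean is
the stabler default). ΔF/F is exactly invariant to detector gain and to
additive offsets that affect all pixels equally — both invariances are
enforced by tests to machine precision.

If `F_baseline ≤ F_background` the normalization is undefined; the trial
is flagged unanalyzable with an explicit error and logged, never silently
dropped. Bleaching detrending (an exponential fitted on the baseline) is
available but off by default; the standard convention applies none.

**Noise term.** Noise is the standard error of the mean of the ΔF/F
samples in the final 50 ms of the baseline window (n = 25 lines at the
default rate). The detection statistic is itself a 50 ms window mean, so
the threshold comparison is a z-like test. Whether the convention should
instead use the sample standard deviation is genuinely ambiguous; the SD
variant is exposed as `noise_stat="sd"`, with SE-of-mean the default.

## Event detection

For each stimulus the transient statistic is the mean ΔF/F over the
half-open window `[stim, stim + 50 ms)` (the line containing the stimulus
instant is included). A trial counts as a successful release event when

    ΔF/F_transient ≥ 2.5 × noise

with the boundary closed ("at least" ⇒ ≥). Raising the multiple can only
ever reduce the success count (a tested monotonicity invariant), and the
rule is scale-free: amplitude changes that keep events well above
threshold leave success probabilities untouched, which is what makes the
estimate robust to postsynaptic manipulations that rescale EPSCaT
amplitude twofold in either direction (also a tested property).

**Calibration.** Because `F_baseline` is estimated from the same baseline
lines, the response-window statistic has variance
`σ²(1/n_resp + 1/n_base)` while the noise SE estimates only `σ/√n_resp`.
With the default 100 ms baseline the effective z of the 2.5× rule is
`2.5/√1.5 ≈ 2.04` and the intrinsic false-positive rate is ≈2.5% (t-like
with 24 df), not Φ(−2.5) ≈ 0.6%. This is a property of the rule as
conventionally stated, not of this implementation; the test suite checks
the empirical rate against an independent Monte-Carlo oracle that
recomputes the statistic from raw noise draws. The practical consequence
is a small upward bias of `p̂_r ≈ (1 − p_r) × 0.025`, largest (~+0.02) at
low `p_r`. Longer baselines shrink it.

**Contamination.** Back-propagating action potentials and dendritic
spikes produce synchronous spine+dendrite transients of similar
amplitude, whereas genuine EPSCaTs are confined to the spine apart from a
small diffusional elevation in the dendrite. A trial is flagged
contaminated when the dendrite transient exceeds its own
`2.5 × noise` threshold. Three policies:

- `off` — no dendrite test;
- `reject_trial` (default) — contaminated trials are excluded from both
  numerator and denominator, with the exclusion itemized in the report;
- `subtract_and_test` — the trial still counts as a success if the spine
  exceeds the dendrite significantly:
  `(spine − dendrite) transient ≥ 2.5 × √(SE_spine² + SE_dendrite²)`.
  The pooled-noise excess test is this package's quantification of the
  qualitative spine-must-exceed-dendrite rule, which is stated in the
  field without a formula.

**Paired pulses.** With two stimuli 70 ms apart, `p_r` is computed from
pulse 1 only; pulse 2 quantifies short-term facilitation. By default the
pulse-2 statistic is taken as-is, riding on any residual pulse-1 decay —
no correction is part of the standard description. With slow indicator
kinetics (τ_decay ≈ 200 ms) that residual is large enough to mis-score
pulse-2 failures on pulse-1 successes, so an optional correction
(`p1_tail_correction="local_baseline"`) re-references the pulse-2 window
to the mean ΔF/F over the 20 ms immediately before the second stimulus
and pools the noise term accordingly
(`SD × √(1/n_resp + 1/n_pre)`). A free-parameter exponential fit to the
≤20 ms inter-pulse segment was considered and rejected: estimating a
~200 ms decay constant from a 20 ms support is ill-conditioned at
realistic shot-noise levels, so extrapolated tails are unstable, while
the local-baseline increment statistic is exactly calibrated (the shared
`F_baseline` term cancels in the increment). Quantitative paired-pulse
ratios should enable this correction; the default is left off to match
the standard description.

## Estimation

`p̂_r = k/N` over analyzable pulse-1 trials, with the binomial standard
error

    SE = √(p̂_r (1 − p̂_r) / N)

zero at `p̂_r ∈ {0, 1}` and maximal at 0.5. Confidence intervals default
to Wilson score (well-behaved at the boundaries); Wald (`p̂ ± z·SE`, the
formula's literal companion) and Clopper–Pearson are options. The trial
planner inverts the SE formula: `required_trials(0.5, 0.1) = 25`,
consistent with the field's 20–30-trial rule of thumb at an SE tolerance
near 0.1. Pre/post-plasticity comparisons report
`Δp_r = p̂_after − p̂_before`, its root-sum-square SE, and a two-proportion
p-value — Fisher's exact test on the 2×2 success table by default
(conservative; a normal-approximation z-test is the option) — plus a
direction label at the configured α. Raw and analyzable trial counts are
always reported together so denominators stay auditable. No
multiple-testing correction is applied in the single-synapse workflow.

## Synthetic line scans

The generator emulates exactly the statistical structure the analysis
assumes, with ground truth recorded per trial:

- **Release**: pulse 1 is Bernoulli at `true_pr`; pulse 2 at
  `min(1, true_pr × facilitation_factor)`, independent of pulse 1. This
  marginal facilitation model is the smallest one producing the
  facilitated second pulse; conditioning pulse-2 release on pulse-1
  failure is out of scope.
- **Waveform**: `A·(exp(−t/τ_decay) − exp(−t/τ_rise))` normalized to peak
  `A`, injected into the spine ROI, with `dendrite_bleed_fraction` of it
  in the dendrite ROI. Defaults τ_rise = 10 ms, τ_decay = 200 ms are
  conventions typical of a high-affinity indicator — no numeric EPSCaT
  kinetics are part of the standard protocol, so these are explicitly
  labeled conventions, not measured values.
- **Amplitude**: lognormal with mean `amplitude_dff` (default 0.5) and
  CV 0.2, keeping amplitudes positive. 0.5 places events ≈13× the noise
  SE of the default optics — comfortably the "well above threshold"
  regime the method requires (an adequately loaded cell shows bAP
  transients of ΔF/F > 0.8; uniquantal EPSCaTs are somewhat smaller).
- **Contamination**: with probability `contamination_rate` per trial an
  equal-amplitude transient is added to spine and dendrite alike at the
  first stimulus (bAPs/dendritic spikes are stimulus-locked). Default 0;
  raised explicitly when studying contamination rejection.
- **Noise**: pixel values are Poisson around the noiseless expectation
  `background_level + baseline_photon_rate · e^(−t/bleach_tau) · (1 + ΔF/F(t))`
  — photomultiplier detection is shot-noise dominated; read noise is
  ignored and Gaussian noise is recovered in the large-count limit.
  Defaults: 50 photons/pixel/line of dye signal, background 5, bleaching
  off (`bleach_tau_s = ∞`).
- **Geometry/timing**: 40-pixel line with spine `[5,12)`, dendrite
  `[16,28)`, background `[30,40)`; 200 lines at 500 Hz; stimuli at 100
  and 170 ms; line `i` maps to time `i/rate` with all windows half-open.

`dendrite_bleed_fraction` defaults to 0.01: diffusion through the spine
neck is strongly restricted, and the published spine-vs-dendrite
contamination rule is only usable if diffusional elevation sits at or
below the dendrite detection threshold — at 0.01 the bleed transient is
≈1.6 dendrite noise SEs, the edge-of-detectability regime the method
presumes. `true_pr` defaults to 0.3, the middle of the basal range
reported with stimulating electrodes placed at a sanitary distance from
the spine (~0.2–0.4); `facilitation_factor` defaults to 1.5.

Reproducibility: each trial's random stream derives from
`(seed, trial_index)` via `numpy` seed sequences, so experiments are
bit-reproducible and any trial can be regenerated in isolation.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: mechanical/focus drift, motion artifacts,
indicator saturation and buffering kinetics, ER/store-driven amplification
(CICR), detector read noise, correlated (non-shot) noise, stimulation
failures of the axon, and multivesicular release. Results on synthetic
data validate the statistical machinery, not the optics of any particular
microscope.

## Numerical conventions and degenerate inputs

- Pixel and line indices 0-based; ROI spans and all time windows
  half-open `[start, stop)`; times in ms from scan start.
- Threshold boundary closed (equality is a success).
- Any non-finite ΔF/F inside an analysis window voids the trial with an
  explicit error; zero baseline noise is a degenerate-noise error (the
  threshold test is undefined).
- Batch detection never aborts on a failing trial: the trial's calls are
  emitted with `success=None` and the reason attached, and a warning is
  logged with the trial id.
- Acquisition metadata is never read from TIFF tags; the sidecar config
  is authoritative. Log output contains no timestamps, so a rerun with
  the same config and seed produces a byte-identical report bundle.

## Known limitations

- The intrinsic ≈2.5% false-positive rate of the 2.5×-noise rule (above)
  biases `p̂_r` upward by ≈`(1−p_r)·0.025`; at `p_r = 0.1` this is ≈+0.02.
  Use longer baselines, or a higher threshold multiple, where small
  `p_r` values must be resolved.
- The uncorrected pulse-2 statistic overstates facilitation whenever
  τ_decay is comparable to the inter-stimulus interval; enable the
  local-baseline correction for quantitative paired-pulse ratios.
- `p_r` here is the probability of *any* release (uni- or multivesicular);
  vesicular release probability and amplitude-based quantal-size analysis
  are out of scope, as is automatic ROI segmentation and frame-scan
  (xy–t) data.

## Problem sizes used in validation

The statistical test suite uses 1,000 replicate 30-trial experiments per
release probability for estimator recovery, 10,000 release-free trials
(against a 200,000-draw oracle) for detection calibration, 200 replicates
per amplitude for the robustness check, 3,000 trials for contamination
metrics, and 5,000 for facilitation; `scripts/acceptance.py` recomputes
the same quantities at moderately smaller sizes (300 replicates, 2,000 to
5,000 trials) chosen to keep a full from-scratch run in the tens of
seconds.
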