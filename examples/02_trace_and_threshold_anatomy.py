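"""Dissect one trial: dF/F normalization and the threshold statistic.

Generates a single trial guaranteed to contain a release event and shows
every intermediate number the detector uses: F_baseline, F_background,
the baseline noise SE, the 50 ms window mean, and the resulting verdict.
"""

from oqa import DetectionConfig, SimParams, call_event, extract_trace, simulate_trial

params = SimParams(true_pr=1.0, amplitude_cv=0.0, seed=7)
record, truth = simulate_trial(params, 0)

spine = extract_trace(record, "spine")
dendrite = extract_trace(record, "dendrite")

print(f"trial {record.trial_id}: {record.n_pixels} pixels x {record.n_lines} lines, "
      f"{record.line_period_ms:.1f} ms/line")
print(f"spine ROI:   F_baseline = {spine.f_baseline:.2f}, F_background = {spine.f_background:.2f}")
print(f"             noise SE (last 50 ms of baseline, n={spine.n_noise_lines}) = {spine.noise_se:.4f}")

call = call_event(spine, dendrite, record.stim_times_ms[0],
                  DetectionConfig(), pulse_index=1,
                  stim_times_ms=record.stim_times_ms)
print(f"pulse 1:     dF/F transient (50 ms window mean) = {call.dff_transient:.3f}")
print(f"             threshold = 2.5 x noise = {call.threshold:.4f}")
print(f"             success = {call.success}  (injected amplitude {truth.amp_p1:.2f} dF/F)")
print(f"dendrite:    transient = {call.dendrite_dff_transient:.4f} "
      f"(vs its threshold {2.5 * call.dendrite_noise_se:.4f}) -> contaminated = {call.contaminated}")
print()
print("The transient sits far above threshold: with a high-affinity dye,")
print("uniquantal events are detected essentially without misses, so the")
print("success/failure tally is a faithful Bernoulli record of release.")
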