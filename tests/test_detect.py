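"""Threshold detection, contamination handling, and the batch driver."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oqa import (
    DegenerateNoiseError,
    DetectionConfig,
    SimParams,
    WindowError,
    call_event,
    call_trials,
    contamination_test,
    extract_trace,
    simulate_experiment,
)

from conftest import build_record


def noisy_record(rng, spine_step=0.0, dendrite_step=0.0, noise=0.05, n_lines=100):
    """Baseline 2 + Gaussian noise; optional post-stimulus steps (in raw F,
    so a step of 1 is a dF/F step of 1)."""
    spine = 2.0 + noise * rng.standard_normal(n_lines)
    dend = 2.0 + noise * rng.standard_normal(n_lines)
    spine[50:] += spine_step
    dend[50:] += dendrite_step
    return build_record(spine, dendrite_values=dend, stim_times_ms=(100.0,))


class TestThresholdRule:
    def test_flat_trace_is_failure(self):
        rng = np.random.default_rng(0)
        rec = noisy_record(rng)
        spine = extract_trace(rec, "spine")
        call = call_event(spine, None, 100.0)
        assert call.success is False
        assert call.dff_transient < call.threshold

    def test_boundary_equality_is_success(self):
        """'At least 2.5 times greater' is a closed boundary: equality counts."""
        rng = np.random.default_rng(1)
        rec = noisy_record(rng)
        spine = extract_trace(rec, "spine")
        # synthesize a trace whose transient exactly equals the threshold
        target = 2.5 * spine.noise_se
        mask = (spine.times_ms >= 100.0) & (spine.times_ms < 150.0)
        spine.values[mask] = target
        call = call_event(spine, None, 100.0)
        assert call.dff_transient == pytest.approx(call.threshold)
        assert call.success is True

    def test_large_transient_is_success(self):
        rng = np.random.default_rng(2)
        rec = noisy_record(rng, spine_step=1.0)
        spine = extract_trace(rec, "spine")
        assert call_event(spine, None, 100.0).success is True

    def test_zero_noise_errors(self, hand_record):
        spine = extract_trace(hand_record, "spine")  # noiseless step record
        assert spine.noise_se == 0.0
        with pytest.raises(DegenerateNoiseError):
            call_event(spine, None, 100.0)

    def test_window_outside_scan_errors(self):
        rng = np.random.default_rng(3)
        rec = noisy_record(rng)
        spine = extract_trace(rec, "spine")
        with pytest.raises(WindowError):
            call_event(spine, None, 190.0)  # [190, 240) beyond the 200 ms scan

    def test_nan_in_window_errors(self):
        rng = np.random.default_rng(4)
        rec = noisy_record(rng)
        spine = extract_trace(rec, "spine")
        spine.values[60] = math.nan
        with pytest.raises(WindowError, match="non-finite"):
            call_event(spine, None, 100.0)

    @settings(derandomize=True, max_examples=20)
    @given(mult=st.floats(min_value=0.5, max_value=10.0))
    def test_threshold_monotonicity(self, mult):
        """Raising the threshold multiple never increases the success count."""
        rng = np.random.default_rng(5)
        recs = [noisy_record(rng, spine_step=s) for s in
                (0.0, 0.05, 0.1, 0.2, 0.5, 1.0)]
        lo = call_trials(recs, DetectionConfig(threshold_multiple=mult,
                                               contamination_policy="off"))
        hi = call_trials(recs, DetectionConfig(threshold_multiple=mult * 1.5,
                                               contamination_policy="off"))
        n_lo = sum(bool(c.success) for c in lo)
        n_hi = sum(bool(c.success) for c in hi)
        assert n_hi <= n_lo

    def test_matches_ground_truth_at_high_snr(self, high_snr_params):
        """At amplitude ~30x noise SE no release event is ever missed; the
        only disagreements with ground truth are the detector's calibrated
        false positives on non-release trials (a few percent)."""
        recs, truth = simulate_experiment(high_snr_params, 100)
        calls = call_trials(recs, DetectionConfig(contamination_policy="off"))
        got = np.array([bool(c.success) for c in calls if c.pulse_index == 1])
        rel = truth.released_p1
        assert got[rel].all()  # zero misses
        assert got[~rel].mean() <= 0.10  # false positives at the ~2.5% base rate


class TestContamination:
    def test_spine_only_event_not_contaminated(self):
        rng = np.random.default_rng(6)
        rec = noisy_record(rng, spine_step=1.0, dendrite_step=0.0)
        spine = extract_trace(rec, "spine")
        dend = extract_trace(rec, "dendrite")
        call = call_event(spine, dend, 100.0, DetectionConfig())
        assert call.contaminated is False
        assert call.success is True

    def test_equal_transients_rejected(self):
        """Synchronous equal-amplitude spine+dendrite events (bAP signature):
        flagged, and excluded under the reject_trial policy."""
        rng = np.random.default_rng(7)
        rec = noisy_record(rng, spine_step=1.0, dendrite_step=1.0)
        spine = extract_trace(rec, "spine")
        dend = extract_trace(rec, "dendrite")
        call = call_event(spine, dend, 100.0, DetectionConfig())
        assert call.contaminated is True
        assert call.success is None

    def test_equal_transients_fail_excess_test(self):
        rng = np.random.default_rng(8)
        rec = noisy_record(rng, spine_step=1.0, dendrite_step=1.0)
        spine = extract_trace(rec, "spine")
        dend = extract_trace(rec, "dendrite")
        cfg = DetectionConfig(contamination_policy="subtract_and_test")
        call = call_event(spine, dend, 100.0, cfg)
        assert call.contaminated is True
        assert call.success is False

    def test_spine_excess_passes_subtract_and_test(self):
        """EPSCaT riding on a bAP: spine far above dendrite still counts."""
        rng = np.random.default_rng(9)
        rec = noisy_record(rng, spine_step=2.0, dendrite_step=1.0)
        spine = extract_trace(rec, "spine")
        dend = extract_trace(rec, "dendrite")
        cfg = DetectionConfig(contamination_policy="subtract_and_test")
        call = call_event(spine, dend, 100.0, cfg)
        assert call.contaminated is True
        assert call.success is True

    def test_pooled_noise_in_excess_rule(self):
        contaminated, ok = contamination_test(
            spine_transient=1.0,
            dendrite_transient=0.5,
            spine_noise_se=0.06,
            dendrite_noise_se=0.08,
            config=DetectionConfig(contamination_policy="subtract_and_test"),
        )
        assert contaminated is True
        assert ok == (0.5 >= 2.5 * math.hypot(0.06, 0.08))

    def test_flags_match_ground_truth(self):
        """Simulated contamination at high SNR is recovered trial by trial."""
        params = SimParams(true_pr=0.3, contamination_rate=0.3,
                           dendrite_bleed_fraction=0.0, seed=11)
        recs, truth = simulate_experiment(params, 200)
        calls = call_trials(recs, DetectionConfig())
        flags = [c.contaminated for c in calls if c.pulse_index == 1]
        assert flags == list(truth.contaminated)


class TestBatchDriver:
    def test_call_count_two_pulses(self, default_params):
        recs, _ = simulate_experiment(default_params, 30)
        calls = call_trials(recs, DetectionConfig())
        assert len(calls) == 60
        assert {c.pulse_index for c in calls} == {1, 2}

    def test_permutation_equivariance(self, default_params):
        """No cross-trial state: permuting trials permutes the calls."""
        recs, _ = simulate_experiment(default_params, 10)
        fwd = call_trials(recs, DetectionConfig())
        rev = call_trials(recs[::-1], DetectionConfig())
        by_id = {(c.trial_id, c.pulse_index): c for c in rev}
        for c in fwd:
            assert by_id[(c.trial_id, c.pulse_index)] == c

    def test_empty_input_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="oqa.detect"):
            assert call_trials([], DetectionConfig()) == []
        assert any("empty" in r.message for r in caplog.records)

    def test_failing_trial_never_aborts_batch(self):
        """A degenerate trial yields error-tagged calls; the rest proceed."""
        rng = np.random.default_rng(12)
        good = noisy_record(rng, spine_step=1.0)
        bad = build_record(np.full(100, 0.5), background_value=1.0,
                           stim_times_ms=(100.0, 170.0), trial_id="bad-1")
        calls = call_trials([good, bad], DetectionConfig())
        bad_calls = [c for c in calls if c.trial_id == "bad-1"]
        assert len(bad_calls) == 2
        assert all(c.success is None and "Normalization" in c.error for c in bad_calls)
        assert any(c.success is True for c in calls if c.trial_id != "bad-1")

    def test_deterministic(self, default_params):
        recs, _ = simulate_experiment(default_params, 10)
        assert call_trials(recs, DetectionConfig()) == call_trials(
            recs, DetectionConfig()
        )
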