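"""Binomial p_r estimation, facilitation, planning, and comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oqa import (
    EstimationError,
    EventCall,
    PrEstimate,
    ProtocolError,
    compare_pr,
    estimate_pr,
    facilitation,
    required_trials,
)


def make_calls(successes, pulse=1, contaminated_at=(), start=0):
    calls = []
    for i, s in enumerate(successes, start=start):
        contam = i in contaminated_at
        calls.append(
            EventCall(
                trial_id=f"t-{i:03d}",
                pulse_index=pulse,
                dff_transient=0.5 if s else 0.0,
                noise_se=0.01,
                threshold=0.025,
                success=None if contam else bool(s),
                contaminated=contam,
            )
        )
    return calls


class TestEstimatePr:
    def test_zero_successes_boundary(self):
        est = estimate_pr(make_calls([0] * 20))
        assert est.pr_hat == 0.0
        assert est.se == 0.0  # SE vanishes at p_r = 0

    def test_direct_evaluation(self):
        est = estimate_pr(make_calls([1] * 15 + [0] * 15))
        assert est.pr_hat == pytest.approx(0.5)
        assert est.se == pytest.approx(math.sqrt(0.25 / 30), abs=1e-9)
        assert est.se == pytest.approx(0.09129, abs=5e-6)

    @settings(derandomize=True, max_examples=40)
    @given(k=st.integers(0, 40), extra=st.integers(1, 40))
    def test_se_formula_and_symmetry(self, k, extra):
        """SE = sqrt(p(1-p)/N) and SE(p) = SE(1-p) on arbitrary counts."""
        n = k + extra
        est = estimate_pr(make_calls([1] * k + [0] * (n - k)))
        mirror = estimate_pr(make_calls([0] * k + [1] * (n - k)))
        p = k / n
        assert est.se == pytest.approx(math.sqrt(p * (1 - p) / n), abs=1e-12)
        assert est.se == pytest.approx(mirror.se, abs=1e-12)

    def test_ordering_invariance(self):
        calls = make_calls([1, 0, 0, 1, 1, 0, 1, 0])
        a = estimate_pr(calls)
        b = estimate_pr(calls[::-1])
        assert (a.pr_hat, a.se, a.ci_low, a.ci_high) == (
            b.pr_hat, b.se, b.ci_low, b.ci_high
        )

    def test_exclusions_itemized(self):
        calls = make_calls([1, 1, 0, 0, 1, 0], contaminated_at={0, 3})
        est = estimate_pr(calls)
        assert est.n_raw == 6
        assert est.n_trials == 4
        assert est.excluded == {"contaminated": 2}
        assert est.pr_hat == pytest.approx(2 / 4)

    def test_pulse2_calls_ignored(self):
        calls = make_calls([1, 0, 1, 0]) + make_calls([1, 1, 1, 1], pulse=2)
        assert estimate_pr(calls).pr_hat == pytest.approx(0.5)

    def test_no_analyzable_trials_errors(self):
        with pytest.raises(EstimationError):
            estimate_pr(make_calls([1, 0], contaminated_at={0, 1}))

    def test_wilson_ci_contains_estimate(self):
        for method in ("wilson", "wald", "clopper-pearson"):
            est = estimate_pr(make_calls([1] * 6 + [0] * 24), ci_method=method)
            assert est.ci_low <= est.pr_hat <= est.ci_high
            assert 0.0 <= est.ci_low and est.ci_high <= 1.0


class TestRequiredTrials:
    @pytest.mark.parametrize(
        "pr,se,expected", [(0.5, 0.1, 25), (0.1, 0.1, 9), (0.5, 1e6, 1)]
    )
    def test_closed_form_inversion(self, pr, se, expected):
        assert required_trials(pr, se) == expected

    @settings(derandomize=True, max_examples=60)
    @given(
        pr=st.floats(0.01, 0.99),
        se=st.floats(0.01, 0.5),
    )
    def test_minimality(self, pr, se):
        """Returned N satisfies the SE bound; N-1 does not (unless N=1)."""
        n = required_trials(pr, se)
        assert math.sqrt(pr * (1 - pr) / n) <= se + 1e-12
        if n > 1:
            assert math.sqrt(pr * (1 - pr) / (n - 1)) > se

    def test_consistent_with_20_30_trial_guidance(self):
        """20-30 trials at p_r near 0.5 corresponds to SE tolerance ~0.09-0.11."""
        assert 20 <= required_trials(0.5, 0.11) <= 30
        assert 20 <= required_trials(0.5, 0.0925) <= 30


class TestFacilitation:
    def test_ratio_of_proportions(self):
        calls = make_calls([1] * 6 + [0] * 14) + make_calls(
            [1] * 12 + [0] * 8, pulse=2
        )
        fac = facilitation(calls)
        assert fac.p1_hat == pytest.approx(0.3)
        assert fac.p2_hat == pytest.approx(0.6)
        assert fac.ppr == pytest.approx(2.0)

    def test_identical_pulses_give_unity(self):
        pattern = [1, 0, 1, 1, 0]
        calls = make_calls(pattern) + make_calls(pattern, pulse=2)
        assert facilitation(calls).ppr == pytest.approx(1.0)

    def test_undefined_at_zero_p1(self):
        calls = make_calls([0] * 5) + make_calls([1] * 5, pulse=2)
        assert math.isnan(facilitation(calls).ppr)

    def test_single_pulse_protocol_errors(self):
        with pytest.raises(ProtocolError):
            facilitation(make_calls([1, 0, 1]))


class TestComparePr:
    def test_identical_inputs_null(self):
        est = estimate_pr(make_calls([1] * 10 + [0] * 20))
        cmp = compare_pr(est, est)
        assert cmp.delta_pr == 0.0
        assert cmp.p_value > 0.05
        assert cmp.direction == "no-change"

    def test_delta_arithmetic(self):
        before = estimate_pr(make_calls([1] * 6 + [0] * 24))
        after = estimate_pr(make_calls([1] * 24 + [0] * 6))
        cmp = compare_pr(before, after)
        assert cmp.delta_pr == pytest.approx(0.6)
        assert cmp.se_delta == pytest.approx(math.hypot(before.se, after.se))
        assert cmp.direction == "potentiation"
        # oracle: Fisher's exact on the same 2x2 table
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[6, 24], [24, 6]])
        assert cmp.p_value == pytest.approx(p)

    def test_depression_direction(self):
        before = estimate_pr(make_calls([1] * 24 + [0] * 6))
        after = estimate_pr(make_calls([1] * 6 + [0] * 24))
        assert compare_pr(before, after).direction == "depression"

    def test_ztest_option(self):
        before = estimate_pr(make_calls([1] * 6 + [0] * 24))
        after = estimate_pr(make_calls([1] * 20 + [0] * 10))
        cmp = compare_pr(before, after, test="ztest")
        assert 0.0 < cmp.p_value < 0.05

    def test_type_i_error_calibration(self):
        """Under the null (equal true p_r) the comparison rejects at ~alpha.

        Oracle: exact binomial enumeration via simulated counts at n=30.
        Fisher's exact is conservative, so the rate must not exceed alpha
        by more than binomial error and will typically sit below it.
        """
        rng = np.random.default_rng(13)
        n_rep, alpha, rejections = 2000, 0.05, 0
        for _ in range(n_rep):
            k1, k2 = rng.binomial(30, 0.4, size=2)
            before = PrEstimate(30, int(k1), k1 / 30,
                                math.sqrt(k1 / 30 * (1 - k1 / 30) / 30), 0, 1)
            after = PrEstimate(30, int(k2), k2 / 30,
                               math.sqrt(k2 / 30 * (1 - k2 / 30) / 30), 0, 1)
            if compare_pr(before, after, alpha=alpha).p_value < alpha:
                rejections += 1
        rate = rejections / n_rep
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_rep)
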