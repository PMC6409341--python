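"""Binomial release-probability estimation, facilitation, and planning.

Release probability p_r is the proportion of analyzable imaging trials in
which the first stimulus evoked a detected EPSCaT.  Under the binomial
model its standard error is

    SE = sqrt(p_r (1 - p_r) / N_trials)

which vanishes at p_r in {0, 1} and peaks at p_r = 0.5 — hence the field's
rule of thumb of 20-30 imaging trials, more when p_r is near 0.5.  With
paired-pulse stimulation, p_r is only ever computed from the first pulse;
the second pulse quantifies short-term facilitation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .detect import EventCall
from .errors import ConfigurationError, EstimationError, ProtocolError

__all__ = [
    "PrEstimate",
    "FacilitationResult",
    "PrComparison",
    "estimate_pr",
    "required_trials",
    "facilitation",
    "compare_pr",
]

CI_METHODS = {"wilson": "wilson", "wald": "normal", "clopper-pearson": "beta"}
COMPARISON_TESTS = ("fisher", "ztest")


def binomial_se(p: float, n: int) -> float:
    """sqrt(p(1-p)/n): the binomial SE of a proportion."""
    return math.sqrt(p * (1.0 - p) / n)


@dataclass
class PrEstimate:
    """Release probability with uncertainty and trial bookkeeping."""

    n_trials: int  # analyzable trials (post-exclusion)
    n_success: int  # successes at pulse 1
    pr_hat: float
    se: float
    ci_low: float
    ci_high: float
    ci_method: str = "wilson"
    ci_level: float = 0.95
    n_raw: int = 0  # trials before exclusion
    excluded: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_success": self.n_success,
            "pr_hat": self.pr_hat,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "n_raw": self.n_raw,
            "excluded": dict(self.excluded),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrEstimate":
        return cls(**d)


@dataclass
class FacilitationResult:
    """Success proportions at the two pulses and their ratio.

    ``ppr`` (paired-pulse ratio of probabilities) is NaN when p1_hat = 0.
    """

    p1_hat: float
    p2_hat: float
    ppr: float
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {
            "p1_hat": self.p1_hat,
            "p2_hat": self.p2_hat,
            "ppr": self.ppr,
            "n1": self.n1,
            "n2": self.n2,
        }


@dataclass
class PrComparison:
    """Pre/post comparison of two release-probability estimates."""

    delta_pr: float
    se_delta: float
    p_value: float
    test: str
    alpha: float
    direction: str  # potentiation | depression | no-change

    def to_dict(self) -> dict:
        return {
            "delta_pr": self.delta_pr,
            "se_delta": self.se_delta,
            "p_value": self.p_value,
            "test": self.test,
            "alpha": self.alpha,
            "direction": self.direction,
        }


def _pulse_calls(calls: Sequence[EventCall], pulse: int) -> List[EventCall]:
    return [c for c in calls if c.pulse_index == pulse]


def _exclusion_reason(call: EventCall) -> str:
    if call.error is not None:
        return "error"
    if call.contaminated:
        return "contaminated"
    return "undefined"


def estimate_pr(
    calls: Sequence[EventCall],
    *,
    ci_method: str = "wilson",
    ci_level: float = 0.95,
) -> PrEstimate:
    """Estimate p_r from pulse-1 event calls.

    Contaminated or errored trials (``success is None``) are excluded from
    both numerator and denominator; the exclusion counts are itemized so
    the denominators stay auditable.  The order of the calls is irrelevant.
    """
    if ci_method not in CI_METHODS:
        raise ConfigurationError(
            f"ci_method must be one of {tuple(CI_METHODS)}, got {ci_method!r}"
        )
    p1 = _pulse_calls(calls, 1)
    analyzable = [c for c in p1 if c.success is not None]
    excluded = Counter(_exclusion_reason(c) for c in p1 if c.success is None)
    if not analyzable:
        raise EstimationError(
            f"no analyzable pulse-1 trials ({len(p1)} raw, "
            f"{sum(excluded.values())} excluded)"
        )
    n = len(analyzable)
    k = sum(bool(c.success) for c in analyzable)
    pr_hat = k / n
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method=CI_METHODS[ci_method])
    return PrEstimate(
        n_trials=n,
        n_success=k,
        pr_hat=pr_hat,
        se=binomial_se(pr_hat, n),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_method=ci_method,
        ci_level=ci_level,
        n_raw=len(p1),
        excluded=dict(excluded),
    )


def required_trials(pr_guess: float, target_se: float) -> int:
    """Smallest N with sqrt(pr(1-pr)/N) <= target_se.

    Inverts the binomial SE formula; the answer is largest near
    pr_guess = 0.5 (e.g. required_trials(0.5, 0.1) = 25, consistent with
    the 20-30-trial rule of thumb at an SE tolerance near 0.1).
    """
    if not (0.0 < pr_guess < 1.0):
        raise ConfigurationError("pr_guess must lie strictly between 0 and 1")
    if target_se <= 0:
        raise ConfigurationError("target_se must be positive")
    n = math.ceil(pr_guess * (1.0 - pr_guess) / target_se**2)
    # guard against float round-off at exact boundaries
    while n > 1 and binomial_se(pr_guess, n - 1) <= target_se:
        n -= 1
    return max(1, n)


def facilitation(calls: Sequence[EventCall]) -> FacilitationResult:
    """Per-pulse success proportions and the paired-pulse probability ratio."""
    p2 = _pulse_calls(calls, 2)
    if not p2:
        raise ProtocolError(
            "facilitation requires paired-pulse data; no pulse-2 calls found"
        )
    a1 = [c for c in _pulse_calls(calls, 1) if c.success is not None]
    a2 = [c for c in p2 if c.success is not None]
    if not a1 or not a2:
        raise EstimationError("no analyzable trials at one of the pulses")
    p1_hat = sum(bool(c.success) for c in a1) / len(a1)
    p2_hat = sum(bool(c.success) for c in a2) / len(a2)
    ppr = p2_hat / p1_hat if p1_hat > 0 else math.nan
    return FacilitationResult(p1_hat=p1_hat, p2_hat=p2_hat, ppr=ppr, n1=len(a1), n2=len(a2))


def compare_pr(
    before: PrEstimate,
    after: PrEstimate,
    *,
    test: str = "fisher",
    alpha: float = 0.05,
) -> PrComparison:
    """Compare p_r across epochs (e.g. baseline vs. 30 min post-induction).

    Reports delta = after - before, its root-sum-square SE, and a
    two-proportion p-value: Fisher's exact test on the 2x2 success table
    (default) or the normal-approximation z-test.
    """
    if test not in COMPARISON_TESTS:
        raise ConfigurationError(
            f"test must be one of {COMPARISON_TESTS}, got {test!r}"
        )
    delta = after.pr_hat - before.pr_hat
    se_delta = math.sqrt(before.se**2 + after.se**2)
    table = [
        [before.n_success, before.n_trials - before.n_success],
        [after.n_success, after.n_trials - after.n_success],
    ]
    if test == "fisher":
        _, p_value = stats.fisher_exact(table)
    else:
        counts = np.array([after.n_success, before.n_success])
        nobs = np.array([after.n_trials, before.n_trials])
        if before.pr_hat == after.pr_hat:
            p_value = 1.0
        else:
            _, p_value = proportions_ztest(counts, nobs)
    if p_value < alpha:
        direction = "potentiation" if delta > 0 else "depression"
    else:
        direction = "no-change"
    return PrComparison(
        delta_pr=float(delta),
        se_delta=float(se_delta),
        p_value=float(p_value),
        test=test,
        alpha=alpha,
        direction=direction,
    )
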