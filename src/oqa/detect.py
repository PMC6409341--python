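"""All-or-none EPSCaT event detection.

A putative transient is quantified as the mean dF/F over a 50 ms window
starting at the point of stimulation (dF/F_transient).  A trial counts as
a successful release event when dF/F_transient is at least 2.5 times the
baseline noise term.  Back-propagating action potentials and dendritic
spikes produce synchronous spine+dendrite Ca2+ signals of similar
amplitude; such trials are recognized by running the same threshold test
on the dendrite trace, and handled according to the configured policy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateNoiseError, OQAError, WindowError
from .linescan import LineScanRecord, Trace, extract_trace

__all__ = ["DetectionConfig", "EventCall", "call_event", "contamination_test", "call_trials"]

logger = logging.getLogger(__name__)

CONTAMINATION_POLICIES = ("off", "reject_trial", "subtract_and_test")
P1_TAIL_CORRECTIONS = ("none", "local_baseline")


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the threshold test.

    Attributes
    ----------
    response_window_ms
        Length of the post-stimulus averaging window (default 50 ms).
    threshold_multiple
        Noise multiplier for a success ("at least 2.5 times greater than
        noise"; the boundary is closed: equality counts).
    contamination_policy
        'off' (no dendrite test), 'reject_trial' (contaminated trials are
        excluded from both numerator and denominator; default) or
        'subtract_and_test' (a contaminated trial may still count as a
        success if the spine-minus-dendrite excess passes a pooled-noise
        threshold test).
    contamination_multiple
        Multiplier for both the dendrite self-test and the excess test.
    p1_tail_correction
        'none' (default: the second-pulse window statistic is taken as-is,
        riding on any residual first-pulse decay) or 'local_baseline'
        (re-reference the second-pulse window to the mean dF/F over the
        ``p2_local_baseline_ms`` immediately preceding it, with the noise
        term pooled over both windows).
    """

    response_window_ms: float = 50.0
    threshold_multiple: float = 2.5
    contamination_policy: str = "reject_trial"
    contamination_multiple: float = 2.5
    p1_tail_correction: str = "none"
    p2_local_baseline_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.response_window_ms <= 0:
            raise ConfigurationError("response_window_ms must be positive")
        if self.threshold_multiple <= 0 or self.contamination_multiple <= 0:
            raise ConfigurationError("threshold multiples must be positive")
        if self.contamination_policy not in CONTAMINATION_POLICIES:
            raise ConfigurationError(
                f"contamination_policy must be one of {CONTAMINATION_POLICIES}, "
                f"got {self.contamination_policy!r}"
            )
        if self.p1_tail_correction not in P1_TAIL_CORRECTIONS:
            raise ConfigurationError(
                f"p1_tail_correction must be one of {P1_TAIL_CORRECTIONS}, "
                f"got {self.p1_tail_correction!r}"
            )
        if self.p2_local_baseline_ms <= 0:
            raise ConfigurationError("p2_local_baseline_ms must be positive")


@dataclass
class EventCall:
    """Per-trial, per-pulse detection verdict and the statistics behind it.

    ``success`` is ``None`` when the verdict is undefined: a contaminated
    trial under the reject_trial policy, or a trial that errored during
    extraction (``error`` then carries the reason).  Such calls are
    excluded from the p_r denominator downstream.
    """

    trial_id: str
    pulse_index: int  # 1-based over stim_times
    dff_transient: float
    noise_se: float
    threshold: float
    success: Optional[bool]
    contaminated: bool
    dendrite_dff_transient: float = math.nan
    dendrite_noise_se: float = math.nan
    error: Optional[str] = None


def contamination_test(
    spine_transient: float,
    dendrite_transient: float,
    spine_noise_se: float,
    dendrite_noise_se: float,
    config: DetectionConfig,
) -> tuple[bool, Optional[bool]]:
    """Dendrite self-test and (optionally) the spine-excess test.

    Returns ``(contaminated, excess_ok)``.  A trial is flagged contaminated
    when the dendrite transient itself exceeds its own noise threshold —
    the signature of a bAP or dendritic spike, which elevates spine and
    dendrite alike.  ``excess_ok`` is only computed under the
    'subtract_and_test' policy: the spine must significantly exceed the
    dendrite, i.e. (spine - dendrite) transient >= contamination_multiple
    x pooled noise, pooled = sqrt(se_spine^2 + se_dendrite^2); otherwise
    it is ``None``.
    """
    contaminated = (
        dendrite_transient >= config.contamination_multiple * dendrite_noise_se
    )
    excess_ok: Optional[bool] = None
    if config.contamination_policy == "subtract_and_test" and contaminated:
        pooled = math.sqrt(spine_noise_se**2 + dendrite_noise_se**2)
        excess_ok = (
            spine_transient - dendrite_transient
            >= config.contamination_multiple * pooled
        )
    return contaminated, excess_ok


def _transient_and_noise(
    trace: Trace,
    stim_time_ms: float,
    pulse_index: int,
    stim_times_ms: Sequence[float],
    config: DetectionConfig,
) -> tuple[float, float]:
    """Window statistic and the noise term it is compared against.

    For pulse 2 under 'local_baseline' correction, the statistic is the
    increment of the response-window mean over the mean of the short
    window immediately before the stimulus, and the noise SE is pooled
    over both windows (sd x sqrt(1/n_resp + 1/n_pre)).
    """
    w = config.response_window_ms
    transient = trace.window_mean(stim_time_ms, stim_time_ms + w)
    noise = trace.noise_se
    if (
        pulse_index >= 2
        and config.p1_tail_correction == "local_baseline"
    ):
        pre_len = min(config.p2_local_baseline_ms, stim_time_ms - stim_times_ms[0])
        if pre_len < trace.line_period_ms:
            raise WindowError(
                f"trial {trace.trial_id}: no room for a local baseline before "
                f"pulse {pulse_index}"
            )
        pre = trace.window_mean(stim_time_ms - pre_len, stim_time_ms)
        n_resp = max(1, int(round(w / trace.line_period_ms)))
        n_pre = max(1, int(round(pre_len / trace.line_period_ms)))
        transient = transient - pre
        noise = trace.noise_sd * math.sqrt(1.0 / n_resp + 1.0 / n_pre)
    return transient, noise


def call_event(
    spine: Trace,
    dendrite: Optional[Trace],
    stim_time_ms: float,
    config: DetectionConfig = DetectionConfig(),
    pulse_index: int = 1,
    stim_times_ms: Optional[Sequence[float]] = None,
) -> EventCall:
    """Classify one pulse of one trial as release success or failure.

    dF/F_transient is the mean dF/F over the half-open response window
    [stim, stim + window); success requires it to be at least
    ``threshold_multiple`` times the baseline noise term, and — when a
    contamination policy is active — the contamination handling to pass.
    """
    if stim_times_ms is None:
        stim_times_ms = (stim_time_ms,)
    if spine.noise_se == 0:
        raise DegenerateNoiseError(
            f"trial {spine.trial_id}: baseline noise is zero; the threshold "
            "test is undefined"
        )
    transient, noise = _transient_and_noise(
        spine, stim_time_ms, pulse_index, stim_times_ms, config
    )
    threshold = config.threshold_multiple * noise
    above = transient >= threshold

    contaminated = False
    success: Optional[bool] = above
    dend_transient = math.nan
    dend_noise = math.nan
    if dendrite is not None and config.contamination_policy != "off":
        dend_transient, dend_noise = _transient_and_noise(
            dendrite, stim_time_ms, pulse_index, stim_times_ms, config
        )
        contaminated, excess_ok = contamination_test(
            transient, dend_transient, noise, dend_noise, config
        )
        if contaminated:
            if config.contamination_policy == "reject_trial":
                success = None
            else:  # subtract_and_test
                success = above and bool(excess_ok)
    elif dendrite is not None:
        dend_transient, _ = _transient_and_noise(
            dendrite, stim_time_ms, pulse_index, stim_times_ms, config
        )
        dend_noise = dendrite.noise_se

    return EventCall(
        trial_id=spine.trial_id,
        pulse_index=pulse_index,
        dff_transient=float(transient),
        noise_se=float(noise),
        threshold=float(threshold),
        success=success,
        contaminated=contaminated,
        dendrite_dff_transient=float(dend_transient),
        dendrite_noise_se=float(dend_noise),
        error=None,
    )


def call_trials(
    records: Sequence[LineScanRecord],
    config: DetectionConfig = DetectionConfig(),
    *,
    noise_stat: str = "se",
    background_per_line: bool = False,
    detrend_bleach: bool = False,
) -> List[EventCall]:
    """Run detection over a batch of records: one call per trial per pulse.

    Per-trial errors (degenerate normalization, bad windows) never abort
    the batch: the affected trial yields calls with ``success=None`` and
    the reason in ``error``, and a warning is logged with the trial id.
    """
    if len(records) == 0:
        logger.warning("call_trials received an empty record list")
        return []
    calls: List[EventCall] = []
    for record in records:
        try:
            spine = extract_trace(
                record,
                "spine",
                noise_stat=noise_stat,
                background_per_line=background_per_line,
                detrend_bleach=detrend_bleach,
            )
            dendrite = extract_trace(
                record,
                "dendrite",
                noise_stat=noise_stat,
                background_per_line=background_per_line,
                detrend_bleach=detrend_bleach,
            )
            for k, stim in enumerate(record.stim_times_ms, start=1):
                calls.append(
                    call_event(
                        spine,
                        dendrite,
                        stim,
                        config,
                        pulse_index=k,
                        stim_times_ms=record.stim_times_ms,
                    )
                )
        except OQAError as exc:
            logger.warning("trial %s excluded: %s", record.trial_id, exc)
            for k in range(1, len(record.stim_times_ms) + 1):
                calls.append(
                    EventCall(
                        trial_id=record.trial_id,
                        pulse_index=k,
                        dff_transient=math.nan,
                        noise_se=math.nan,
                        threshold=math.nan,
                        success=None,
                        contaminated=False,
                        error=f"{type(exc).__name__}: {exc}",
                    )
                )
    return calls
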