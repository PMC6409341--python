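"""Shared fixtures: hand-built records and standard simulator settings."""

import numpy as np
import pytest

from oqa import LineScanRecord, SimParams


def build_record(
    spine_values,
    *,
    background_value=1.0,
    dendrite_values=None,
    line_period_ms=2.0,
    stim_times_ms=(100.0,),
    trial_id="hand-0",
):
    """Hand-built record: 12-pixel line, spine [0,2), dendrite [4,6),
    background [8,12); each ROI spatially constant per line."""
    spine_values = np.asarray(spine_values, dtype=float)
    n_lines = len(spine_values)
    if dendrite_values is None:
        dendrite_values = np.full(n_lines, spine_values[0])
    m = np.full((12, n_lines), float(background_value))
    m[0:2, :] = spine_values
    m[4:6, :] = np.asarray(dendrite_values, dtype=float)
    return LineScanRecord(
        matrix=m,
        line_period_ms=line_period_ms,
        roi_spine=(0, 2),
        roi_dendrite=(4, 6),
        roi_background=(8, 12),
        stim_times_ms=stim_times_ms,
        trial_id=trial_id,
    )


@pytest.fixture
def hand_record():
    """Baseline F=2 for 50 lines (100 ms), then a step to F=3; background 1.

    Direct substitution into the normalization: dF/F = (3-2)/(2-1) = 1
    after the stimulus, 0 before.
    """
    values = np.concatenate([np.full(50, 2.0), np.full(25, 3.0)])
    return build_record(values)


@pytest.fixture
def default_params():
    return SimParams(seed=0)


@pytest.fixture
def high_snr_params():
    """Amplitude far above threshold, no contamination, no bleed."""
    return SimParams(
        true_pr=0.5,
        amplitude_dff=1.0,
        amplitude_cv=0.0,
        dendrite_bleed_fraction=0.0,
        contamination_rate=0.0,
        seed=0,
    )
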