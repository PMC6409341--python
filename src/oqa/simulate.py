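"""Synthetic line-scan generator with known ground truth.

Emulates the statistical structure optical quantal analysis relies on:
stochastic all-or-none spine Ca2+ transients (Bernoulli release at a true
p_r), paired-pulse facilitation at a 70 ms inter-stimulus interval,
transients restricted to the spine ROI apart from a small diffusional
bleed into the dendrite, occasional global spine+dendrite events
(bAP/dendritic-spike contamination), Poisson photon shot noise, and
optional slow exponential bleaching.  Every trial carries a ground-truth
row recording exactly what was injected, so each downstream stage can be
validated without laboratory data.

The generative model per trial:

* pulse 1 releases with probability ``true_pr``; pulse 2 with probability
  ``min(1, true_pr * facilitation_factor)``, independently of pulse 1
  (a marginal facilitation model);
* each release adds ``A * (exp(-t/tau_decay) - exp(-t/tau_rise))``,
  normalized to peak amplitude A (in dF/F units, A lognormal with the
  configured CV), to the spine ROI, and ``dendrite_bleed_fraction`` of it
  to the dendrite ROI;
* a contamination event (probability ``contamination_rate`` per trial,
  injected at the first stimulus) adds an equal-amplitude transient to
  spine and dendrite alike;
* the expected photon count of a dye pixel is
  ``background_level + baseline_photon_rate * exp(-t/bleach_tau) * (1 + dF/F(t))``
  and the observed count is Poisson around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .linescan import LineScanRecord

__all__ = [
    "ROIGeometry",
    "SimParams",
    "GroundTruthRow",
    "SimGroundTruth",
    "simulate_trial",
    "simulate_experiment",
    "epscat_waveform",
    "noiseless_expectation",
]


@dataclass(frozen=True)
class ROIGeometry:
    """Pixel spans (0-based, half-open) for the ROIs along the scanned line."""

    n_pixels: int = 40
    spine: Tuple[int, int] = (5, 12)
    dendrite: Tuple[int, int] = (16, 28)
    background: Tuple[int, int] = (30, 40)


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of one synthetic experiment.

    Defaults encode the standard acquisition protocol (200 lines at
    500 Hz = 400 ms per trial; paired pulses 70 ms apart, the first
    100 ms into the scan) and conventional EPSCaT kinetics for a
    high-affinity indicator (tau_rise 10 ms, tau_decay 200 ms — the
    source protocol states no numeric kinetics, so these are documented
    conventions, not measured values).
    """

    true_pr: float = 0.3
    facilitation_factor: float = 1.5
    isi_ms: float = 70.0
    line_rate_hz: float = 500.0
    n_lines: int = 200
    stim_onset_ms: float = 100.0
    n_pulses: int = 2
    amplitude_dff: float = 0.5
    amplitude_cv: float = 0.2
    tau_rise_ms: float = 10.0
    tau_decay_ms: float = 200.0
    dendrite_bleed_fraction: float = 0.01
    contamination_rate: float = 0.0
    baseline_photon_rate: float = 50.0
    background_level: float = 5.0
    bleach_tau_s: float = math.inf
    roi_geometry: ROIGeometry = field(default_factory=ROIGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.true_pr <= 1.0):
            raise ConfigurationError("true_pr must lie in [0, 1]")
        if self.facilitation_factor < 1.0:
            raise ConfigurationError("facilitation_factor must be >= 1")
        for name in ("isi_ms", "line_rate_hz", "tau_rise_ms", "tau_decay_ms",
                     "amplitude_dff", "baseline_photon_rate", "bleach_tau_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ConfigurationError("tau_rise_ms must be below tau_decay_ms")
        if self.amplitude_cv < 0:
            raise ConfigurationError("amplitude_cv must be non-negative")
        if not (0.0 <= self.dendrite_bleed_fraction <= 1.0):
            raise ConfigurationError("dendrite_bleed_fraction must lie in [0, 1]")
        if not (0.0 <= self.contamination_rate <= 1.0):
            raise ConfigurationError("contamination_rate must lie in [0, 1]")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be non-negative")
        if self.n_lines < 2:
            raise ConfigurationError("n_lines must be at least 2")
        if self.n_pulses not in (1, 2):
            raise ConfigurationError("n_pulses must be 1 or 2")
        if self.stim_onset_ms <= 0:
            raise ConfigurationError("stim_onset_ms must be positive")
        g = self.roi_geometry
        spans = {"spine": g.spine, "dendrite": g.dendrite, "background": g.background}
        covered = np.zeros(g.n_pixels, dtype=int)
        for name, (lo, hi) in spans.items():
            if not (0 <= lo < hi <= g.n_pixels):
                raise ConfigurationError(
                    f"ROI '{name}' span [{lo}, {hi}) invalid for a "
                    f"{g.n_pixels}-pixel line"
                )
            covered[lo:hi] += 1
        if np.any(covered > 1):
            raise ConfigurationError("ROI spans must be disjoint")
        duration = self.n_lines * 1000.0 / self.line_rate_hz
        needed = self.stim_onset_ms + self.isi_ms + 50.0
        if duration < needed:
            raise ConfigurationError(
                f"scan duration {duration:.1f} ms cannot hold both analysis "
                f"windows (needs >= {needed:.1f} ms: stim_onset + isi + 50)"
            )

    @property
    def line_period_ms(self) -> float:
        return 1000.0 / self.line_rate_hz

    @property
    def stim_times_ms(self) -> Tuple[float, ...]:
        if self.n_pulses == 1:
            return (self.stim_onset_ms,)
        return (self.stim_onset_ms, self.stim_onset_ms + self.isi_ms)

    @property
    def p2_release_prob(self) -> float:
        return min(1.0, self.true_pr * self.facilitation_factor)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_geometry"] = asdict(self.roi_geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if isinstance(d.get("roi_geometry"), dict):
            g = dict(d["roi_geometry"])
            for k in ("spine", "dendrite", "background"):
                if k in g:
                    g[k] = tuple(g[k])
            d["roi_geometry"] = ROIGeometry(**g)
        if d.get("bleach_tau_s") in (None, "inf", ".inf"):
            d["bleach_tau_s"] = math.inf
        return cls(**d)


@dataclass
class GroundTruthRow:
    """What was actually injected into one synthetic trial."""

    trial_id: str
    released_p1: bool
    released_p2: bool
    amp_p1: float  # dF/F peak; NaN if no release
    amp_p2: float
    contaminated: bool
    contamination_amp: float
    noise_seed: int


@dataclass
class SimGroundTruth:
    """Validation ledger: one row per generated trial."""

    rows: List[GroundTruthRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    @property
    def released_p1(self) -> np.ndarray:
        return np.array([r.released_p1 for r in self.rows], dtype=bool)

    @property
    def released_p2(self) -> np.ndarray:
        return np.array([r.released_p2 for r in self.rows], dtype=bool)

    @property
    def contaminated(self) -> np.ndarray:
        return np.array([r.contaminated for r in self.rows], dtype=bool)


def epscat_waveform(
    t_ms: np.ndarray, amplitude: float, tau_rise_ms: float, tau_decay_ms: float
) -> np.ndarray:
    """Difference-of-exponentials transient normalized to peak ``amplitude``.

    Zero for t < 0.  The unnormalized kernel exp(-t/tau_d) - exp(-t/tau_r)
    peaks at t* = tau_r tau_d / (tau_d - tau_r) * ln(tau_d / tau_r).
    """
    t = np.asarray(t_ms, dtype=float)
    g = np.where(
        t >= 0,
        np.exp(-np.clip(t, 0, None) / tau_decay_ms)
        - np.exp(-np.clip(t, 0, None) / tau_rise_ms),
        0.0,
    )
    t_peak = (
        tau_rise_ms * tau_decay_ms / (tau_decay_ms - tau_rise_ms)
        * math.log(tau_decay_ms / tau_rise_ms)
    )
    peak = math.exp(-t_peak / tau_decay_ms) - math.exp(-t_peak / tau_rise_ms)
    return amplitude * g / peak


def _draw_amplitude(params: SimParams, rng: np.random.Generator) -> float:
    """Lognormal amplitude with mean ``amplitude_dff`` and the stated CV."""
    if params.amplitude_cv == 0:
        return params.amplitude_dff
    sigma2 = math.log(1.0 + params.amplitude_cv**2)
    mu = math.log(params.amplitude_dff) - sigma2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=math.sqrt(sigma2)))


def noiseless_expectation(
    params: SimParams, truth: GroundTruthRow
) -> np.ndarray:
    """Expected photon-count matrix (pixels x lines) for a given truth row.

    This is the Poisson mean the sampler draws from; exposing it lets the
    generative model's linearity and bleaching be checked directly.
    """
    t = np.arange(params.n_lines) * params.line_period_ms
    dff_spine = np.zeros_like(t)
    dff_dend = np.zeros_like(t)
    stims = params.stim_times_ms
    if truth.released_p1:
        w = epscat_waveform(t - stims[0], truth.amp_p1,
                            params.tau_rise_ms, params.tau_decay_ms)
        dff_spine += w
        dff_dend += params.dendrite_bleed_fraction * w
    if truth.released_p2 and len(stims) > 1:
        w = epscat_waveform(t - stims[1], truth.amp_p2,
                            params.tau_rise_ms, params.tau_decay_ms)
        dff_spine += w
        dff_dend += params.dendrite_bleed_fraction * w
    if truth.contaminated:
        w = epscat_waveform(t - stims[0], truth.contamination_amp,
                            params.tau_rise_ms, params.tau_decay_ms)
        dff_spine += w
        dff_dend += w

    bleach = np.exp(-(t / 1000.0) / params.bleach_tau_s)
    g = params.roi_geometry
    expected = np.full((g.n_pixels, params.n_lines),
                       float(params.background_level))
    rate = params.baseline_photon_rate
    expected[g.spine[0]:g.spine[1], :] += rate * bleach * (1.0 + dff_spine)
    expected[g.dendrite[0]:g.dendrite[1], :] += rate * bleach * (1.0 + dff_dend)
    return expected


def _draw_truth(
    params: SimParams, trial_index: int, rng: np.random.Generator, noise_seed: int
) -> GroundTruthRow:
    released_p1 = bool(rng.random() < params.true_pr)
    released_p2 = bool(
        params.n_pulses == 2 and rng.random() < params.p2_release_prob
    )
    contaminated = bool(rng.random() < params.contamination_rate)
    return GroundTruthRow(
        trial_id=f"trial-{trial_index:04d}",
        released_p1=released_p1,
        released_p2=released_p2,
        amp_p1=_draw_amplitude(params, rng) if released_p1 else math.nan,
        amp_p2=_draw_amplitude(params, rng) if released_p2 else math.nan,
        contaminated=contaminated,
        contamination_amp=_draw_amplitude(params, rng) if contaminated else math.nan,
        noise_seed=noise_seed,
    )


def _trial_seed(params: SimParams, trial_index: int) -> int:
    # deterministic per (seed, trial); independent streams via SeedSequence
    return int(
        np.random.SeedSequence([params.seed, trial_index]).generate_state(1)[0]
    )


def simulate_trial(
    params: SimParams, trial_index: int = 0
) -> Tuple[LineScanRecord, GroundTruthRow]:
    """Generate one synthetic line-scan trial and its ground-truth row.

    Reproducible: the trial's random stream is derived from
    ``(params.seed, trial_index)``, so any trial can be regenerated in
    isolation.
    """
    noise_seed = _trial_seed(params, trial_index)
    rng = np.random.default_rng(noise_seed)
    truth = _draw_truth(params, trial_index, rng, noise_seed)
    expected = noiseless_expectation(params, truth)
    counts = rng.poisson(expected).astype(np.uint16)
    g = params.roi_geometry
    record = LineScanRecord(
        matrix=counts,
        line_period_ms=params.line_period_ms,
        roi_spine=g.spine,
        roi_dendrite=g.dendrite,
        roi_background=g.background,
        stim_times_ms=params.stim_times_ms,
        baseline_window_ms=(0.0, params.stim_onset_ms),
        trial_id=truth.trial_id,
    )
    return record, truth


def simulate_experiment(
    params: SimParams, n_trials: int
) -> Tuple[List[LineScanRecord], SimGroundTruth]:
    """Generate ``n_trials`` independent trials under one parameter set.

    A typical experiment images 20-30 stimulation trials per epoch; large
    n is used for statistical validation of the pipeline itself.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    records: List[LineScanRecord] = []
    truth = SimGroundTruth()
    for i in range(n_trials):
        rec, row = simulate_trial(params, i)
        records.append(rec)
        truth.rows.append(row)
    return records, truth
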