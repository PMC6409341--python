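"""Line-scan records and dF/F trace extraction.

A line scan (xt image) repeatedly samples a single spatial line through a
dendritic spine and its parent dendrite, giving a spatial-pixel x line
matrix at high temporal resolution (typically 500 lines/s).  Fluorescence
in each region of interest (ROI) is converted to a fractional change

    dF/F = (F - F_baseline) / (F_baseline - F_background)

where F is the ROI-mean fluorescence of one line, F_baseline is the mean
ROI fluorescence over the pre-stimulus baseline window, and F_background
is the mean fluorescence of a region devoid of fluorescent structure.
The trace's noise term is the standard error of the mean of the dF/F
samples in the final 50 ms of the baseline window, the quantity the
event-detection threshold is expressed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigurationError,
    DegenerateNormalizationError,
    WindowError,
)

__all__ = ["LineScanRecord", "Trace", "extract_trace", "smooth_trace", "NOISE_WINDOW_MS"]

#: Length (ms) of the terminal baseline segment used for the noise estimate.
NOISE_WINDOW_MS = 50.0

ROI_LABELS = ("spine", "dendrite", "background")


def _check_span(name: str, span: Tuple[int, int], n_pixels: int) -> None:
    lo, hi = int(span[0]), int(span[1])
    if not (0 <= lo < hi <= n_pixels):
        raise ConfigurationError(
            f"ROI '{name}' span [{lo}, {hi}) is empty or outside the "
            f"{n_pixels}-pixel scan line"
        )


@dataclass(eq=False)
class LineScanRecord:
    """One trial's xt fluorescence matrix plus timing and ROI metadata.

    Parameters
    ----------
    matrix
        Non-negative intensity array of shape (n_pixels, n_lines); rows are
        positions along the scanned line, columns are successive lines.
    line_period_ms
        Milliseconds per line (1000 / line rate).
    roi_spine, roi_dendrite, roi_background
        Half-open 0-based pixel spans ``(start, stop)`` along the line.
    stim_times_ms
        One or two stimulus times, ms from scan start, strictly increasing.
    baseline_window_ms
        Half-open ``(start, stop)`` window used for F_baseline.  ``None``
        means "scan start to first stimulus".
    """

    matrix: np.ndarray
    line_period_ms: float
    roi_spine: Tuple[int, int]
    roi_dendrite: Tuple[int, int]
    roi_background: Tuple[int, int]
    stim_times_ms: Tuple[float, ...]
    baseline_window_ms: Optional[Tuple[float, float]] = None
    trial_id: str = "trial-0"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.stim_times_ms = tuple(float(t) for t in self.stim_times_ms)
        self.validate()

    # -- geometry helpers -------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_lines * self.line_period_ms

    @property
    def times_ms(self) -> np.ndarray:
        """Timestamp of each line: line i spans [i, i+1) line periods."""
        return np.arange(self.n_lines) * self.line_period_ms

    def roi_span(self, roi: str) -> Tuple[int, int]:
        try:
            return {
                "spine": self.roi_spine,
                "dendrite": self.roi_dendrite,
                "background": self.roi_background,
            }[roi]
        except KeyError:
            raise ConfigurationError(
                f"unknown ROI {roi!r}; expected one of {ROI_LABELS}"
            ) from None

    def effective_baseline_window(self) -> Tuple[float, float]:
        if self.baseline_window_ms is not None:
            return (float(self.baseline_window_ms[0]), float(self.baseline_window_ms[1]))
        return (0.0, self.stim_times_ms[0])

    def line_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean mask of lines whose timestamps fall in [start, stop)."""
        t = self.times_ms
        return (t >= start_ms) & (t < stop_ms)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.matrix.ndim != 2:
            raise ConfigurationError(
                f"trial {self.trial_id}: matrix must be 2-D (pixels x lines), "
                f"got shape {self.matrix.shape}"
            )
        if np.any(self.matrix < 0):
            raise ConfigurationError(
                f"trial {self.trial_id}: matrix contains negative intensities"
            )
        if self.line_period_ms <= 0:
            raise ConfigurationError("line_period_ms must be positive")
        spans = {
            "spine": self.roi_spine,
            "dendrite": self.roi_dendrite,
            "background": self.roi_background,
        }
        for name, span in spans.items():
            _check_span(name, span, self.n_pixels)
        covered = np.zeros(self.n_pixels, dtype=int)
        for lo, hi in spans.values():
            covered[lo:hi] += 1
        if np.any(covered > 1):
            raise ConfigurationError("ROI spans overlap; they must be disjoint")
        if not (1 <= len(self.stim_times_ms) <= 2):
            raise ConfigurationError("stim_times_ms must hold 1 or 2 stimulus times")
        if len(self.stim_times_ms) == 2 and not (
            self.stim_times_ms[0] < self.stim_times_ms[1]
        ):
            raise ConfigurationError("stim_times_ms must be strictly increasing")
        if self.stim_times_ms[-1] >= self.duration_ms:
            raise ConfigurationError(
                f"last stimulus at {self.stim_times_ms[-1]} ms lies beyond the "
                f"{self.duration_ms:.1f} ms scan"
            )
        b0, b1 = self.effective_baseline_window()
        if not (0 <= b0 < b1 <= self.stim_times_ms[0]):
            raise ConfigurationError(
                f"baseline window [{b0}, {b1}) must be non-empty and end at or "
                f"before the first stimulus ({self.stim_times_ms[0]} ms)"
            )


@dataclass(eq=False)
class Trace:
    """A dF/F time series for one ROI, with the normalization bookkeeping.

    ``noise_se`` is the standard error of the mean of the dF/F samples in
    the last 50 ms of the baseline window (the detection statistic is itself
    a 50 ms window mean, so the threshold test is a z-like comparison);
    ``noise_sd`` is the sample standard deviation of the same samples,
    selectable as the noise term via ``noise_stat='sd'``.
    """

    values: np.ndarray
    times_ms: np.ndarray
    roi_label: str
    f_baseline: float
    f_background: float
    noise_se: float
    noise_sd: float
    n_noise_lines: int
    line_period_ms: float
    trial_id: str = "trial-0"

    @property
    def n_lines(self) -> int:
        return len(self.values)

    def window_mean(self, start_ms: float, stop_ms: float) -> float:
        """Mean dF/F over lines with timestamps in [start, stop)."""
        if start_ms < 0 or stop_ms > self.n_lines * self.line_period_ms:
            raise WindowError(
                f"trial {self.trial_id}: window [{start_ms}, {stop_ms}) ms "
                f"exceeds the {self.n_lines * self.line_period_ms:.1f} ms scan"
            )
        mask = (self.times_ms >= start_ms) & (self.times_ms < stop_ms)
        if not mask.any():
            raise WindowError(
                f"trial {self.trial_id}: window [{start_ms}, {stop_ms}) ms "
                "contains no scan lines"
            )
        vals = self.values[mask]
        if not np.all(np.isfinite(vals)):
            raise WindowError(
                f"trial {self.trial_id}: non-finite dF/F inside window "
                f"[{start_ms}, {stop_ms}) ms"
            )
        return float(vals.mean())


def _fit_baseline_bleach(f: np.ndarray, t_ms: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Log-linear exponential trend fitted on baseline lines, normalized to 1 at t=0."""
    fb = f[mask]
    if np.any(fb <= 0):
        return np.ones_like(f)
    coef = np.polyfit(t_ms[mask], np.log(fb), 1)
    trend = np.exp(coef[0] * t_ms)  # intercept absorbed by normalization below
    return trend / trend[0]


def extract_trace(
    record: LineScanRecord,
    roi: str,
    *,
    noise_stat: str = "se",
    background_per_line: bool = False,
    detrend_bleach: bool = False,
) -> Trace:
    """Convert one ROI of a line-scan record to a dF/F trace.

    Per line, raw F is the unweighted mean intensity over the ROI pixels.
    F_background is the mean over the background ROI (whole scan by default;
    per-line with ``background_per_line=True``).  F_baseline is the mean of
    raw F over the baseline window.  Then
    ``dF/F = (F - F_baseline) / (F_baseline - F_background)``.

    ``detrend_bleach`` optionally divides raw F by an exponential trend
    fitted to the baseline lines before normalization (off by default; the
    standard convention applies no detrending).

    Raises
    ------
    DegenerateNormalizationError
        If F_baseline <= F_background (trial flagged unanalyzable).
    ConfigurationError
        If the baseline window is shorter than the 50 ms noise window.
    """
    if roi == "background":
        raise ConfigurationError("extract_trace targets 'spine' or 'dendrite'")
    lo, hi = record.roi_span(roi)
    t = record.times_ms
    f = record.matrix[lo:hi, :].astype(float).mean(axis=0)

    blo, bhi = record.roi_span("background")
    if background_per_line:
        f_background = record.matrix[blo:bhi, :].astype(float).mean(axis=0)
    else:
        f_background = float(record.matrix[blo:bhi, :].mean())

    b0, b1 = record.effective_baseline_window()
    if (b1 - b0) < NOISE_WINDOW_MS:
        raise ConfigurationError(
            f"trial {record.trial_id}: baseline window [{b0}, {b1}) ms is "
            f"shorter than the {NOISE_WINDOW_MS:.0f} ms noise window; "
            "stimulation must follow at least 50 ms of baseline imaging"
        )
    base_mask = record.line_mask(b0, b1)
    if detrend_bleach:
        f = f / _fit_baseline_bleach(f, t, base_mask)

    f_baseline = float(f[base_mask].mean())
    fbg_scalar = float(np.mean(f_background))
    if f_baseline <= fbg_scalar:
        raise DegenerateNormalizationError(
            f"trial {record.trial_id}, ROI {roi!r}: F_baseline ({f_baseline:.3g}) "
            f"<= F_background ({fbg_scalar:.3g}); normalization undefined, "
            "trial flagged unanalyzable"
        )

    dff = (f - f_baseline) / (f_baseline - f_background)

    noise_mask = record.line_mask(b1 - NOISE_WINDOW_MS, b1)
    noise_samples = dff[noise_mask]
    n_noise = int(noise_mask.sum())
    noise_sd = float(noise_samples.std(ddof=1)) if n_noise > 1 else 0.0
    noise_se = noise_sd / np.sqrt(n_noise) if n_noise > 0 else 0.0

    if noise_stat == "se":
        pass
    elif noise_stat == "sd":
        noise_se, noise_sd = noise_sd, noise_sd
    else:
        raise ConfigurationError(f"noise_stat must be 'se' or 'sd', got {noise_stat!r}")

    return Trace(
        values=dff,
        times_ms=t,
        roi_label=roi,
        f_baseline=f_baseline,
        f_background=fbg_scalar,
        noise_se=float(noise_se),
        noise_sd=float(noise_sd),
        n_noise_lines=n_noise,
        line_period_ms=record.line_period_ms,
        trial_id=record.trial_id,
    )


def smooth_trace(trace: Trace, method: str = "boxcar", width_ms: float = 10.0) -> Trace:
    """Return a smoothed copy of a trace, for display only.

    Event detection consumes the raw dF/F trace; smoothing exists purely to
    render figures the way published transients are shown.  ``width_ms`` is
    the boxcar length or, for ``method='gaussian'``, the FWHM of the kernel.
    """
    if width_ms < trace.line_period_ms:
        raise ConfigurationError(
            f"smoothing width {width_ms} ms is below one line period "
            f"({trace.line_period_ms} ms)"
        )
    n = max(1, int(round(width_ms / trace.line_period_ms)))
    if method == "boxcar":
        smoothed = ndimage.uniform_filter1d(trace.values, size=n, mode="nearest")
    elif method == "gaussian":
        sigma = n / 2.355  # FWHM -> sigma
        smoothed = ndimage.gaussian_filter1d(trace.values, sigma=sigma, mode="nearest")
    else:
        raise ConfigurationError(f"unknown smoothing method {method!r}")
    return replace(trace, values=smoothed)
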