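"""File formats and experiment configuration.

Images travel as multi-page TIFF (one page per trial, rows = spatial
pixels, columns = lines) or as one delimited matrix per trial; traces,
events and ground truth as tidy CSV; configuration and reports as
YAML/JSON.  Acquisition metadata is never read from TIFF tags — the
sidecar configuration is authoritative, which sidesteps vendor-tag
dialects.  Pixel and line indices are 0-based, ROI spans half-open, and
times are in ms from scan start.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .detect import DetectionConfig, EventCall
from .errors import ConfigurationError
from .linescan import LineScanRecord, Trace
from .simulate import SimParams, SimGroundTruth

__all__ = [
    "AnalysisConfig",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "read_linescan",
    "write_linescan_tiff",
    "write_linescan_matrices",
    "traces_to_frame",
    "events_to_frame",
    "events_from_frame",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage settings: extraction, detection, and statistics."""

    baseline_window_ms: Optional[Tuple[float, float]] = None
    noise_stat: str = "se"  # 'se' (default) or 'sd'
    background_per_line: bool = False
    detrend_bleach: bool = False
    response_window_ms: float = 50.0
    threshold_multiple: float = 2.5
    contamination_policy: str = "reject_trial"
    contamination_multiple: float = 2.5
    p1_tail_correction: str = "none"
    p2_local_baseline_ms: float = 20.0
    ci_method: str = "wilson"
    ci_level: float = 0.95
    comparison_test: str = "fisher"
    alpha: float = 0.05

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(
            response_window_ms=self.response_window_ms,
            threshold_multiple=self.threshold_multiple,
            contamination_policy=self.contamination_policy,
            contamination_multiple=self.contamination_multiple,
            p1_tail_correction=self.p1_tail_correction,
            p2_local_baseline_ms=self.p2_local_baseline_ms,
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved experiment configuration.

    Shipped defaults are the standard acquisition protocol: 500 lines/s,
    200 lines, paired pulses 70 ms apart starting 100 ms into the scan,
    50 ms analysis windows, and a 2.5x noise threshold.
    """

    line_rate_hz: float = 500.0
    n_lines: int = 200
    stim_times_ms: Tuple[float, ...] = (100.0, 170.0)
    roi_spine: Tuple[int, int] = (5, 12)
    roi_dendrite: Tuple[int, int] = (16, 28)
    roi_background: Tuple[int, int] = (30, 40)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulation: Optional[SimParams] = None
    n_trials: int = 30
    seed: int = 0
    version: str = __version__

    @property
    def line_period_ms(self) -> float:
        return 1000.0 / self.line_rate_hz

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "version": self.version,
            "seed": self.seed,
            "acquisition": {
                "line_rate_hz": self.line_rate_hz,
                "n_lines": self.n_lines,
                "stim_times_ms": list(self.stim_times_ms),
            },
            "roi": {
                "spine": list(self.roi_spine),
                "dendrite": list(self.roi_dendrite),
                "background": list(self.roi_background),
            },
            "analysis": dataclasses.asdict(self.analysis),
            "n_trials": self.n_trials,
        }
        if self.analysis.baseline_window_ms is not None:
            d["analysis"]["baseline_window_ms"] = list(self.analysis.baseline_window_ms)
        if self.simulation is not None:
            sim = self.simulation.to_dict()
            if math.isinf(sim["bleach_tau_s"]):
                sim["bleach_tau_s"] = None  # JSON-safe; None means no bleaching
            sim["roi_geometry"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in sim["roi_geometry"].items()
            }
            d["simulation"] = sim
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        try:
            acq = d.get("acquisition", {})
            roi = d.get("roi", {})
            ana = dict(d.get("analysis", {}))
            if ana.get("baseline_window_ms") is not None:
                ana["baseline_window_ms"] = tuple(ana["baseline_window_ms"])
            sim = d.get("simulation")
            return cls(
                line_rate_hz=float(acq.get("line_rate_hz", 500.0)),
                n_lines=int(acq.get("n_lines", 200)),
                stim_times_ms=tuple(acq.get("stim_times_ms", (100.0, 170.0))),
                roi_spine=tuple(roi.get("spine", (5, 12))),
                roi_dendrite=tuple(roi.get("dendrite", (16, 28))),
                roi_background=tuple(roi.get("background", (30, 40))),
                analysis=AnalysisConfig(**ana),
                simulation=SimParams.from_dict(sim) if sim else None,
                n_trials=int(d.get("n_trials", 30)),
                seed=int(d.get("seed", 0)),
                version=str(d.get("version", __version__)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid experiment config: {exc}") from exc

    def with_seed(self, seed: int) -> "ExperimentConfig":
        sim = (
            dataclasses.replace(self.simulation, seed=seed)
            if self.simulation is not None
            else None
        )
        return dataclasses.replace(self, seed=seed, simulation=sim)


def load_config(path: PathLike) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    return ExperimentConfig.from_dict(data)


def save_config(config: ExperimentConfig, path: PathLike) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


# -- line-scan image I/O --------------------------------------------------


def _records_from_arrays(
    arrays: Sequence[np.ndarray],
    config: ExperimentConfig,
    trial_ids: Sequence[str],
) -> List[LineScanRecord]:
    records = []
    for arr, tid in zip(arrays, trial_ids):
        if arr.ndim != 2:
            raise ConfigurationError(
                f"{tid}: expected a 2-D pixels x lines matrix, got shape {arr.shape}"
            )
        for name, span in (
            ("spine", config.roi_spine),
            ("dendrite", config.roi_dendrite),
            ("background", config.roi_background),
        ):
            if span[1] > arr.shape[0]:
                raise ConfigurationError(
                    f"{tid}: ROI '{name}' span [{span[0]}, {span[1]}) exceeds "
                    f"the {arr.shape[0]}-pixel scan line"
                )
        records.append(
            LineScanRecord(
                matrix=arr,
                line_period_ms=config.line_period_ms,
                roi_spine=config.roi_spine,
                roi_dendrite=config.roi_dendrite,
                roi_background=config.roi_background,
                stim_times_ms=config.stim_times_ms,
                baseline_window_ms=config.analysis.baseline_window_ms,
                trial_id=tid,
            )
        )
    return records


def read_linescan(path: PathLike, config: ExperimentConfig) -> List[LineScanRecord]:
    """Read trials from a multi-page TIFF or a directory of delimited matrices.

    TIFF: one page per trial, page order = trial order.  Directory: every
    ``*.csv`` (comma) or ``*.txt``/``*.tsv`` (whitespace/tab) file, sorted
    by name, one matrix per trial.  Timing and ROI metadata come from the
    sidecar config, never from image tags.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input not found: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".csv", ".txt", ".tsv")
        )
        if not files:
            raise ConfigurationError(f"no delimited matrices found in {path}")
        arrays, ids = [], []
        for f in files:
            delim = "," if f.suffix.lower() == ".csv" else None
            try:
                arrays.append(np.atleast_2d(np.loadtxt(f, delimiter=delim)))
            except ValueError as exc:
                raise ConfigurationError(f"cannot parse matrix {f}: {exc}") from exc
            ids.append(f.stem)
        return _records_from_arrays(arrays, config, ids)
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            stack = tifffile.imread(path)
        except (ValueError, OSError) as exc:
            raise ConfigurationError(f"cannot read TIFF {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None, :, :]
        arrays = [stack[i] for i in range(stack.shape[0])]
        ids = [f"trial-{i:04d}" for i in range(len(arrays))]
        return _records_from_arrays(arrays, config, ids)
    raise ConfigurationError(
        f"unsupported input {path}: expected .tif/.tiff or a directory of "
        "delimited matrices"
    )


def write_linescan_tiff(records: Sequence[LineScanRecord], path: PathLike) -> None:
    """Write trials as a grayscale multi-page TIFF (uint16, page = trial)."""
    path = Path(path)
    stack = np.stack([r.matrix.astype(np.uint16) for r in records])
    tifffile.imwrite(path, stack, photometric="minisblack")


def write_linescan_matrices(records: Sequence[LineScanRecord], out_dir: PathLike) -> None:
    """Write one CSV matrix per trial (rows = pixels, columns = lines)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for r in records:
        np.savetxt(out_dir / f"{r.trial_id}.csv", r.matrix, fmt="%d", delimiter=",")


# -- tidy tables ----------------------------------------------------------


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    """Tidy long-format table: trial_id, roi, time_ms, dff."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "roi": tr.roi_label,
                    "time_ms": tr.times_ms,
                    "dff": tr.values,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def events_to_frame(calls: Sequence[EventCall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])


def events_from_frame(frame: pd.DataFrame) -> List[EventCall]:
    """Rebuild EventCall objects from an events CSV/DataFrame."""
    calls = []
    for row in frame.to_dict("records"):
        success = row.get("success")
        if success is None or (isinstance(success, float) and math.isnan(success)):
            success = None
        elif isinstance(success, str):  # CSV round-trip with missing values
            success = success.strip().lower() == "true"
        else:
            success = bool(success)
        error = row.get("error")
        if isinstance(error, float) and math.isnan(error):
            error = None
        contaminated = row["contaminated"]
        if isinstance(contaminated, str):
            contaminated = contaminated.strip().lower() == "true"
        calls.append(
            EventCall(
                trial_id=str(row["trial_id"]),
                pulse_index=int(row["pulse_index"]),
                dff_transient=float(row["dff_transient"]),
                noise_se=float(row["noise_se"]),
                threshold=float(row["threshold"]),
                success=success,
                contaminated=bool(contaminated),
                dendrite_dff_transient=float(row.get("dendrite_dff_transient", math.nan)),
                dendrite_noise_se=float(row.get("dendrite_noise_se", math.nan)),
                error=error,
            )
        )
    return calls


def write_ground_truth_csv(truth: SimGroundTruth, path: PathLike) -> None:
    truth.to_frame().to_csv(path, index=False)
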