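"""Trace and configuration file I/O.

Traces travel as plain CSV with ``# key=value`` header lines carrying the
sample rate, units (uA | V | code | normalized) and channel/stage metadata,
followed by ``time_s,value`` rows (plus a ``channel`` column for interleaved
streams).  Floats are written with 17 significant digits so a write/read
round trip is lossless.  Run configurations are YAML with sections named
after the objects they build (physio, frontend, fir, vitals); unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ConfigurationError
from .filters import FIRSpec
from .frontend import AdcTrace, FrontEndConfig, RCStage, VoltageTrace
from .physio import OpticalChannelTrace, PhysioGroundTruth

__all__ = [
    "TraceRecord",
    "read_trace",
    "write_trace",
    "RunConfig",
    "load_config",
    "save_config",
    "write_ground_truth",
    "read_ground_truth",
    "read_lut",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class TraceRecord:
    """A parsed trace file: samples, timing and header metadata."""

    time_s: np.ndarray
    values: np.ndarray
    meta: dict[str, str]
    channel: np.ndarray | None = None  # per-row wavelength for interleaved streams

    @property
    def sample_rate_hz(self) -> float:
        return float(self.meta["sample_rate_hz"])

    @property
    def units(self) -> str:
        return self.meta.get("units", "")

    def to_optical(self) -> OpticalChannelTrace:
        return OpticalChannelTrace(int(float(self.meta.get("wavelength_nm", 0))),
                                   self.sample_rate_hz, self.values)

    def to_voltage(self) -> VoltageTrace:
        return VoltageTrace(self.values, self.sample_rate_hz,
                            stage_label=self.meta.get("stage_label", ""))


def _trace_meta(trace) -> tuple[np.ndarray, float, dict[str, Any]]:
    if isinstance(trace, OpticalChannelTrace):
        return trace.samples, trace.sample_rate_hz, {
            "units": "uA", "wavelength_nm": trace.wavelength_nm}
    if isinstance(trace, VoltageTrace):
        return trace.samples, trace.sample_rate_hz, {
            "units": "V", "stage_label": trace.stage_label}
    if isinstance(trace, AdcTrace):
        return trace.codes.astype(float), trace.sample_rate_hz, {
            "units": "code", "stage_label": trace.stage_label,
            "bits": trace.bits, "supply_v": trace.supply_v}
    raise FormatError(f"cannot serialize object of type {type(trace).__name__}")


def write_trace(trace, path, extra_meta: Mapping[str, Any] | None = None) -> None:
    """Write a trace as '#'-headed CSV (columns time_s,value)."""
    samples, fs, meta = _trace_meta(trace)
    meta = {"sample_rate_hz": fs, **meta, **(extra_meta or {})}
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        frame = pd.DataFrame({"time_s": np.arange(samples.size) / fs,
                              "value": samples})
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_trace(path) -> TraceRecord:
    """Parse a trace file; malformed headers or rows raise FormatError naming the line."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if "=" not in body:
                    raise FormatError(f"{path}: line {lineno}: header line "
                                      f"without key=value: {stripped!r}")
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    if "sample_rate_hz" not in meta:
        raise FormatError(f"{path}: missing required header 'sample_rate_hz'")
    if not body_lines:
        raise FormatError(f"{path}: no data rows")
    try:
        frame = pd.read_csv(_io.StringIO("".join(body_lines)),
                            float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: unparsable CSV body: {exc}") from exc
    required = {"time_s", "value"}
    if not required <= set(frame.columns):
        raise FormatError(f"{path}: body must have columns {sorted(required)}, "
                          f"got {list(frame.columns)}")
    if frame[["time_s", "value"]].isna().any().any():
        bad = int(frame[["time_s", "value"]].isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: ragged or non-numeric data row {bad + 2}")
    t = frame["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: time column is not strictly increasing")
        if np.ptp(dt) > 1e-9 * max(abs(dt[0]), 1e-300):
            raise FormatError(f"{path}: sampling interval is not constant")
    channel = (frame["channel"].to_numpy() if "channel" in frame.columns else None)
    return TraceRecord(t, frame["value"].to_numpy(dtype=float), meta, channel)


# ---------------------------------------------------------------------------
# Configuration


def _build(cls, data: Mapping[str, Any], context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**dict(data))


def _frontend_from_dict(data: Mapping[str, Any]) -> FrontEndConfig:
    data = dict(data)
    for key in ("stage1", "stage2"):
        if key in data and isinstance(data[key], Mapping):
            data[key] = _build(RCStage, data[key], f"frontend.{key}")
    return _build(FrontEndConfig, data, "frontend")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration: one section per pipeline stage."""

    physio: PhysioGroundTruth = dataclasses.field(default_factory=PhysioGroundTruth)
    frontend: FrontEndConfig = dataclasses.field(default_factory=FrontEndConfig)
    fir: FIRSpec = dataclasses.field(default_factory=FIRSpec)
    vitals: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    log_level: str = "warning"

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {"physio", "frontend", "fir", "vitals", "seed", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"run config: unknown sections {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        if "physio" in data:
            kwargs["physio"] = _build(PhysioGroundTruth, data["physio"], "physio")
        if "frontend" in data:
            kwargs["frontend"] = _frontend_from_dict(data["frontend"])
        if "fir" in data:
            kwargs["fir"] = _build(FIRSpec, data["fir"], "fir")
        if "vitals" in data:
            kwargs["vitals"] = dict(data["vitals"])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "log_level" in data:
            kwargs["log_level"] = str(data["log_level"])
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {
            "physio": _plain(dataclasses.asdict(self.physio)),
            "frontend": _plain(dataclasses.asdict(self.frontend)),
            "fir": _plain(dataclasses.asdict(self.fir)),
            "vitals": _plain(self.vitals),
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _plain(obj):
    """Recursively convert numpy scalars/arrays so YAML stays readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_ground_truth(gt: PhysioGroundTruth, path) -> None:
    """Ground-truth sidecar: the physiology that generated a trace."""
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(dataclasses.asdict(gt)), fh, sort_keys=False)


def read_ground_truth(path) -> PhysioGroundTruth:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PhysioGroundTruth, data, "ground truth")


def read_lut(path) -> np.ndarray:
    """Two-column text lookup table (R, SpO2), strictly decreasing in SpO2."""
    try:
        table = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable lookup table: {exc}") from exc
    if table.shape[1] != 2:
        raise FormatError(f"{path}: lookup table must have exactly two columns")
    return table
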