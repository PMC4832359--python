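"""File I/O: CSV/TSV time series, JSON fit reports and YAML/JSON run configs.

The interchange time-series format is delimited text with the header
``time_s, pyruvate, lactate, alanine, bicarbonate`` (delimiter auto-detected).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CHANNELS, AcquisitionSchedule
from .simulate import DEFAULT_NOISE_SD, TimeSeries

__all__ = [
    "REQUIRED_COLUMNS",
    "SCHEMA_VERSION",
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "write_report",
    "write_pseudo_rates",
    "load_config",
    "config_hash",
]

REQUIRED_COLUMNS = ("time_s",) + CHANNELS
SCHEMA_VERSION = "hpkinetics-report-1"


class TimeSeriesParseError(ValueError):
    """Malformed time-series file (carries a descriptive, line-numbered message)."""


def read_timeseries(path, dialect: str | None = None, label: str | None = None) -> TimeSeries:
    """Read a delimited time-series file into a validated :class:`TimeSeries`.

    Parameters
    ----------
    path : str or Path
    dialect : {None, "csv", "tsv"}
        Delimiter; ``None`` auto-detects comma vs tab.

    Raises
    ------
    TimeSeriesParseError
        On a missing column, non-numeric cell or non-monotone time column,
        with the offending file line number where applicable.
    """
    path = Path(path)
    sep = {None: None, "csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TimeSeriesParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in REQUIRED_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TimeSeriesParseError(
                f"{path}, line {row + 2}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}")
        df[col] = coerced
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        deltas = np.diff(t)
        if np.any(deltas <= 0):
            row = int(np.flatnonzero(deltas <= 0)[0]) + 1
            raise TimeSeriesParseError(
                f"{path}, line {row + 2}: time_s is not strictly increasing "
                f"({t[row]} after {t[row - 1]})")
    return TimeSeries(times=t, signals=df[list(CHANNELS)].to_numpy(dtype=float),
                      label=label if label is not None else path.stem)


def write_timeseries(ts: TimeSeries, path, float_format: str = "%.17g") -> Path:
    """Write a TimeSeries as CSV (round-trips through :func:`read_timeseries`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ts.to_frame().to_csv(path, index=False, float_format=float_format)
    return path


def write_pseudo_rates(courses: pd.DataFrame, path) -> Path:
    """Write pseudo-rate time courses (time-indexed DataFrame) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    courses.to_csv(path, float_format="%.12g")
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(result, path, extra: dict | None = None) -> Path:
    """Serialize a FitResult / CohortSummary / ModelComparison as JSON.

    The report is schema-versioned and carries any ``extra`` provenance
    (config hash, seed, package version).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kind = type(result).__name__
    payload = {"schema_version": SCHEMA_VERSION, "kind": kind,
               "report": _jsonable(result.to_dict())}
    if extra:
        payload["provenance"] = _jsonable(extra)
    path.write_text(json.dumps(payload, indent=2, allow_nan=False) + "\n")
    return path


def read_report(path) -> dict:
    """Load a report written by :func:`write_report` (with schema check)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema: {payload.get('schema_version')!r}")
    return payload


@dataclass
class RunConfig:
    """Validated configuration for a CLI run."""

    model_kind: str = "second_order"
    group: str = "glucose"
    repetition_time: float = 2.0
    flip_angle: float = 10.0
    n_points: int = 90
    start_time: float = 0.0
    bounds: dict | None = None
    n_starts: int = 16
    seed: int = 0
    noise_sd: tuple = DEFAULT_NOISE_SD
    pdh_cofactor: str = "nadm"
    input_term: str = "literal"
    outdir: str = "hpkinetics_out"

    def __post_init__(self) -> None:
        if self.model_kind not in ("second_order", "first_order"):
            raise ValueError("model_kind must be 'second_order' or 'first_order'")
        if self.group not in ("glucose", "pyruvate"):
            raise ValueError("group must be 'glucose' or 'pyruvate'")
        if self.pdh_cofactor not in ("nadm", "nadhm"):
            raise ValueError("pdh_cofactor must be 'nadm' or 'nadhm'")
        if self.input_term not in ("literal", "conservative"):
            raise ValueError("input_term must be 'literal' or 'conservative'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        self.schedule()  # validates the acquisition fields

    def schedule(self) -> AcquisitionSchedule:
        return AcquisitionSchedule(repetition_time=self.repetition_time,
                                   flip_angle=self.flip_angle,
                                   n_points=self.n_points,
                                   start_time=self.start_time)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config file into a validated :class:`RunConfig`."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(sorted(unknown))}")
    if "noise_sd" in data and isinstance(data["noise_sd"], list):
        data["noise_sd"] = tuple(data["noise_sd"])
    return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a config, logged for provenance."""
    blob = json.dumps(_jsonable(cfg.to_dict()), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
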