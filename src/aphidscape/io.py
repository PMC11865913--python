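"""Table I/O, run configuration, and the run manifest.

CSV dialect: UTF-8, comma-separated, ``.`` decimal, ISO dates, missing values
as empty fields.  All tables round-trip (write then read gives the identical
table).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .regression import PipelineConfig
from .simulate import DynamicsTruth, SimulationConfig, WeatherParams

SAMPLING_COLUMNS = ["site_id", "year", "day", "leaves", "total_SA", "total_LB", "total_MM"]
WEATHER_COLUMNS = ["site_id", "date", "tmax_c", "ppt_mm"]
SITES_COLUMNS = ["site_id", "x", "y", "year"]


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_sampling_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SAMPLING_COLUMNS, path)
    for (site, year), grp in df.groupby(["site_id", "year"], sort=False):
        days = grp["day"].to_numpy()
        if len(days) > 1 and not (days[1:] > days[:-1]).all():
            raise SchemaError(
                f"{path}: site {site} year {year}: sampling days must be "
                "strictly increasing"
            )
    if (df["leaves"] < 1).any():
        bad = df.index[df["leaves"] < 1][0]
        raise SchemaError(f"{path}: line {bad + 2}: leaves must be >= 1")
    return df


def write_sampling_csv(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, SAMPLING_COLUMNS, path)
    df[SAMPLING_COLUMNS].to_csv(path, index=False)


def read_weather_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, WEATHER_COLUMNS, path)
    if (df["ppt_mm"] < 0).any():
        bad = df.index[df["ppt_mm"] < 0][0]
        raise SchemaError(f"{path}: line {bad + 2}: column ppt_mm must be >= 0")
    return df


def write_weather_csv(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, WEATHER_COLUMNS, path)
    out = df[WEATHER_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SITES_COLUMNS, path)
    return df


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["site_id", "year"], path)
    return df


def write_metrics_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class LandscapeConfig:
    radius: float = 5000.0
    connectivity: int = 8
    prox_radius: float = 1000.0  # PROX search radius, m (explicit by policy)
    count_boundary: bool = True


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise SchemaError(f"config section {context!r} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise SchemaError(f"unknown config key(s) in {context!r}: {sorted(unknown)}")
    kwargs = {}
    nested = {
        "weather_params": WeatherParams,
        "dynamics_params": DynamicsTruth,
    }
    for key, value in data.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = _build(nested[key], value, f"{context}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON run configuration; unknown keys are an error."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"simulation", "landscape", "pipeline"}
    if unknown:
        raise SchemaError(f"{path}: unknown top-level config key(s): {sorted(unknown)}")
    return RunConfig(
        simulation=_build(SimulationConfig, raw.get("simulation", {}), "simulation"),
        landscape=_build(LandscapeConfig, raw.get("landscape", {}), "landscape"),
        pipeline=_build(PipelineConfig, raw.get("pipeline", {}), "pipeline"),
    )


def config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    canonical = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(
    out_dir: str | Path, cfg: RunConfig, seed: int, files: list[str]
) -> dict:
    """Write run_manifest.json with config hash, seed, and file checksums."""
    import datetime

    from . import __version__

    out = Path(out_dir)
    checksums = {}
    for name in sorted(files):
        p = out / name
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "checksums": checksums,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
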