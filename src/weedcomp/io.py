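"""Tabular schemas, run configuration and provenance helpers.

Observation CSV (long format, one row per pot):
    year, regime, gdd_flowering, species, density, replicate, yield_t_ha
optionally ``t_mean_flowering`` and component columns.

Temperature CSV (one row per day per regime-year):
    date (ISO-8601), regime, year, t_mean_c

Output files embed the run configuration and seed as ``# key: value``
comment lines at the top of each CSV (readable back with
``pd.read_csv(..., comment='#')``) or a ``meta`` object in JSON.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .gdd import StageCalendar, TemperatureSeries

__all__ = [
    "RunConfig",
    "load_config",
    "read_observations",
    "write_observations",
    "read_temperatures",
    "write_temperatures",
    "write_csv_with_meta",
    "write_json_with_meta",
    "file_sha256",
]

OBS_REQUIRED = ["year", "regime", "gdd_flowering", "species", "density", "replicate", "yield_t_ha"]
TEMP_REQUIRED = ["date", "regime", "year", "t_mean_c"]

# sanity ranges for unit validation
MAX_DENSITY = 1000.0  # plants m⁻²
MAX_YIELD = 20.0  # t ha⁻¹


@dataclass
class RunConfig:
    """Pipeline-wide settings with defaults.

    Stage dates are month-day strings applied to each trial year.
    """

    t_base: float = 10.0
    transplanting: str = "06-01"
    tillering: str = "08-10"
    flowering: str = "08-28"
    maturity: str = "10-15"
    min_weed_free_yield: float = 1.0  # t ha⁻¹, pooled-fit level inclusion
    alpha: float = 0.05
    n_starts: int = 5
    tol: float = 1e-12
    seed: int = 0

    def calendar(self, year: int) -> StageCalendar:
        def parse(md: str) -> dt.date:
            month, day = (int(v) for v in md.split("-"))
            return dt.date(year, month, day)

        return StageCalendar(
            transplanting=parse(self.transplanting),
            tillering=parse(self.tillering),
            flowering=parse(self.flowering),
            maturity=parse(self.maturity),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a TOML run config; missing keys keep their defaults."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate an observation CSV.

    Schema violations are collected and reported together with their
    1-based data row numbers.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in OBS_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    errors: list[str] = []
    for col in ("year", "gdd_flowering", "density", "replicate", "yield_t_ha"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        for row in df.index[coerced.isna() & df[col].notna()]:
            errors.append(f"row {row + 1}: unparsable {col} value {df.loc[row, col]!r}")
        df[col] = coerced
    for row in df.index[df[OBS_REQUIRED].isna().any(axis=1)]:
        errors.append(f"row {row + 1}: missing value in required column")
    ok = df[OBS_REQUIRED].notna().all(axis=1)
    bad_density = ok & ((df["density"] < 0) | (df["density"] > MAX_DENSITY))
    for row in df.index[bad_density]:
        errors.append(
            f"row {row + 1}: density {df.loc[row, 'density']} outside [0, {MAX_DENSITY}]"
        )
    bad_yield = ok & ((df["yield_t_ha"] < 0) | (df["yield_t_ha"] > MAX_YIELD))
    for row in df.index[bad_yield]:
        errors.append(
            f"row {row + 1}: yield {df.loc[row, 'yield_t_ha']} outside [0, {MAX_YIELD}]"
        )
    key = ["year", "regime", "species", "density", "replicate"]
    dup = df.duplicated(subset=key, keep="first")
    for row in df.index[dup]:
        errors.append(f"row {row + 1}: duplicate observation key {tuple(df.loc[row, key])}")
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    df["year"] = df["year"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_observations(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    write_csv_with_meta(df, path, meta)


def read_temperatures(path: str | Path) -> list[TemperatureSeries]:
    """Read a temperature CSV into one series per (year, regime)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TEMP_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    out = []
    for (year, regime), group in df.groupby(["year", "regime"], sort=True):
        out.append(TemperatureSeries.from_frame(group))
    return out


def write_temperatures(
    series_list: list[TemperatureSeries], path: str | Path, meta: dict | None = None
) -> None:
    frames = [
        pd.DataFrame(
            {
                "date": s.dates.strftime("%Y-%m-%d"),
                "regime": s.regime_label,
                "year": s.year,
                "t_mean_c": s.t_mean,
            }
        )
        for s in series_list
    ]
    write_csv_with_meta(pd.concat(frames, ignore_index=True), path, meta)


def _meta_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {json.dumps(v, default=str)}\n" for k, v in meta.items())


def write_csv_with_meta(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a CSV with the run metadata embedded as leading comment lines."""
    with open(path, "w", newline="") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, index=False, lineterminator="\n")


def write_json_with_meta(obj: dict, path: str | Path, meta: dict | None = None) -> None:
    payload = dict(obj)
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    return str(value)


def file_sha256(path: str | Path) -> str:
    """Provenance hash of an input file."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
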