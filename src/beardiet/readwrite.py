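"""CSV readers/writers with schema validation, and the run configuration.

All tables are UTF-8, comma-delimited CSV with a required header row and "."
decimals; dates are ISO-8601. Percent columns are 0-100 and suffixed
``_pct``; fraction columns are 0-1 and suffixed ``_frac`` where ambiguity is
possible. Validation errors always name the offending column or field.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .energy import season_of_date
from .foods import FoodType
from .intake import DEFAULT_SCAT_EQUIVALENTS, FeedingSign, ScatRecord

logger = logging.getLogger(__name__)

SPECIES_LEVELS = ("grizzly", "black_sympatric", "black_allopatric")
SEX_LEVELS = ("F", "M")
INTENSITY_LEVELS = tuple(DEFAULT_SCAT_EQUIVALENTS)


class SchemaError(ValueError):
    """A malformed input table; the message names the offending field."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _check_enum(df: pd.DataFrame, col: str, levels: Sequence[str], what: str) -> None:
    bad = sorted(set(df[col].dropna().astype(str)) - set(levels))
    if bad:
        raise SchemaError(f"{what}: column '{col}' has invalid value(s) {bad}")


def _check_range(df, col, lo, hi, what, lo_open=False):
    v = pd.to_numeric(df[col], errors="coerce")
    if v.isna().any() and df[col].notna().any() and v.isna().sum() > df[col].isna().sum():
        raise SchemaError(f"{what}: column '{col}' has non-numeric values")
    bad = (v <= lo) if lo_open else (v < lo)
    bad = bad | (v > hi)
    if bad.fillna(False).any():
        raise SchemaError(f"{what}: column '{col}' has values outside ({lo}, {hi}]")


def read_scats(path) -> list[ScatRecord]:
    """Read a scats CSV (bear_day_id, scat_id, taxon, percent_fecal_volume)."""
    df = pd.read_csv(path)
    _require_columns(df, ["bear_day_id", "scat_id", "taxon", "percent_fecal_volume"], "scats")
    _check_range(df, "percent_fecal_volume", 0.0, 100.0, "scats", lo_open=True)
    records = []
    for (bd, sid), grp in df.groupby(["bear_day_id", "scat_id"], sort=False):
        items = tuple(
            (str(r["taxon"]), float(r["percent_fecal_volume"])) for _, r in grp.iterrows()
        )
        records.append(ScatRecord(bear_day_id=str(bd), scat_id=str(sid), items=items))
    return records


def read_signs(path) -> list[FeedingSign]:
    """Read a feeding-signs CSV (bear_day_id, site_id, taxon, intensity)."""
    df = pd.read_csv(path)
    _require_columns(df, ["bear_day_id", "site_id", "taxon", "intensity"], "signs")
    _check_enum(df, "intensity", INTENSITY_LEVELS, "signs")
    return [
        FeedingSign(
            bear_day_id=str(r["bear_day_id"]),
            taxon=str(r["taxon"]),
            intensity=str(r["intensity"]),
            site_id=str(r["site_id"]),
        )
        for _, r in df.iterrows()
    ]


def read_days(path) -> pd.DataFrame:
    """Read a bear-day metadata CSV and derive the season of each date."""
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["bear_day_id", "bear_id", "date", "species", "sex", "body_mass_kg", "fix_interval_min"],
        "days",
    )
    _check_enum(df, "species", SPECIES_LEVELS, "days")
    _check_enum(df, "sex", SEX_LEVELS, "days")
    if df["bear_day_id"].duplicated().any():
        dup = df.loc[df["bear_day_id"].duplicated(), "bear_day_id"].iloc[0]
        raise SchemaError(f"days: duplicate bear_day_id {dup!r}")
    mass = pd.to_numeric(df["body_mass_kg"], errors="coerce")
    if mass.isna().any() or (mass <= 0).any():
        raise SchemaError("days: column 'body_mass_kg' must be positive numbers")
    df = df.copy()
    df["season"] = df["date"].map(season_of_date)
    df["group"] = df["species"].astype(str) + "_" + df["sex"].astype(str)
    return df


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run; defaults are the study constants."""

    scats: Optional[str] = None
    signs: Optional[str] = None
    days: Optional[str] = None
    composition: Optional[str] = None
    out: str = "beardiet_out"
    band_center: float = 17.0
    band_half_width: float = 4.0
    dominance: float = 95.0
    member_min: float = 50.0
    mean_min: float = 75.0
    scat_equivalents: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCAT_EQUIVALENTS)
    )
    n_dims: Optional[int] = None
    k_max: Optional[int] = None
    seed: int = 0
    verbosity: str = "INFO"

    DEFAULTS = {
        "band_center": 17.0,
        "band_half_width": 4.0,
        "dominance": 95.0,
        "member_min": 50.0,
        "mean_min": 75.0,
    }

    def __post_init__(self) -> None:
        for name, default in self.DEFAULTS.items():
            value = getattr(self, name)
            if value != default:
                logger.info("RunConfig: %s overridden to %s (default %s)", name, value, default)
        for k, default in DEFAULT_SCAT_EQUIVALENTS.items():
            if k not in self.scat_equivalents:
                raise SchemaError(f"config: scat_equivalents missing class {k!r}")
            if self.scat_equivalents[k] != default:
                logger.info(
                    "RunConfig: scat equivalent %s overridden to %s (default %s)",
                    k, self.scat_equivalents[k], default,
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**raw)
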