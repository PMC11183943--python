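"""Tidy observation and weather tables: schemas, validation, CSV round-trip.

The experimental unit is one nectar measurement from one flower. Tables are
held as pandas DataFrames with a fixed column contract; every reader
validates on the way in and every writer emits a file the reader accepts
unchanged (read ∘ write is the identity on all fields).

Observation CSV columns
    date                 ISO-8601 calendar day (YYYY-MM-DD)
    round_hour           integer clock hour of the sampling round
    species              categorical label (e.g. plum, blackthorn, cherry, pear)
    tree_id              identifier, unique within species
    treatment            "bagged" or "open"
    flower_id            identifier, unique within (date, round, species, tree, treatment)
    volume_uL            non-negative nectar volume in microliters; exactly 0
                         for an empty flower (the hurdle zero)
    concentration_brix   optional sugar concentration in [0, 100] °Brix;
                         empty string when not measured (never 0)
    concentration_pooled optional flag: the Brix reading came from a pool of
                         the cell's five flowers

Weather CSV columns
    timestamp            hour-resolution instant (ISO-8601)
    temperature_C        air temperature
    precipitation_mm     non-negative hourly precipitation
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ROUND_SET",
    "OBSERVATION_COLUMNS",
    "WEATHER_COLUMNS",
    "SchemaError",
    "ValidationError",
    "read_observations",
    "write_observations",
    "validate_observations",
    "read_weather",
    "write_weather",
    "validate_weather",
]

#: Sampling rounds used in the field design: every 2 h from 9:00 to 15:00,
#: with an optional extra 17:00 round.
DEFAULT_ROUND_SET = frozenset({9, 11, 13, 15, 17})

OBSERVATION_COLUMNS = [
    "date",
    "round_hour",
    "species",
    "tree_id",
    "treatment",
    "flower_id",
    "volume_uL",
    "concentration_brix",
    "concentration_pooled",
]

#: Columns that must be present in an observation CSV; the two concentration
#: columns are optional and filled with missing values when absent.
REQUIRED_OBSERVATION_COLUMNS = OBSERVATION_COLUMNS[:7]

WEATHER_COLUMNS = ["timestamp", "temperature_C", "precipitation_mm"]

TREATMENTS = ("bagged", "open")


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class ValidationError(ValueError):
    """A row violates a table invariant; the message names the row."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def validate_observations(
    df: pd.DataFrame, round_set: Iterable[int] = DEFAULT_ROUND_SET
) -> pd.DataFrame:
    """Validate an observation table in place and return it.

    Checks every invariant of the schema: non-negative volumes, treatments
    in {bagged, open}, rounds drawn from ``round_set``, parseable dates,
    concentrations in [0, 100] where present, and uniqueness of the
    (date, round_hour, species, tree_id, treatment, flower_id) key.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        naming the first offending row index otherwise.
    """
    _require_columns(df, REQUIRED_OBSERVATION_COLUMNS, "observation table")
    round_set = set(int(h) for h in round_set)

    try:
        dates = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable date in observation table: {exc}") from exc
    df["date"] = dates.dt.strftime("%Y-%m-%d")

    rounds = pd.to_numeric(df["round_hour"], errors="coerce")
    bad = df.index[rounds.isna() | ~rounds.isin(list(round_set))]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: round_hour {df.loc[bad[0], 'round_hour']!r} "
            f"not in configured round set {sorted(round_set)}"
        )
    df["round_hour"] = rounds.astype(int)

    bad = df.index[~df["treatment"].isin(TREATMENTS)]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: treatment {df.loc[bad[0], 'treatment']!r} "
            f"not one of {TREATMENTS}"
        )

    volumes = pd.to_numeric(df["volume_uL"], errors="coerce")
    bad = df.index[volumes.isna() | (volumes < 0)]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: volume_uL {df.loc[bad[0], 'volume_uL']!r} "
            "must be a non-negative number"
        )
    df["volume_uL"] = volumes.astype(float)

    if "concentration_brix" in df.columns:
        conc = pd.to_numeric(df["concentration_brix"], errors="coerce")
        stated = df["concentration_brix"].notna()
        bad = df.index[stated & (conc.isna() | (conc < 0) | (conc > 100))]
        if len(bad):
            raise ValidationError(
                f"row {bad[0]}: concentration_brix "
                f"{df.loc[bad[0], 'concentration_brix']!r} must lie in [0, 100]"
            )
        df["concentration_brix"] = conc
    else:
        df["concentration_brix"] = np.nan

    if "concentration_pooled" not in df.columns:
        df["concentration_pooled"] = pd.Series(pd.NA, index=df.index, dtype="boolean")
    else:
        df["concentration_pooled"] = df["concentration_pooled"].map(
            {True: True, False: False, "True": True, "False": False, "": pd.NA},
            na_action="ignore",
        ).astype("boolean")

    key = ["date", "round_hour", "species", "tree_id", "treatment", "flower_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        i = df.index[dup][0]
        raise ValidationError(
            f"row {i}: duplicate observation key "
            f"{tuple(df.loc[i, key])} — keys must be unique"
        )
    return df[OBSERVATION_COLUMNS + [c for c in df.columns if c not in OBSERVATION_COLUMNS]]


def read_observations(
    path: str | Path, round_set: Iterable[int] = DEFAULT_ROUND_SET
) -> pd.DataFrame:
    """Read and validate a flower-observation CSV.

    Missing concentrations are parsed as NaN (absent), never as 0. Row
    order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"species": str, "tree_id": str, "flower_id": str, "date": str},
        keep_default_na=False,
        na_values=[""],
        float_precision="round_trip",
    )
    return validate_observations(df, round_set=round_set)


def write_observations(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated observation table to CSV.

    Absent concentrations are serialized as the empty string so that a
    re-read restores NaN, not zero.
    """
    if len(df) == 0:
        raise ValidationError("refusing to write an empty observation table")
    df = validate_observations(df.copy())
    path = Path(path)
    out = df[OBSERVATION_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="")
    return path


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a weather table: monotone timestamps, precipitation ≥ 0."""
    _require_columns(df, WEATHER_COLUMNS, "weather table")
    try:
        ts = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable timestamp: {exc}") from exc
    df = df.assign(timestamp=ts).sort_values("timestamp", kind="stable")
    if df["timestamp"].duplicated().any():
        i = df.index[df["timestamp"].duplicated()][0]
        raise ValidationError(f"row {i}: duplicated timestamp {df.loc[i, 'timestamp']}")
    df = df.reset_index(drop=True)
    temp = pd.to_numeric(df["temperature_C"], errors="coerce")
    if temp.isna().any():
        i = df.index[temp.isna()][0]
        raise ValidationError(f"row {i}: temperature_C is not a number")
    precip = pd.to_numeric(df["precipitation_mm"], errors="coerce")
    bad = df.index[precip.isna() | (precip < 0)]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: precipitation_mm must be a non-negative number"
        )
    df["temperature_C"] = temp.astype(float)
    df["precipitation_mm"] = precip.astype(float)
    return df


def read_weather(path: str | Path) -> pd.DataFrame:
    """Read, sort and validate an hourly weather CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_weather(pd.read_csv(path, float_precision="round_trip"))


def write_weather(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated weather table to CSV (ISO timestamps)."""
    df = validate_weather(df.copy())
    out = df[WEATHER_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False)
    return Path(path)
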