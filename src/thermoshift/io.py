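"""CSV readers and writers for the plot, trait, occurrence and temperature tables.

Formats (UTF-8, mandatory header row, ``""`` or ``NA`` for missing):

* ``plots.csv``: ``plot_id,elevation_m,land_use[,zone]``
* ``traits.csv``: ``species_id,lineage,temperature_value,strategy_code``
* ``occurrences.csv``: ``plot_id,year,species_id``
* ``temperature.csv``: ``year,mean_temp_c``

Headers are matched case-insensitively.  Reading validates invariants
(elevation range, land-use vocabulary, indicator grid, referential
integrity of occurrences) and deduplicates occurrence rows.  Writers
produce deterministic byte-identical output for identical inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_ZONE_THRESHOLDS,
    ELEVATION_MAX,
    LandUse,
    Lineage,
    TemperatureSeries,
    Zone,
    assign_zone,
    is_on_grid,
)

log = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA")


class FormatError(ValueError):
    """A table does not conform to the documented column contract."""


class ReferentialError(ValueError):
    """Cross-table reference to an unknown identifier."""


def _read_csv(path: str | Path, required: Sequence[str], optional: Sequence[str] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    keep = [c for c in (*required, *optional) if c in df.columns]
    df = df[keep]
    return df.replace(list(MISSING_TOKENS), pd.NA)


def _parse_enum(series: pd.Series, enum_cls, what: str, table: str) -> pd.Series:
    allowed = {e.value for e in enum_cls}
    bad = sorted(set(series.dropna()) - allowed)
    if bad:
        raise FormatError(
            f"{table}: unknown {what} value(s) {bad}; allowed: {sorted(allowed)}"
        )
    return series


def read_plots(
    path: str | Path,
    zone_thresholds: Sequence[float] = DEFAULT_ZONE_THRESHOLDS,
) -> pd.DataFrame:
    """Read and validate the plot table; derive ``zone`` where absent."""
    df = _read_csv(path, ["plot_id", "elevation_m", "land_use"], ["zone"])
    if df["plot_id"].isna().any():
        raise FormatError("plots: empty plot_id")
    if df["plot_id"].duplicated().any():
        dups = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()
        raise FormatError(f"plots: duplicated plot_id(s): {dups[:10]}")
    elev = pd.to_numeric(df["elevation_m"], errors="coerce")
    if elev.isna().any():
        raise FormatError("plots: non-numeric elevation_m")
    if ((elev < 0) | (elev > ELEVATION_MAX)).any():
        bad = df.loc[(elev < 0) | (elev > ELEVATION_MAX), "plot_id"].tolist()
        raise FormatError(
            f"plots: elevation outside [0, {ELEVATION_MAX}] for plot(s) {bad[:10]}"
        )
    _parse_enum(df["land_use"], LandUse, "land_use", "plots")
    out = pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(str),
            "elevation_m": elev.astype(float),
            "land_use": df["land_use"].astype(str),
        }
    )
    if "zone" in df.columns and df["zone"].notna().all():
        _parse_enum(df["zone"], Zone, "zone", "plots")
        out["zone"] = df["zone"].astype(str)
    else:
        out["zone"] = [assign_zone(e, zone_thresholds).value for e in out["elevation_m"]]
    return out


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read and validate the species trait table."""
    df = _read_csv(path, ["species_id", "lineage", "temperature_value", "strategy_code"])
    if df["species_id"].isna().any():
        raise FormatError("traits: empty species_id")
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise FormatError(f"traits: duplicated species_id(s): {dups[:10]}")
    _parse_enum(df["lineage"], Lineage, "lineage", "traits")
    tv = pd.to_numeric(df["temperature_value"], errors="coerce")
    present = df["temperature_value"].notna()
    if (present & tv.isna()).any():
        raise FormatError("traits: non-numeric temperature_value")
    off = [v for v in tv[present] if not is_on_grid(v)]
    if off:
        raise FormatError(
            f"traits: temperature_value(s) off the 0.5-step [1, 5] grid: {off[:10]}"
        )
    return pd.DataFrame(
        {
            "species_id": df["species_id"].astype(str),
            "lineage": df["lineage"].astype(str),
            "temperature_value": tv.astype(float),
            "strategy_code": df["strategy_code"].astype("string"),
        }
    )


def read_occurrences(path: str | Path, plots: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the occurrence table; deduplicate (plot, year, species) rows.

    When ``plots`` is given, occurrences referencing unknown plot ids raise
    a :class:`ReferentialError` listing the offenders.
    """
    df = _read_csv(path, ["plot_id", "year", "species_id"])
    if df[["plot_id", "species_id"]].isna().any().any():
        raise FormatError("occurrences: empty plot_id or species_id")
    year = pd.to_numeric(df["year"], errors="coerce")
    if year.isna().any() or (year != year.round()).any():
        raise FormatError("occurrences: year must be an integer calendar year")
    out = pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(str),
            "year": year.astype(int),
            "species_id": df["species_id"].astype(str),
        }
    )
    n0 = len(out)
    out = out.drop_duplicates(ignore_index=True)
    if len(out) < n0:
        log.info("occurrences: dropped %d duplicated row(s)", n0 - len(out))
    if plots is not None:
        unknown = sorted(set(out["plot_id"]) - set(plots["plot_id"]))
        if unknown:
            raise ReferentialError(
                f"occurrences: unknown plot_id(s): {unknown[:10]}"
                + ("..." if len(unknown) > 10 else "")
            )
    return out


def read_temperature(path: str | Path) -> TemperatureSeries:
    """Read the annual mean-temperature series."""
    df = _read_csv(path, ["year", "mean_temp_c"])
    year = pd.to_numeric(df["year"], errors="coerce")
    temp = pd.to_numeric(df["mean_temp_c"], errors="coerce")
    if year.isna().any() or temp.isna().any():
        raise FormatError("temperature: non-numeric year or mean_temp_c")
    return TemperatureSeries(tuple(int(y) for y in year), tuple(float(t) for t in temp))


def read_tables(
    plot_csv: str | Path,
    trait_csv: str | Path,
    occurrence_csv: str | Path,
    zone_thresholds: Sequence[float] = DEFAULT_ZONE_THRESHOLDS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the three core tables."""
    plots = read_plots(plot_csv, zone_thresholds)
    traits = read_traits(trait_csv)
    occurrences = read_occurrences(occurrence_csv, plots)
    return plots, traits, occurrences


# ---------------------------------------------------------------- writers

def _write_csv(df: pd.DataFrame, path: str | Path, float_cols: Iterable[str] = ()) -> None:
    df = df.copy()
    for col in float_cols:
        if col in df.columns:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False, na_rep="", lineterminator="\n", encoding="utf-8")


def write_plots(plots: pd.DataFrame, path: str | Path) -> None:
    _write_csv(plots, path, float_cols=["elevation_m"])


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    _write_csv(traits, path, float_cols=["temperature_value"])


def write_occurrences(occurrences: pd.DataFrame, path: str | Path) -> None:
    _write_csv(occurrences, path)


def write_temperature(series: TemperatureSeries, path: str | Path) -> None:
    df = pd.DataFrame({"year": series.years, "mean_temp_c": series.mean_temp})
    _write_csv(df, path, float_cols=["mean_temp_c"])
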