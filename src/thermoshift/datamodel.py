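"""Core domain types for permanent-plot resurvey data.

The analysis operates on three tables — plots, species traits and
occurrences — plus an optional annual mean-temperature series.  Records are
plain dataclasses; the table-level representation used throughout the
pipeline is a pandas DataFrame (see :mod:`thermoshift.io`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence


class LandUse(str, enum.Enum):
    """The three major land-use types of the monitoring design."""

    MANAGED_GRASSLAND = "managed_grassland"
    FOREST = "forest"
    UNMANAGED_OPEN = "unmanaged_open"


class Zone(str, enum.Enum):
    """Elevational vegetation zones (nival plots are pooled into alpine)."""

    COLLINE = "colline"
    MONTANE = "montane"
    SUBALPINE = "subalpine"
    ALPINE = "alpine"


class Lineage(str, enum.Enum):
    BRYOPHYTE = "bryophyte"
    VASCULAR = "vascular"


class Affinity(str, enum.Enum):
    """Temperature-affinity classes of indicator values."""

    CRYOPHILIC = "cryophilic"
    MESOPHILIC = "mesophilic"
    THERMOPHILIC = "thermophilic"
    UNCLASSIFIED = "unclassified"


class Longevity(str, enum.Enum):
    """Life-strategy summary: short- vs long-lived species."""

    SHORT_LIVED = "short_lived"
    LONG_LIVED = "long_lived"
    UNCLASSIFIED = "unclassified"


#: Default single national rule for elevational zones (metres a.s.l.).
#: Lower bounds of montane, subalpine and alpine.
DEFAULT_ZONE_THRESHOLDS: tuple[float, float, float] = (800.0, 1500.0, 2200.0)

ELEVATION_MAX = 5000.0

#: Ordinal indicator-value grid: 1.0, 1.5, ..., 5.0.
TEMPERATURE_GRID: tuple[float, ...] = tuple(1.0 + 0.5 * k for k in range(9))


def is_on_grid(value: float, *, tol: float = 1e-9) -> bool:
    """True if ``value`` lies on the 0.5-step indicator grid in [1, 5]."""
    if not (1.0 - tol <= value <= 5.0 + tol):
        return False
    return abs(value * 2.0 - round(value * 2.0)) <= tol


def assign_zone(
    elevation: float,
    thresholds: Sequence[float] = DEFAULT_ZONE_THRESHOLDS,
) -> Zone:
    """Map elevation (m a.s.l.) to an elevational zone.

    A single national threshold rule is used: colline below the first
    threshold, montane and subalpine between, alpine at or above the last.
    Monotone in elevation by construction.
    """
    if not math.isfinite(elevation) or elevation < 0:
        raise ValueError(f"elevation must be finite and >= 0, got {elevation!r}")
    t_mont, t_sub, t_alp = thresholds
    if not (0 < t_mont < t_sub < t_alp):
        raise ValueError(f"zone thresholds must be increasing, got {thresholds!r}")
    if elevation < t_mont:
        return Zone.COLLINE
    if elevation < t_sub:
        return Zone.MONTANE
    if elevation < t_alp:
        return Zone.SUBALPINE
    return Zone.ALPINE


@dataclass(frozen=True)
class PlotRecord:
    """One permanent plot."""

    plot_id: str
    elevation: float
    land_use: LandUse
    zone: Zone | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.elevation <= ELEVATION_MAX):
            raise ValueError(
                f"plot {self.plot_id!r}: elevation {self.elevation} outside "
                f"[0, {ELEVATION_MAX}]"
            )

    def with_zone(self, thresholds: Sequence[float] = DEFAULT_ZONE_THRESHOLDS) -> "PlotRecord":
        zone = self.zone or assign_zone(self.elevation, thresholds)
        return PlotRecord(self.plot_id, self.elevation, self.land_use, zone)


@dataclass(frozen=True)
class TraitRecord:
    """One species: lineage, optional temperature value, life strategy."""

    species_id: str
    lineage: Lineage
    temperature_value: float | None = None
    strategy_code: str | None = None

    def __post_init__(self) -> None:
        tv = self.temperature_value
        if tv is not None and not is_on_grid(tv):
            raise ValueError(
                f"species {self.species_id!r}: temperature value {tv} is not "
                "on the 0.5-step grid in [1, 5]"
            )

    @property
    def longevity(self) -> Longevity:
        """Derived life-strategy summary (short- vs long-lived)."""
        from .strategies import classify_life_strategy

        return classify_life_strategy(self.strategy_code, self.lineage)


@dataclass(frozen=True)
class OccurrenceRecord:
    """Presence of one species in one plot-survey."""

    plot_id: str
    year: int
    species_id: str


@dataclass(frozen=True)
class TemperatureSeries:
    """Annual mean temperatures (°C) over the study window."""

    years: tuple[int, ...]
    mean_temp: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.years) != len(self.mean_temp):
            raise ValueError("years and mean_temp must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
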