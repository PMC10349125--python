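"""Thermophilisation rates, elevational CTI lapse, NES and isotherm shifts.

The thermophilisation rate of a community is the OLS slope of its CTI
against survey year (CTI units per year).  The notional elevation shift
(NES) normalises that rate by the elevational CTI lapse — the decline of
per-plot mean CTI with elevation, expressed per 100 m — to give the
elevation difference (m per decade) at which equal-CTI communities are
found a decade apart:

    NES = thermophilisation rate / |lapse|  ×  1000   [m/decade]

e.g. a rate of 0.01 CTI/yr over a lapse of 0.1 CTI per 100 m is an NES of
100 m per decade.  The expected NES under pure temperature tracking is the
isotherm shift: warming rate divided by the adiabatic lapse rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

#: Adiabatic lapse-rate bounds for Switzerland, °C per 100 m.
DEFAULT_ADIABATIC_BOUNDS = (0.5, 0.67)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fit_plot_trend(years, ctis) -> float:
    """OLS slope of CTI on calendar year for one community (CTI/yr).

    Pairs with undefined (NaN) CTI are dropped; with fewer than two usable
    pairs or a single distinct year the trend is undefined and NaN is
    returned (such communities are excluded from NES computation).
    """
    years = np.asarray(years, dtype=float)
    ctis = np.asarray(ctis, dtype=float)
    ok = np.isfinite(ctis) & np.isfinite(years)
    years, ctis = years[ok], ctis[ok]
    if years.size < 2 or np.unique(years).size < 2:
        return float("nan")
    xc = years - years.mean()
    return float((xc * (ctis - ctis.mean())).sum() / (xc * xc).sum())


@dataclass(frozen=True)
class LapseEstimate:
    """Elevational CTI lapse of one lineage (slope per 100 m, expected < 0)."""

    lineage: str
    lapse_per_100m: float
    se_per_100m: float
    intercept: float
    r_squared: float
    p_value: float
    n_plots: int

    @property
    def magnitude(self) -> float:
        return abs(self.lapse_per_100m)


class LapseRegression(BaseEstimator):
    """OLS of per-plot mean CTI on elevation, reported per 100 m.

    Parameters
    ----------
    lineage : str
        Label carried into the resulting :class:`LapseEstimate`.

    Attributes
    ----------
    lapse_per_100m_ : float
        Fitted slope per 100 m of elevation (negative when communities are
        more cryophilic higher up, the expected direction).
    r_squared_, p_value_, intercept_, n_plots_ :
        Usual OLS summaries.
    """

    def __init__(self, lineage: str = ""):
        self.lineage = lineage

    def fit(self, elevation_m, mean_cti):
        elevation_m = np.asarray(elevation_m, dtype=float)
        mean_cti = np.asarray(mean_cti, dtype=float)
        ok = np.isfinite(elevation_m) & np.isfinite(mean_cti)
        elevation_m, mean_cti = elevation_m[ok], mean_cti[ok]
        if elevation_m.size < 3:
            raise ValueError(
                f"lapse estimation needs >= 3 plots with defined mean CTI, "
                f"got {elevation_m.size}"
            )
        if np.ptp(elevation_m) == 0:
            raise ValueError("lapse estimation needs >= 2 distinct elevations")
        res = stats.linregress(elevation_m / 100.0, mean_cti)
        self.lapse_per_100m_ = float(res.slope)
        self.se_per_100m_ = float(res.stderr)
        self.intercept_ = float(res.intercept)
        # a flat response has no explainable variance: R^2 = 0 by convention
        r2 = float(res.rvalue**2)
        self.r_squared_ = 0.0 if not np.isfinite(r2) else r2
        self.p_value_ = float(res.pvalue)
        self.n_plots_ = int(elevation_m.size)
        return self

    def predict(self, elevation_m):
        elevation_m = np.asarray(elevation_m, dtype=float)
        return self.intercept_ + self.lapse_per_100m_ * elevation_m / 100.0

    def estimate_(self) -> LapseEstimate:
        return LapseEstimate(
            lineage=self.lineage,
            lapse_per_100m=self.lapse_per_100m_,
            se_per_100m=self.se_per_100m_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            p_value=self.p_value_,
            n_plots=self.n_plots_,
        )


def estimate_lapse(elevation_m, mean_cti, lineage: str = "") -> LapseEstimate:
    """Elevational CTI lapse from per-plot mean CTI (see :class:`LapseRegression`)."""
    return LapseRegression(lineage=lineage).fit(elevation_m, mean_cti).estimate_()


def compute_nes(slope_per_yr: float, lapse_magnitude: float) -> float:
    """Notional elevation shift (m/decade) from a CTI trend and lapse magnitude."""
    if not (lapse_magnitude > 0):
        raise ValueError(
            f"lapse magnitude must be > 0 to normalise a CTI trend, got {lapse_magnitude!r}"
        )
    return slope_per_yr * 1000.0 / lapse_magnitude


def estimate_warming(series) -> tuple[float, float, float]:
    """Warming rate from an annual series: OLS slope × 10 (°C/decade), R², p."""
    years = np.asarray(series.years, dtype=float)
    temps = np.asarray(series.mean_temp, dtype=float)
    if years.size < 3:
        raise ValueError("warming estimation needs >= 3 years")
    if np.ptp(years) == 0:
        raise ValueError("warming estimation needs >= 2 distinct years")
    res = stats.linregress(years, temps)
    return float(res.slope * 10.0), float(res.rvalue**2), float(res.pvalue)


@dataclass(frozen=True)
class IsothermShift:
    """Expected upward isotherm shift implied by a warming rate."""

    warming_rate: float  # °C per decade
    adiabatic_lapse_low: float  # °C per 100 m
    adiabatic_lapse_high: float
    shift_low: float  # m per decade (warming / high lapse)
    shift_high: float  # m per decade (warming / low lapse)

    @property
    def rounded(self) -> tuple[int, int]:
        """Half-up whole-metre window, as reported."""
        return (_round_half_up(self.shift_low), _round_half_up(self.shift_high))


def isotherm_shift(
    warming_rate: float,
    adiabatic_bounds: tuple[float, float] = DEFAULT_ADIABATIC_BOUNDS,
) -> IsothermShift:
    """Isotherm-shift window (m/decade) for adiabatic lapse-rate bounds."""
    low, high = adiabatic_bounds
    if not (0 < low <= high):
        raise ValueError(f"adiabatic bounds must satisfy 0 < low <= high, got {adiabatic_bounds!r}")
    return IsothermShift(
        warming_rate=warming_rate,
        adiabatic_lapse_low=low,
        adiabatic_lapse_high=high,
        shift_low=warming_rate / high * 100.0,
        shift_high=warming_rate / low * 100.0,
    )


def plot_mean_cti(surveys: pd.DataFrame) -> pd.DataFrame:
    """Per plot × lineage mean CTI over all surveys with a defined CTI."""
    ok = surveys[np.isfinite(surveys["cti"])]
    return (
        ok.groupby(["plot_id", "lineage"], sort=True)["cti"]
        .mean()
        .rename("mean_cti")
        .reset_index()
    )


def estimate_lapses(
    surveys: pd.DataFrame, plots: pd.DataFrame
) -> dict[str, LapseEstimate]:
    """Lineage-wise elevational lapse from per-plot mean CTI vs elevation."""
    means = plot_mean_cti(surveys).merge(
        plots[["plot_id", "elevation_m"]], on="plot_id"
    )
    out: dict[str, LapseEstimate] = {}
    for lineage, grp in means.groupby("lineage", sort=True):
        out[str(lineage)] = estimate_lapse(
            grp["elevation_m"], grp["mean_cti"], lineage=str(lineage)
        )
    return out


def build_trends(
    surveys: pd.DataFrame,
    lapses: dict[str, LapseEstimate],
    subset: str = "all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-community thermophilisation rates and NES.

    Parameters
    ----------
    surveys : DataFrame
        Output of :func:`thermoshift.community.build_surveys` (for a
        life-strategy subset, surveys rebuilt from the filtered species set).
    lapses : dict
        Lineage → :class:`LapseEstimate`.  A non-negative estimated lapse
        aborts: the NES presupposes CTI declining with elevation.
    subset : str
        Label recorded on every trend row (``all``/``short_lived``/``long_lived``).

    Returns
    -------
    (trends, exclusions)
        ``trends`` has one row per eligible community (>= 2 surveys with a
        defined CTI); ``exclusions`` lists ineligible communities and the
        reason.
    """
    for lineage, lap in lapses.items():
        if lap.lapse_per_100m >= 0:
            raise ValueError(
                f"estimated lapse for {lineage} is non-negative "
                f"({lap.lapse_per_100m:+.4f} per 100 m); NES requires CTI "
                "to decline with elevation"
            )

    rows, excl = [], []
    for (plot_id, lineage), grp in surveys.groupby(["plot_id", "lineage"], sort=True):
        ok = np.isfinite(grp["cti"].to_numpy())
        n_used = int(ok.sum())
        if n_used < 2 or grp.loc[ok, "year"].nunique() < 2:
            excl.append(
                {
                    "plot_id": plot_id,
                    "lineage": lineage,
                    "subset": subset,
                    "reason": "fewer than two CTI values",
                }
            )
            continue
        slope = fit_plot_trend(grp["year"], grp["cti"])
        lap = lapses[str(lineage)]
        rows.append(
            {
                "plot_id": plot_id,
                "lineage": lineage,
                "subset": subset,
                "n_surveys_used": n_used,
                "mean_n_with_t": float(grp.loc[ok, "n_with_t"].mean()),
                "slope_per_yr": slope,
                "nes_m_per_decade": compute_nes(slope, lap.magnitude),
            }
        )
    trends = pd.DataFrame(
        rows,
        columns=[
            "plot_id", "lineage", "subset", "n_surveys_used",
            "mean_n_with_t", "slope_per_yr", "nes_m_per_decade",
        ],
    )
    exclusions = pd.DataFrame(excl, columns=["plot_id", "lineage", "subset", "reason"])
    if len(exclusions):
        log.info(
            "%s subset: %d communities excluded (fewer than two CTI values)",
            subset, len(exclusions),
        )
    return trends, exclusions
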