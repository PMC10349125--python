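"""Community temperature index (CTI) and temperature-affinity counts.

The CTI of a community (one lineage on one plot in one survey year) is the
unweighted arithmetic mean of the ordinal temperature indicator values
(1 = most cryophilic ... 5 = most thermophilic, 0.5 steps) of the species
present.  Species without an indicator value contribute to richness but not
to the CTI; a community whose species all lack values has an undefined CTI.

Affinity classes partition the indicator grid: values 1–2.5 are cryophilic,
3 mesophilic and 3.5–5 thermophilic.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import Affinity, is_on_grid

log = logging.getLogger(__name__)

#: Class bounds on the indicator grid: cryophilic <= CRYO_MAX < mesophilic
#: band < THERMO_MIN <= thermophilic.
CRYO_MAX = 2.5
THERMO_MIN = 3.5


def classify_affinity(
    temperature_value: float | None,
    cryo_max: float = CRYO_MAX,
    thermo_min: float = THERMO_MIN,
) -> Affinity:
    """Temperature-affinity class of one indicator value.

    Missing values map to ``UNCLASSIFIED``; off-grid values are rejected.
    """
    if temperature_value is None or (
        isinstance(temperature_value, float) and math.isnan(temperature_value)
    ):
        return Affinity.UNCLASSIFIED
    if not is_on_grid(temperature_value):
        raise ValueError(
            f"temperature value {temperature_value!r} is not on the 0.5-step [1, 5] grid"
        )
    if temperature_value <= cryo_max:
        return Affinity.CRYOPHILIC
    if temperature_value < thermo_min:
        return Affinity.MESOPHILIC
    return Affinity.THERMOPHILIC


def compute_cti(temperature_values: Iterable[float]) -> float:
    """Unweighted mean indicator value; NaN (undefined) on empty input.

    The caller is responsible for passing one value per *distinct* species
    (presence–absence semantics) and for excluding species without values.
    """
    values = np.asarray(list(temperature_values), dtype=float)
    if values.size == 0:
        return float("nan")
    return float(values.mean())


def build_surveys(
    plots: pd.DataFrame,
    traits: pd.DataFrame,
    occurrences: pd.DataFrame,
    cryo_max: float = CRYO_MAX,
    thermo_min: float = THERMO_MIN,
) -> pd.DataFrame:
    """Assemble per plot × lineage × year community summaries.

    Returns one row per community with at least one occurrence of the
    lineage: richness, number of species carrying an indicator value, CTI
    (NaN when no member species has a value) and cryo/meso/thermo counts.
    """
    occ = occurrences.merge(
        traits[["species_id", "lineage", "temperature_value"]],
        on="species_id",
        how="left",
    )
    unknown = occ["lineage"].isna()
    if unknown.any():
        missing = sorted(occ.loc[unknown, "species_id"].unique())
        raise ValueError(
            f"occurrences reference species absent from the trait table: {missing[:10]}"
        )
    occ = occ.drop_duplicates(["plot_id", "year", "species_id"])

    tv = occ["temperature_value"]
    occ = occ.assign(
        has_t=tv.notna(),
        is_cryo=tv.notna() & (tv <= cryo_max),
        is_thermo=tv.notna() & (tv >= thermo_min),
    )
    occ["is_meso"] = occ["has_t"] & ~occ["is_cryo"] & ~occ["is_thermo"]

    grouped = occ.groupby(["plot_id", "lineage", "year"], sort=True)
    out = grouped.agg(
        n_species=("species_id", "size"),
        n_with_t=("has_t", "sum"),
        cti_sum=("temperature_value", "sum"),
        n_cryo=("is_cryo", "sum"),
        n_meso=("is_meso", "sum"),
        n_thermo=("is_thermo", "sum"),
    ).reset_index()
    with np.errstate(invalid="ignore"):
        out["cti"] = np.where(
            out["n_with_t"] > 0, out["cti_sum"] / out["n_with_t"], np.nan
        )
    out = out.drop(columns="cti_sum")
    for col in ("n_species", "n_with_t", "n_cryo", "n_meso", "n_thermo"):
        out[col] = out[col].astype(int)
    out = out[
        ["plot_id", "lineage", "year", "n_species", "n_with_t", "cti",
         "n_cryo", "n_meso", "n_thermo"]
    ]

    n_obs = int(out["n_species"].sum())
    n_cov = int(out["n_with_t"].sum())
    if n_obs:
        log.info(
            "built %d communities; indicator-value coverage %.1f%% of %d observations",
            len(out), 100.0 * n_cov / n_obs, n_obs,
        )
    return out
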