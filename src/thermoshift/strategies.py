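"""Life-strategy classification into short- vs long-lived species.

Bryophytes follow the During life-strategy system: fugitives, annual
shuttles, colonists (incl. ephemeral and pioneer colonists) and short-lived
shuttles are short-lived; long-lived shuttles, perennials (incl. competitive
and stress-tolerant perennials) and dominants are long-lived.

Vascular plants follow three-letter competitive/stress-tolerant/ruderal
attribute codes: predominantly ruderal codes (rrr, rrs, crr) are
short-lived, predominantly competitive codes (ccc, ccs, ccr) long-lived.
Predominantly stress-tolerant codes (sss, css, rss) and the mixed crs code
are excluded (longevity undefined for the stress-tolerant category), as are
unknown or missing codes.
"""

from __future__ import annotations

import logging

import pandas as pd

from .datamodel import Lineage, Longevity

log = logging.getLogger(__name__)

_BRYOPHYTE_SHORT = {
    "fugitive",
    "annual_shuttle",
    "colonist",
    "ephemeral_colonist",
    "pioneer_colonist",
    "short_lived_shuttle",
}
_BRYOPHYTE_LONG = {
    "long_lived_shuttle",
    "perennial",
    "competitive_perennial",
    "stress_tolerant_perennial",
    "dominant",
}
_VASCULAR_SHORT = {"rrr", "rrs", "crr"}
_VASCULAR_LONG = {"ccc", "ccs", "ccr"}
_VASCULAR_EXCLUDED = {"sss", "css", "rss", "crs"}


def _normalise(code: str) -> str:
    return code.strip().lower().replace(" ", "_").replace("-", "_")


def classify_life_strategy(
    strategy_code: str | None, lineage: str | Lineage
) -> Longevity:
    """Longevity class of one strategy code; unknown codes are unclassified."""
    if strategy_code is None or (isinstance(strategy_code, float) and pd.isna(strategy_code)) or pd.isna(strategy_code):
        return Longevity.UNCLASSIFIED
    code = _normalise(str(strategy_code))
    lineage = Lineage(lineage)
    if lineage is Lineage.BRYOPHYTE:
        if code in _BRYOPHYTE_SHORT:
            return Longevity.SHORT_LIVED
        if code in _BRYOPHYTE_LONG:
            return Longevity.LONG_LIVED
    else:
        if code in _VASCULAR_SHORT:
            return Longevity.SHORT_LIVED
        if code in _VASCULAR_LONG:
            return Longevity.LONG_LIVED
        if code in _VASCULAR_EXCLUDED:
            return Longevity.UNCLASSIFIED
    if code:
        log.debug("unknown strategy code %r (%s): unclassified", strategy_code, lineage.value)
    return Longevity.UNCLASSIFIED


def add_longevity(traits: pd.DataFrame) -> pd.DataFrame:
    """Return the trait table with a derived ``longevity`` column."""
    longevity = [
        classify_life_strategy(code, lin).value
        for code, lin in zip(traits["strategy_code"], traits["lineage"])
    ]
    return traits.assign(longevity=longevity)


def subset_traits(traits: pd.DataFrame, longevity: str | Longevity) -> pd.DataFrame:
    """Trait rows belonging to one longevity class (for subset CTI runs)."""
    longevity = Longevity(longevity)
    tr = traits if "longevity" in traits.columns else add_longevity(traits)
    return tr[tr["longevity"] == longevity.value].reset_index(drop=True)
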