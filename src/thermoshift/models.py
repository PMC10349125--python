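"""The four model families of the thermophilisation analysis.

* CTI trend LMMs: ``CTI ~ year + (1 | plot)`` per lineage × zone × land-use
  stratum, with cluster-bootstrap confidence intervals (plots resampled
  with replacement).
* NES lineage model: ``NES ~ lineage + (1 | plot)`` with a power variance
  function in the community's mean number of contributing species.
* NES full model: lineage, centred elevation ((elev - 514 m)/100 m),
  land-use type and all two- and three-way interactions; non-significant
  interactions (marginal Wald F, p >= 0.05) are dropped in a single step
  and the model refitted.
* Number-of-species models: Poisson GLMM ``n ~ year + (1 | plot)`` per
  affinity class.
* Life-strategy models: ``NES ~ longevity + elevation + land use +
  (1 | plot)`` per lineage, power variance function.

Strata with fewer plots than the low-representation cut (default 14) are
skipped with a recorded reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .glmm import PoissonGLMM
from .lmm import PowerVarianceLMM

log = logging.getLogger(__name__)

#: Minimum plots per factor combination for a stratum model.
MIN_PLOTS_DEFAULT = 14

_LAND_USES = ("managed_grassland", "forest", "unmanaged_open")
_REFERENCE_ELEVATION = 514.0


@dataclass
class ModelFit:
    """Tidy summary of one fitted (G)LMM."""

    model_id: str
    formula: str
    coefficients: pd.DataFrame  # term, estimate, se, stat, p [, ddf]
    n_obs: int
    n_groups: int
    converged: bool
    anova: pd.DataFrame | None = None  # term, f_value, df_num, df_den, p
    ci: pd.DataFrame | None = None  # term, lower, upper
    ci_method: str | None = None  # {"bootstrap", "wald"}
    variance_power: float | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)

    def coef(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "se"])


@dataclass(frozen=True)
class StratumSpec:
    lineage: str
    zone: str
    land_use: str
    min_plots: int = MIN_PLOTS_DEFAULT


def _tidy(model, stat_name: str = "t") -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "term": model.feature_names_,
            "estimate": model.coef_.to_numpy(),
            "se": model.bse_.to_numpy(),
            stat_name: (model.tvalues_ if stat_name == "t" else model.zvalues_).to_numpy(),
            "p": model.pvalues_.to_numpy(),
        }
    )
    if stat_name == "t":
        out["ddf"] = model.dof_.to_numpy()
    return out


def _wald_ci(model, level: float = 0.95) -> pd.DataFrame:
    ci = model.conf_int(level)
    return pd.DataFrame(
        {"term": model.feature_names_, "lower": ci["lower"].to_numpy(), "upper": ci["upper"].to_numpy()}
    )


# --------------------------------------------------------------- CTI trend


class CTITrendLMM(BaseEstimator):
    """``CTI ~ year + (1 | plot)`` for one stratum, bootstrap CI on the trend.

    ``year`` is centred at the first survey year (the trend coefficient is
    unaffected).  A singular fit (between-plot variance ~ 0) falls back to
    the marginal regression, which the profiled engine returns in that
    limit; the fallback is recorded in the notes.

    Attributes
    ----------
    year_coef_, year_se_ : float
        Temporal CTI trend (CTI units per year) and its Wald SE.
    ci_ : tuple(float, float)
        Percentile cluster-bootstrap CI for the trend.
    """

    def __init__(self, bootstrap_b: int = 1000, ci_level: float = 0.95, random_state: int = 0):
        self.bootstrap_b = bootstrap_b
        self.ci_level = ci_level
        self.random_state = random_state

    def fit(self, data: pd.DataFrame):
        data = data.dropna(subset=["cti"])
        year0 = int(data["year"].min())
        X = pd.DataFrame(
            {"intercept": 1.0, "year": data["year"].to_numpy(dtype=float) - year0}
        )
        lmm = PowerVarianceLMM(estimate_power=False).fit(
            X, data["cti"], data["plot_id"]
        )
        self.lmm_ = lmm
        self.year0_ = year0
        self.year_coef_ = float(lmm.coef_["year"])
        self.year_se_ = float(lmm.bse_["year"])
        self.notes_ = ("singular fit: fell back to marginal regression",) if lmm.singular_ else ()

        # nonparametric cluster bootstrap: plots resampled with replacement
        rng = np.random.default_rng(self.random_state)
        years_by_plot, cti_by_plot = [], []
        for _, g in data.groupby("plot_id", sort=True):
            years_by_plot.append(g["year"].to_numpy(dtype=float) - year0)
            cti_by_plot.append(g["cti"].to_numpy(dtype=float))
        n_plots = len(years_by_plot)
        sizes = np.array([a.size for a in years_by_plot])
        stats_ = np.empty(self.bootstrap_b)
        for b in range(self.bootstrap_b):
            take = rng.integers(n_plots, size=n_plots)
            yr = np.concatenate([years_by_plot[t] for t in take])
            Xb = pd.DataFrame({"intercept": np.ones(yr.size), "year": yr})
            yb = np.concatenate([cti_by_plot[t] for t in take])
            gb = np.repeat(np.arange(n_plots), sizes[take])
            try:
                m = PowerVarianceLMM(estimate_power=False).fit(
                    Xb, yb, gb, theta0=lmm.theta_
                )
                stats_[b] = m.coef_["year"]
            except np.linalg.LinAlgError:
                stats_[b] = np.nan
        alpha = 1.0 - self.ci_level
        self.bootstrap_samples_ = stats_
        self.ci_ = tuple(
            float(v)
            for v in np.nanquantile(stats_, [alpha / 2.0, 1.0 - alpha / 2.0])
        )
        return self

    def to_fit(self, model_id: str = "cti_trend") -> ModelFit:
        coef = _tidy(self.lmm_)
        ci = pd.DataFrame(
            {"term": ["year"], "lower": [self.ci_[0]], "upper": [self.ci_[1]]}
        )
        return ModelFit(
            model_id=model_id,
            formula="cti ~ year + (1 | plot_id)",
            coefficients=coef,
            n_obs=self.lmm_.n_obs_,
            n_groups=self.lmm_.n_groups_,
            converged=self.lmm_.converged_,
            ci=ci,
            ci_method="bootstrap",
            notes=self.notes_,
        )


def fit_cti_trend(
    stratum_data: pd.DataFrame,
    bootstrap_b: int = 1000,
    min_plots: int = MIN_PLOTS_DEFAULT,
    random_state: int = 0,
    model_id: str = "cti_trend",
) -> ModelFit | str:
    """Fit one stratum CTI-trend model, or return a skip reason string."""
    usable = stratum_data.dropna(subset=["cti"])
    n_plots = usable["plot_id"].nunique()
    if n_plots < min_plots:
        return f"skipped: {n_plots} plots < {min_plots}"
    est = CTITrendLMM(bootstrap_b=bootstrap_b, random_state=random_state).fit(usable)
    return est.to_fit(model_id)


# --------------------------------------------------------------- NES models


def _check_variance_covariate(trends: pd.DataFrame) -> np.ndarray:
    v = trends["mean_n_with_t"].to_numpy(dtype=float)
    return np.maximum(v, 0.5)  # guard: a community with species but no values


class NESLineageLMM(BaseEstimator):
    """``NES ~ lineage + (1 | plot)`` with a power variance function.

    The intercept is the mean bryophyte NES (m/decade); the ``vascular``
    coefficient is the vascular-minus-bryophyte difference.  The variance
    covariate is the community's mean number of species contributing to its
    CTI.
    """

    def __init__(self, estimate_power: bool = True):
        self.estimate_power = estimate_power

    def fit(self, trends: pd.DataFrame):
        lineages = sorted(trends["lineage"].unique())
        if len(lineages) < 2:
            raise ValueError(
                f"NES lineage model needs both lineages, got only {lineages}"
            )
        both = trends.groupby("plot_id")["lineage"].nunique()
        if (both >= 2).sum() < 2:
            raise ValueError("NES lineage model needs >= 2 plots with both lineages")
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "vascular": (trends["lineage"] == "vascular").astype(float).to_numpy(),
            }
        )
        self.lmm_ = PowerVarianceLMM(estimate_power=self.estimate_power).fit(
            X,
            trends["nes_m_per_decade"],
            trends["plot_id"],
            variance_covariate=_check_variance_covariate(trends) if self.estimate_power else None,
        )
        self.intercept_ = float(self.lmm_.coef_["intercept"])
        self.lineage_effect_ = float(self.lmm_.coef_["vascular"])
        self.variance_power_ = self.lmm_.variance_power_
        return self

    def to_fit(self, model_id: str = "nes_lineage") -> ModelFit:
        return ModelFit(
            model_id=model_id,
            formula="nes ~ lineage + (1 | plot_id), varPower(~mean_n_with_t)",
            coefficients=_tidy(self.lmm_),
            n_obs=self.lmm_.n_obs_,
            n_groups=self.lmm_.n_groups_,
            converged=self.lmm_.converged_,
            ci=_wald_ci(self.lmm_),
            ci_method="wald",
            variance_power=self.variance_power_,
        )


def fit_nes_lineage(trends: pd.DataFrame) -> ModelFit:
    return NESLineageLMM().fit(trends).to_fit()


_FULL_TERMS: dict[str, list[str]] = {
    "lineage": ["vascular"],
    "elevation": ["elev_z"],
    "land_use": ["forest", "unmanaged_open"],
    "lineage:elevation": ["vascular:elev_z"],
    "lineage:land_use": ["vascular:forest", "vascular:unmanaged_open"],
    "elevation:land_use": ["elev_z:forest", "elev_z:unmanaged_open"],
    "lineage:elevation:land_use": [
        "vascular:elev_z:forest",
        "vascular:elev_z:unmanaged_open",
    ],
}
_MAIN_TERMS = ("lineage", "elevation", "land_use")


def _full_design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    cols = {
        "intercept": np.ones(len(df)),
        "vascular": (df["lineage"] == "vascular").astype(float).to_numpy(),
        "elev_z": (df["elevation_m"].to_numpy(dtype=float) - _REFERENCE_ELEVATION) / 100.0,
        "forest": (df["land_use"] == "forest").astype(float).to_numpy(),
        "unmanaged_open": (df["land_use"] == "unmanaged_open").astype(float).to_numpy(),
    }
    X = pd.DataFrame({"intercept": cols["intercept"]})
    for term in terms:
        for col in _FULL_TERMS[term]:
            parts = col.split(":")
            X[col] = np.prod([cols[p] for p in parts], axis=0)
    return X


class NESFullLMM(BaseEstimator):
    """NES full model: lineage x elevation x land use with interaction pruning.

    Fits the full interaction model, runs marginal Wald F-tests per term,
    then refits once without every interaction whose p >= ``alpha`` (main
    effects always retained).  Elevation enters centred at 514 m and scaled
    by 100 m, so the intercept is the bryophyte NES in managed grasslands
    at 514 m a.s.l. and the elevation coefficient is per +100 m.
    """

    def __init__(self, alpha: float = 0.05, estimate_power: bool = True):
        self.alpha = alpha
        self.estimate_power = estimate_power

    def _fit_terms(self, df, terms, v):
        X = _full_design(df, terms)
        notes = []
        while True:
            try:
                lmm = PowerVarianceLMM(estimate_power=self.estimate_power).fit(
                    X, df["nes_m_per_decade"], df["plot_id"], variance_covariate=v
                )
                break
            except np.linalg.LinAlgError:
                # rank deficiency from an empty stratum cell: drop the
                # highest-order offending interaction and retry
                inter = [t for t in terms if ":" in t]
                if not inter:
                    raise
                worst = max(inter, key=lambda t: t.count(":"))
                terms = [t for t in terms if t != worst]
                notes.append(f"dropped rank-deficient interaction {worst}")
                X = _full_design(df, terms)
        return lmm, list(terms), notes

    def fit(self, trends: pd.DataFrame, plots: pd.DataFrame):
        for col in ("land_use", "elevation_m"):
            if col not in plots.columns:
                raise ValueError(f"plot table lacks required column {col!r}")
        df = trends.merge(
            plots[["plot_id", "elevation_m", "land_use"]], on="plot_id", how="left"
        )
        if df["elevation_m"].isna().any():
            raise ValueError("trends reference plots absent from the plot table")
        v = _check_variance_covariate(df)

        terms = list(_FULL_TERMS)
        self.full_lmm_, terms, notes = self._fit_terms(df, terms, v)
        anova_rows = []
        for term in terms:
            f, dfn, dfd, p = self.full_lmm_.wald_f_test(_FULL_TERMS[term])
            anova_rows.append(
                {"term": term, "f_value": f, "df_num": dfn, "df_den": dfd, "p": p}
            )
        self.anova_ = pd.DataFrame(anova_rows)

        keep = [t for t in terms if t in _MAIN_TERMS]
        dropped = []
        for row in anova_rows:
            t = row["term"]
            if t in _MAIN_TERMS:
                continue
            if row["p"] < self.alpha:
                keep.append(t)
            else:
                dropped.append(t)
        self.dropped_interactions_ = tuple(dropped)
        self.reduced_lmm_, self.reduced_terms_, notes2 = self._fit_terms(df, keep, v)
        self.notes_ = tuple(notes + notes2)
        return self

    def to_fits(self) -> tuple[ModelFit, ModelFit]:
        common = dict(ci_method="wald")
        full = ModelFit(
            model_id="nes_full",
            formula="nes ~ lineage * elev_z * land_use + (1 | plot_id), varPower",
            coefficients=_tidy(self.full_lmm_),
            anova=self.anova_,
            n_obs=self.full_lmm_.n_obs_,
            n_groups=self.full_lmm_.n_groups_,
            converged=self.full_lmm_.converged_,
            ci=_wald_ci(self.full_lmm_),
            variance_power=self.full_lmm_.variance_power_,
            notes=self.notes_,
            **common,
        )
        reduced = ModelFit(
            model_id="nes_reduced",
            formula="nes ~ " + " + ".join(self.reduced_terms_) + " + (1 | plot_id), varPower",
            coefficients=_tidy(self.reduced_lmm_),
            n_obs=self.reduced_lmm_.n_obs_,
            n_groups=self.reduced_lmm_.n_groups_,
            converged=self.reduced_lmm_.converged_,
            ci=_wald_ci(self.reduced_lmm_),
            variance_power=self.reduced_lmm_.variance_power_,
            notes=("dropped: " + ", ".join(self.dropped_interactions_),)
            if self.dropped_interactions_
            else (),
            **common,
        )
        return full, reduced


def fit_nes_full(trends: pd.DataFrame, plots: pd.DataFrame) -> tuple[ModelFit, ModelFit]:
    return NESFullLMM().fit(trends, plots).to_fits()


# ------------------------------------------------------------ count models


class CountTrendGLMM(BaseEstimator):
    """``n_species ~ year + (1 | plot)``, Poisson, log link.

    ``year`` is centred at the first survey year; the reported trend is the
    log-scale change per year.
    """

    def fit(self, data: pd.DataFrame):
        year0 = int(data["year"].min())
        X = pd.DataFrame(
            {"intercept": 1.0, "year": data["year"].to_numpy(dtype=float) - year0}
        )
        self.glmm_ = PoissonGLMM().fit(X, data["n"], data["plot_id"])
        self.year_coef_ = float(self.glmm_.coef_["year"])
        self.year_se_ = float(self.glmm_.bse_["year"])
        return self

    def to_fit(self, model_id: str = "count_trend") -> ModelFit:
        return ModelFit(
            model_id=model_id,
            formula="n ~ year + (1 | plot_id), poisson(log)",
            coefficients=_tidy(self.glmm_, stat_name="z"),
            n_obs=self.glmm_.n_obs_,
            n_groups=self.glmm_.n_groups_,
            converged=self.glmm_.converged_,
            ci=_wald_ci(self.glmm_),
            ci_method="wald",
        )


def fit_count_trend(
    stratum_counts: pd.DataFrame, model_id: str = "count_trend"
) -> ModelFit | str:
    """Fit one affinity-class count model, or return a skip reason."""
    if (stratum_counts["n"] == 0).all():
        return "skipped: all counts zero"
    est = CountTrendGLMM().fit(stratum_counts)
    return est.to_fit(model_id)


# ----------------------------------------------------------- life strategy


class LifeStrategyLMM(BaseEstimator):
    """``NES ~ longevity + elevation + land use + (1 | plot)`` per lineage.

    ``trends`` must hold the two longevity subsets (``subset`` column with
    ``short_lived`` and ``long_lived``) of one lineage; the ``long_lived``
    coefficient is the long- vs short-lived contrast.
    """

    def __init__(self, estimate_power: bool = True):
        self.estimate_power = estimate_power

    def fit(self, trends: pd.DataFrame, plots: pd.DataFrame):
        for col in ("land_use", "elevation_m"):
            if col not in plots.columns:
                raise ValueError(f"plot table lacks required column {col!r}")
        for subset in ("short_lived", "long_lived"):
            if not (trends["subset"] == subset).any():
                raise ValueError(f"life-strategy model: subset {subset!r} is empty")
        df = trends.merge(
            plots[["plot_id", "elevation_m", "land_use"]], on="plot_id", how="left"
        )
        X = pd.DataFrame(
            {
                "intercept": np.ones(len(df)),
                "long_lived": (df["subset"] == "long_lived").astype(float).to_numpy(),
                "elev_z": (df["elevation_m"].to_numpy(dtype=float) - _REFERENCE_ELEVATION) / 100.0,
                "forest": (df["land_use"] == "forest").astype(float).to_numpy(),
                "unmanaged_open": (df["land_use"] == "unmanaged_open").astype(float).to_numpy(),
            }
        )
        # a land-use level absent from the data would make the design singular
        X = X.loc[:, (X != 0).any(axis=0)]
        self.lmm_ = PowerVarianceLMM(estimate_power=self.estimate_power).fit(
            X,
            df["nes_m_per_decade"],
            df["plot_id"],
            variance_covariate=_check_variance_covariate(df) if self.estimate_power else None,
        )
        self.strategy_effect_ = float(self.lmm_.coef_["long_lived"])
        return self

    def to_fit(self, model_id: str = "life_strategy") -> ModelFit:
        return ModelFit(
            model_id=model_id,
            formula="nes ~ longevity + elev_z + land_use + (1 | plot_id), varPower",
            coefficients=_tidy(self.lmm_),
            n_obs=self.lmm_.n_obs_,
            n_groups=self.lmm_.n_groups_,
            converged=self.lmm_.converged_,
            ci=_wald_ci(self.lmm_),
            ci_method="wald",
            variance_power=self.lmm_.variance_power_,
        )


def fit_life_strategy(
    trends_by_subset: pd.DataFrame, plots: pd.DataFrame, lineage: str
) -> ModelFit:
    sub = trends_by_subset[trends_by_subset["lineage"] == lineage]
    return (
        LifeStrategyLMM()
        .fit(sub, plots)
        .to_fit(model_id=f"life_strategy_{lineage}")
    )


# ------------------------------------------------------------------ strata


def iter_strata(
    plots: pd.DataFrame, min_plots: int = MIN_PLOTS_DEFAULT
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Eligible (zone, land_use) factor combinations and the skipped ones.

    A combination is eligible when at least ``min_plots`` plots fall in it;
    skipped combinations are returned with plot counts for the report.
    """
    counts = plots.groupby(["zone", "land_use"], sort=True)["plot_id"].nunique()
    eligible, skipped = [], []
    for (zone, lu), n in counts.items():
        if n >= min_plots:
            eligible.append((zone, lu))
        else:
            skipped.append(
                {"zone": zone, "land_use": lu, "n_plots": int(n),
                 "reason": f"{n} plots < {min_plots}"}
            )
    return eligible, pd.DataFrame(skipped, columns=["zone", "land_use", "n_plots", "reason"])
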