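"""Model families: recovery, stratum rules, pruning, interval coverage."""

import numpy as np
import pandas as pd
import pytest

from thermoshift.community import build_surveys
from thermoshift.lmm import PowerVarianceLMM
from thermoshift.models import (
    CTITrendLMM,
    LifeStrategyLMM,
    NESFullLMM,
    NESLineageLMM,
    fit_cti_trend,
    fit_nes_lineage,
    iter_strata,
)
from thermoshift.simulate import ScenarioConfig, generate_scenario
from thermoshift.strategies import subset_traits
from thermoshift.trends import build_trends, estimate_lapses


def make_cti_stratum(rng, n_plots=200, slope=0.008, tau=0.15, sigma=0.2,
                     years=(2001, 2006, 2011, 2016, 2021)):
    """Direct random-intercept CTI panel with a known temporal trend."""
    years = np.asarray(years, dtype=float)
    plot = np.repeat([f"p{i:04d}" for i in range(n_plots)], years.size)
    year = np.tile(years, n_plots)
    b = rng.normal(0.0, tau, n_plots)
    cti = 3.0 + slope * (year - years[0]) + np.repeat(b, years.size) + rng.normal(
        0.0, sigma, plot.size
    )
    return pd.DataFrame({"plot_id": plot, "year": year.astype(int), "cti": cti})


def make_nes_trends(rng, n_plots=300, bryo=30.0, vasc=14.0, sd_b=90.0, sd_v=45.0,
                    tau=25.0):
    """Direct two-lineage NES table with plot-shared deviations."""
    plots = [f"p{i:04d}" for i in range(n_plots)]
    shared = rng.normal(0.0, tau, n_plots)
    rows = []
    for i, p in enumerate(plots):
        nb = rng.poisson(9) + 1
        nv = rng.poisson(25) + 1
        rows.append((p, "bryophyte", bryo + shared[i] + rng.normal(0, sd_b), nb))
        rows.append((p, "vascular", vasc + shared[i] + rng.normal(0, sd_v), nv))
    return pd.DataFrame(
        rows, columns=["plot_id", "lineage", "nes_m_per_decade", "mean_n_with_t"]
    )


class TestCTITrend:
    def test_trend_recovery(self):
        rng = np.random.default_rng(101)
        data = make_cti_stratum(rng, n_plots=200, slope=0.008)
        fit = fit_cti_trend(data, bootstrap_b=60, random_state=1)
        year = fit.coefficients.set_index("term").loc["year"]
        assert year["estimate"] == pytest.approx(0.008, abs=2 * year["se"])

    def test_small_stratum_skipped(self):
        rng = np.random.default_rng(102)
        data = make_cti_stratum(rng, n_plots=13)
        res = fit_cti_trend(data, min_plots=14)
        assert isinstance(res, str) and "13 plots < 14" in res

    def test_bootstrap_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(103)
        widths = {}
        for n in (40, 160):
            data = make_cti_stratum(rng, n_plots=n, slope=0.0)
            est = CTITrendLMM(bootstrap_b=120, random_state=5).fit(data)
            widths[n] = est.ci_[1] - est.ci_[0]
        ratio = widths[40] / widths[160]
        assert 1.3 < ratio < 3.2  # ~ sqrt(160/40) = 2 within Monte-Carlo slack

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(104)
        data = make_cti_stratum(rng, n_plots=60)
        est = CTITrendLMM(bootstrap_b=120, random_state=2).fit(data)
        assert est.ci_[0] < est.year_coef_ < est.ci_[1]


class TestNESLineage:
    def test_recovery_on_direct_data(self):
        rng = np.random.default_rng(301)
        trends = make_nes_trends(rng, n_plots=600, bryo=29.8, vasc=14.0)
        fit = fit_nes_lineage(trends)
        assert fit.coef("intercept") == pytest.approx(29.8, abs=2 * fit.se("intercept"))
        assert fit.coef("vascular") == pytest.approx(-15.8, abs=2 * fit.se("vascular"))

    def test_null_contrast_on_equal_scenario(self):
        cfg = ScenarioConfig(
            n_plots=250,
            nes_true={"bryophyte": 25.0, "vascular": 25.0},
            seed=302,
        )
        data = generate_scenario(cfg)
        sv = build_surveys(data.plots, data.traits, data.occurrences)
        trends, _ = build_trends(sv, estimate_lapses(sv, data.plots))
        fit = fit_nes_lineage(trends)
        assert abs(fit.coef("vascular")) < 2.5 * fit.se("vascular")

    def test_homoscedastic_residuals_give_small_delta(self):
        rng = np.random.default_rng(303)
        trends = make_nes_trends(rng, n_plots=600, sd_b=60.0, sd_v=60.0)
        est = NESLineageLMM().fit(trends)
        assert abs(est.variance_power_) < 0.2

    def test_heteroscedastic_residuals_give_negative_delta(self):
        """Residual SD shrinking with species number must surface as
        a negative power exponent."""
        rng = np.random.default_rng(304)
        trends = make_nes_trends(rng, n_plots=500, sd_b=0.0, sd_v=0.0, tau=10.0)
        noise = rng.normal(0, 300.0, len(trends)) / np.sqrt(trends["mean_n_with_t"])
        trends["nes_m_per_decade"] += noise
        est = NESLineageLMM().fit(trends)
        assert est.variance_power_ < -0.25

    def test_single_lineage_rejected(self):
        rng = np.random.default_rng(305)
        trends = make_nes_trends(rng, n_plots=30)
        with pytest.raises(ValueError, match="both lineages"):
            fit_nes_lineage(trends[trends["lineage"] == "bryophyte"])


def make_full_model_data(rng, n_plots=400, interactions=None):
    """NES table + plot table following the full-model structure exactly."""
    interactions = interactions or {}
    elev = rng.uniform(268, 3060, n_plots)
    lu = rng.choice(["managed_grassland", "forest", "unmanaged_open"], n_plots,
                    p=[0.5, 0.35, 0.15])
    plots = pd.DataFrame(
        {
            "plot_id": [f"p{i:04d}" for i in range(n_plots)],
            "elevation_m": elev,
            "land_use": lu,
            "zone": "montane",
        }
    )
    shared = rng.normal(0, 20.0, n_plots)
    rows = []
    for i in range(n_plots):
        ez = (elev[i] - 514.0) / 100.0
        for lineage, sd in (("bryophyte", 80.0), ("vascular", 40.0)):
            vas = 1.0 if lineage == "vascular" else 0.0
            mean = (
                25.0
                - 12.0 * vas
                + 1.5 * ez
                - 8.0 * (lu[i] == "forest")
                - 4.0 * (lu[i] == "unmanaged_open")
                + interactions.get("vascular:elev_z", 0.0) * vas * ez
            )
            rows.append(
                (
                    plots["plot_id"].iat[i], lineage,
                    mean + shared[i] + rng.normal(0, sd),
                    rng.poisson(9 if lineage == "bryophyte" else 25) + 1,
                )
            )
    trends = pd.DataFrame(
        rows, columns=["plot_id", "lineage", "nes_m_per_decade", "mean_n_with_t"]
    )
    return trends, plots


class TestNESFull:
    def test_pruning_contract_and_reduced_refit(self):
        """Dropped interactions all had p >= 0.05, retained ones p < 0.05,
        main effects always kept — and the reduced fit equals a direct fit
        with exactly the retained terms."""
        rng = np.random.default_rng(401)
        trends, plots = make_full_model_data(rng, n_plots=400)
        est = NESFullLMM().fit(trends, plots)
        anova = est.anova_.set_index("term")
        for term in est.dropped_interactions_:
            assert anova.loc[term, "p"] >= 0.05
        for term in est.reduced_terms_:
            if ":" in term:
                assert anova.loc[term, "p"] < 0.05
        for main in ("lineage", "elevation", "land_use"):
            assert main in est.reduced_terms_

        direct = NESFullLMM(estimate_power=True)
        lmm_direct, _, _ = direct._fit_terms(
            trends.merge(plots[["plot_id", "elevation_m", "land_use"]], on="plot_id"),
            est.reduced_terms_,
            np.maximum(trends["mean_n_with_t"].to_numpy(float), 0.5),
        )
        np.testing.assert_allclose(
            est.reduced_lmm_.coef_.to_numpy(), lmm_direct.coef_.to_numpy(), atol=1e-6
        )

    def test_injected_interaction_retained(self):
        rng = np.random.default_rng(402)
        trends, plots = make_full_model_data(
            rng, n_plots=400, interactions={"vascular:elev_z": 6.0}
        )
        est = NESFullLMM().fit(trends, plots)
        assert "lineage:elevation" in est.reduced_terms_

    def test_intercept_is_colline_reference_prediction(self):
        """With elevation centred at 514 m, the intercept predicts the
        bryophyte NES in managed grasslands at 514 m a.s.l."""
        rng = np.random.default_rng(403)
        trends, plots = make_full_model_data(rng, n_plots=500)
        est = NESFullLMM().fit(trends, plots)
        # truth at the reference point is 25.0
        co = est.reduced_lmm_
        assert co.coef_["intercept"] == pytest.approx(
            25.0, abs=3 * co.bse_["intercept"]
        )

    def test_missing_plot_covariates_rejected(self):
        rng = np.random.default_rng(404)
        trends, plots = make_full_model_data(rng, n_plots=50)
        with pytest.raises(ValueError, match="land_use"):
            NESFullLMM().fit(trends, plots.drop(columns="land_use"))


@pytest.fixture(scope="module")
def strategy_trends():
    cfg = ScenarioConfig(n_plots=300, seed=501)
    data = generate_scenario(cfg)
    trends = []
    sv_all = build_surveys(data.plots, data.traits, data.occurrences)
    lapses = estimate_lapses(sv_all, data.plots)
    for subset in ("short_lived", "long_lived"):
        tr = subset_traits(data.traits, subset)
        occ = data.occurrences[data.occurrences["species_id"].isin(tr["species_id"])]
        sv = build_surveys(data.plots, tr, occ)
        t, _ = build_trends(sv, lapses, subset=subset)
        trends.append(t)
    return pd.concat(trends, ignore_index=True), data.plots


class TestLifeStrategy:

    def test_null_contrast_when_dynamics_identical(self, strategy_trends):
        trends, plots = strategy_trends
        est = LifeStrategyLMM().fit(trends[trends["lineage"] == "vascular"], plots)
        assert abs(est.strategy_effect_) < 3 * est.lmm_.bse_["long_lived"]

    def test_faster_short_lived_detected(self):
        cfg = ScenarioConfig(
            n_plots=500,
            nes_longevity_offset={"short_lived": 60.0, "long_lived": 0.0, "unclassified": 0.0},
            seed=502,
        )
        data = generate_scenario(cfg)
        sv_all = build_surveys(data.plots, data.traits, data.occurrences)
        lapses = estimate_lapses(sv_all, data.plots)
        trends = []
        for subset in ("short_lived", "long_lived"):
            tr = subset_traits(data.traits, subset)
            occ = data.occurrences[data.occurrences["species_id"].isin(tr["species_id"])]
            t, _ = build_trends(build_surveys(data.plots, tr, occ), lapses, subset=subset)
            trends.append(t)
        trends = pd.concat(trends, ignore_index=True)
        est = LifeStrategyLMM().fit(trends[trends["lineage"] == "vascular"], plots=data.plots)
        se = float(est.lmm_.bse_["long_lived"])
        assert est.strategy_effect_ < 0
        assert est.strategy_effect_ == pytest.approx(-60.0, abs=4 * se)

    def test_empty_subset_rejected(self, strategy_trends):
        trends, plots = strategy_trends
        only_short = trends[trends["subset"] == "short_lived"]
        with pytest.raises(ValueError, match="long_lived"):
            LifeStrategyLMM().fit(only_short, plots)

    def test_missing_land_use_rejected(self, strategy_trends):
        trends, plots = strategy_trends
        with pytest.raises(ValueError, match="land_use"):
            LifeStrategyLMM().fit(trends, plots.drop(columns="land_use"))


class TestStrata:
    def test_low_representation_strata_skipped(self):
        data = generate_scenario(ScenarioConfig(n_plots=600, seed=601))
        eligible, skipped = iter_strata(data.plots, min_plots=14)
        assert ("montane", "forest") in eligible
        skipped_pairs = set(zip(skipped["zone"], skipped["land_use"]))
        # unmanaged open areas are rare below the alpine zone by design
        assert ("colline", "unmanaged_open") in skipped_pairs or (
            "montane", "unmanaged_open") in skipped_pairs
        for row in skipped.itertuples():
            assert row.n_plots < 14
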