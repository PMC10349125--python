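"""Generator contracts: determinism, signal injection, missingness, infill."""

import numpy as np
import pandas as pd
import pytest

from thermoshift.community import build_surveys
from thermoshift.simulate import ScenarioConfig, generate_scenario, truth_table
from thermoshift.trends import build_trends, estimate_lapses, fit_plot_trend


def _mean_plot_slope(data):
    sv = build_surveys(data.plots, data.traits, data.occurrences)
    slopes = [
        fit_plot_trend(g["year"], g["cti"])
        for _, g in sv.groupby(["plot_id", "lineage"])
    ]
    slopes = np.array([s for s in slopes if np.isfinite(s)])
    return slopes.mean(), slopes.std(ddof=1) / np.sqrt(slopes.size)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = ScenarioConfig(n_plots=40, seed=5)
        d1 = generate_scenario(cfg)
        d2 = generate_scenario(cfg)
        pd.testing.assert_frame_equal(d1.plots, d2.plots)
        pd.testing.assert_frame_equal(d1.traits, d2.traits)
        pd.testing.assert_frame_equal(d1.occurrences, d2.occurrences)
        assert d1.temperature == d2.temperature

    def test_different_seeds_differ(self):
        cfg = ScenarioConfig(n_plots=40)
        d1 = generate_scenario(cfg, seed=1)
        d2 = generate_scenario(cfg, seed=2)
        assert not d1.occurrences.equals(d2.occurrences)


class TestSignalInjection:
    def test_zero_signal_mean_slope_near_zero(self):
        cfg = ScenarioConfig(
            n_plots=200,
            nes_true={"bryophyte": 0.0, "vascular": 0.0},
            plot_nes_sd=0.0,
            seed=21,
        )
        mean, se = _mean_plot_slope(generate_scenario(cfg))
        assert abs(mean) < 3 * se

    def test_worked_example_inversion(self):
        """NES 100 at lapse 0.1/100 m implies a CTI trend of 0.01 per year."""
        cfg = ScenarioConfig(
            n_plots=200,
            lapse_true={"bryophyte": 0.1, "vascular": 0.1},
            nes_true={"bryophyte": 100.0, "vascular": 100.0},
            plot_nes_sd=0.0,
            seed=22,
        )
        mean, se = _mean_plot_slope(generate_scenario(cfg))
        assert mean == pytest.approx(0.01, abs=3 * se)
        assert abs(mean - 0.01) < 0.003

    def test_lapse_emerges_in_cross_section(self, small_scenario):
        cfg, data = small_scenario
        sv = build_surveys(data.plots, data.traits, data.occurrences)
        lapses = estimate_lapses(sv, data.plots)
        for lineage in ("bryophyte", "vascular"):
            assert lapses[lineage].lapse_per_100m == pytest.approx(
                -cfg.lapse_true[lineage], abs=4 * lapses[lineage].se_per_100m
            )

    def test_nes_recovery_per_stratum(self):
        """Stratum NES offsets propagate through trend estimation."""
        cfg = ScenarioConfig(
            n_plots=400,
            nes_true={"bryophyte": 50.0, "vascular": 50.0},
            nes_land_use_offset={"managed_grassland": 0.0, "forest": -30.0, "unmanaged_open": 0.0},
            plot_nes_sd=0.0,
            seed=23,
        )
        data = generate_scenario(cfg)
        sv = build_surveys(data.plots, data.traits, data.occurrences)
        trends, _ = build_trends(sv, estimate_lapses(sv, data.plots))
        joined = trends.merge(data.plots[["plot_id", "land_use"]], on="plot_id")
        for lu, expected in (("managed_grassland", 50.0), ("forest", 20.0)):
            grp = joined[joined["land_use"] == lu]["nes_m_per_decade"]
            se = grp.std(ddof=1) / np.sqrt(len(grp))
            assert grp.mean() == pytest.approx(expected, abs=4 * se)


class TestTraitStructure:
    def test_missingness_fraction(self, small_scenario):
        cfg, data = small_scenario
        for lineage in ("bryophyte", "vascular"):
            tr = data.traits[data.traits["lineage"] == lineage]
            frac = tr["temperature_value"].isna().mean()
            binom_se = np.sqrt(frac * (1 - frac) / len(tr)) + 1e-9
            assert frac == pytest.approx(
                cfg.trait_missingness[lineage], abs=max(4 * binom_se, 0.01)
            )

    def test_species_values_consistent_across_occurrences(self, small_scenario):
        """One species carries one temperature value: the trait table is
        the single source, so every occurrence of a species shares it."""
        _, data = small_scenario
        assert not data.traits["species_id"].duplicated().any()

    def test_clamping_below_one_percent(self, small_scenario):
        _, data = small_scenario
        assert data.clamp_fraction < 0.01

    def test_grid_values_only(self, small_scenario):
        _, data = small_scenario
        vals = data.traits["temperature_value"].dropna()
        assert ((vals * 2) == (vals * 2).round()).all()
        assert vals.between(1.0, 5.0).all()


class TestInfill:
    def test_infill_signature(self):
        """Cryophilic counts stay flat; meso/thermo counts increase."""
        cfg = ScenarioConfig(n_plots=150, infill=True, seed=31)
        data = generate_scenario(cfg)
        sv = build_surveys(data.plots, data.traits, data.occurrences)
        by_year = sv.groupby("year")[["n_cryo", "n_meso", "n_thermo"]].mean()
        years = by_year.index.to_numpy(dtype=float)

        def slope(col):
            y = by_year[col].to_numpy()
            xc = years - years.mean()
            return (xc * (y - y.mean())).sum() / (xc * xc).sum()

        assert slope("n_thermo") > 0
        assert slope("n_meso") > 0
        assert abs(slope("n_cryo")) < 0.5 * slope("n_meso")

    def test_richness_grows_only_through_warm_classes(self):
        cfg = ScenarioConfig(n_plots=150, infill=True, seed=32)
        data = generate_scenario(cfg)
        sv = build_surveys(data.plots, data.traits, data.occurrences)
        first, last = sv["year"].min(), sv["year"].max()
        cryo_first = sv[sv["year"] == first]["n_cryo"].mean()
        cryo_last = sv[sv["year"] == last]["n_cryo"].mean()
        mc = np.sqrt(cryo_first / (sv["year"] == first).sum()) * 4
        assert abs(cryo_last - cryo_first) < max(3 * mc, 0.5)


class TestTruthTable:
    def test_nes_slope_algebra(self):
        cfg = ScenarioConfig(
            nes_true={"bryophyte": 100.0, "vascular": 100.0},
            lapse_true={"bryophyte": 0.1, "vascular": 0.1},
        )
        tt = truth_table(cfg)
        assert np.allclose(tt["slope_true_per_yr"], 0.01)

    def test_infill_count_trends(self):
        tt = truth_table(ScenarioConfig(infill=True, infill_rate=0.04))
        assert (tt["cryo_count_trend"] == 0.0).all()
        assert (tt["meso_count_trend"] == 0.04).all()
        tt_off = truth_table(ScenarioConfig(infill=False))
        assert tt_off["cryo_count_trend"].isna().all()

    def test_warming_conversion(self):
        tt = truth_table(ScenarioConfig(warming_true=0.42))
        assert np.allclose(tt["warming_slope_per_yr"], 0.042)


class TestConfigValidation:
    def test_empty_survey_years(self):
        with pytest.raises(ValueError):
            ScenarioConfig(survey_years=()).validate()

    def test_negative_richness(self):
        with pytest.raises(ValueError):
            ScenarioConfig(richness_mean={"bryophyte": -1.0, "vascular": 27.3}).validate()

    def test_nonpositive_lapse(self):
        with pytest.raises(ValueError):
            ScenarioConfig(lapse_true={"bryophyte": 0.0, "vascular": 0.098}).validate()

    def test_land_use_probabilities_must_sum_to_one(self):
        rule = {
            "colline": {"managed_grassland": 0.5, "forest": 0.4, "unmanaged_open": 0.2}
        }
        with pytest.raises(ValueError):
            ScenarioConfig(land_use_rule=rule).validate()
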