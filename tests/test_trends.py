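"""Per-plot trends, lapse regression, NES formula and isotherm shifts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoshift.datamodel import TemperatureSeries
from thermoshift.trends import (
    build_trends,
    compute_nes,
    estimate_lapse,
    estimate_lapses,
    estimate_warming,
    fit_plot_trend,
    isotherm_shift,
)


def ols_slope_oracle(x, y):
    """Closed-form OLS slope: sum (x-xbar)(y-ybar) / sum (x-xbar)^2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / (xc * xc).sum())


class TestFitPlotTrend:
    def test_exact_linear(self):
        assert fit_plot_trend([2001, 2006, 2011], [3.00, 3.05, 3.10]) == pytest.approx(0.01)

    def test_constant_series(self):
        assert fit_plot_trend([2001, 2006, 2011, 2016], [2.5] * 4) == pytest.approx(0.0)

    def test_undefined_below_two_points(self):
        assert math.isnan(fit_plot_trend([2001], [3.0]))
        assert math.isnan(fit_plot_trend([2001, 2006], [3.0, float("nan")]))
        assert math.isnan(fit_plot_trend([2001, 2001], [3.0, 3.2]))

    @settings(max_examples=200, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(min_value=1990, max_value=2030),
                st.floats(min_value=1.0, max_value=5.0),
            ),
            min_size=2,
            max_size=8,
            unique_by=lambda t: t[0],
        ).filter(lambda d: len({t[0] for t in d}) >= 2)
    )
    def test_agrees_with_closed_form_oracle(self, data):
        years, ctis = zip(*data)
        assert fit_plot_trend(years, ctis) == pytest.approx(
            ols_slope_oracle(years, ctis), abs=1e-6
        )


class TestEstimateLapse:
    def test_two_point_line_with_padding(self):
        # 3 plots on an exact -0.1/100 m line
        elev = [500.0, 1000.0, 1500.0]
        cti = [3.0, 2.5, 2.0]
        est = estimate_lapse(elev, cti, lineage="vascular")
        assert est.lapse_per_100m == pytest.approx(-0.1)
        assert est.r_squared == pytest.approx(1.0)

    def test_flat_cti(self):
        est = estimate_lapse([500, 1000, 1500, 2000], [3.0] * 4)
        assert est.lapse_per_100m == pytest.approx(0.0)
        assert est.r_squared == pytest.approx(0.0)

    def test_degenerate_elevations_rejected(self):
        with pytest.raises(ValueError):
            estimate_lapse([500, 500, 500], [3.0, 2.9, 3.1])

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError):
            estimate_lapse([500, 1000], [3.0, 2.5])


class TestComputeNes:
    def test_worked_example(self):
        assert compute_nes(0.01, 0.1) == pytest.approx(100.0)

    def test_zero_rate(self):
        assert compute_nes(0.0, 0.082) == 0.0

    def test_direct_evaluation(self):
        assert compute_nes(0.00244, 0.082) == pytest.approx(29.7561, abs=1e-3)

    def test_nonpositive_lapse_rejected(self):
        with pytest.raises(ValueError):
            compute_nes(0.01, 0.0)
        with pytest.raises(ValueError):
            compute_nes(0.01, -0.1)

    @settings(max_examples=100, derandomize=True)
    @given(
        slope=st.floats(min_value=-0.05, max_value=0.05),
        lapse=st.floats(min_value=0.01, max_value=0.5),
        a=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_linearity_and_scale_equivariance(self, slope, lapse, a):
        base = compute_nes(slope, lapse)
        # linear in the thermophilisation rate
        assert compute_nes(a * slope, lapse) == pytest.approx(a * base, rel=1e-9, abs=1e-9)
        # invariant under a common rescaling of rate and lapse
        assert compute_nes(a * slope, a * lapse) == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestEstimateWarming:
    def test_noiseless_line(self):
        years = tuple(range(2001, 2022))
        temps = tuple(6.0 + 0.042 * (y - 2001) for y in years)
        rate, r2, _ = estimate_warming(TemperatureSeries(years, temps))
        assert rate == pytest.approx(0.42)
        assert r2 == pytest.approx(1.0)

    def test_constant_series(self):
        years = tuple(range(2001, 2012))
        rate, r2, _ = estimate_warming(TemperatureSeries(years, (7.0,) * 11))
        assert rate == pytest.approx(0.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            estimate_warming(TemperatureSeries((2001, 2002), (5.0, 5.1)))


class TestIsothermShift:
    def test_reported_window(self):
        shift = isotherm_shift(0.42, (0.5, 0.67))
        assert shift.shift_low == pytest.approx(62.6866, abs=1e-3)
        assert shift.shift_high == pytest.approx(84.0)
        assert shift.rounded == (63, 84)

    def test_zero_warming(self):
        shift = isotherm_shift(0.0, (0.5, 0.67))
        assert (shift.shift_low, shift.shift_high) == (0.0, 0.0)

    def test_degenerate_bounds(self):
        shift = isotherm_shift(0.5, (0.5, 0.5))
        assert shift.shift_low == shift.shift_high == pytest.approx(100.0)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            isotherm_shift(0.42, (0.0, 0.5))


class TestBuildTrends:
    def _surveys(self):
        return pd.DataFrame(
            {
                "plot_id": ["p1"] * 3 + ["p2"],
                "lineage": ["bryophyte"] * 4,
                "year": [2001, 2006, 2011, 2001],
                "n_species": [5, 5, 5, 4],
                "n_with_t": [4, 4, 4, 3],
                "cti": [3.0, 3.05, 3.10, 2.0],
                "n_cryo": [1, 1, 1, 2],
                "n_meso": [2, 2, 2, 1],
                "n_thermo": [1, 1, 1, 0],
            }
        )

    def _lapses(self, small_scenario_like=None):
        from thermoshift.trends import LapseEstimate

        return {
            "bryophyte": LapseEstimate("bryophyte", -0.1, 0.01, 3.5, 0.9, 1e-5, 100)
        }

    def test_exclusion_of_single_survey_community(self):
        trends, excl = build_trends(self._surveys(), self._lapses())
        assert list(trends["plot_id"]) == ["p1"]
        assert trends.iloc[0]["slope_per_yr"] == pytest.approx(0.01)
        assert trends.iloc[0]["nes_m_per_decade"] == pytest.approx(100.0)
        assert list(excl["plot_id"]) == ["p2"]
        assert excl.iloc[0]["reason"] == "fewer than two CTI values"

    def test_positive_lapse_aborts(self):
        from thermoshift.trends import LapseEstimate

        lapses = {"bryophyte": LapseEstimate("bryophyte", 0.05, 0.01, 2.0, 0.5, 0.1, 100)}
        with pytest.raises(ValueError, match="decline"):
            build_trends(self._surveys(), lapses)

    def test_lapse_recovery_from_scenario(self, small_scenario):
        """Synthetic truth: estimated lapse within sampling error of -0.082/-0.098."""
        cfg, data = small_scenario
        from thermoshift.community import build_surveys

        sv = build_surveys(data.plots, data.traits, data.occurrences)
        lapses = estimate_lapses(sv, data.plots)
        for lineage in ("bryophyte", "vascular"):
            est = lapses[lineage]
            assert est.lapse_per_100m < 0
            assert abs(est.lapse_per_100m + cfg.lapse_true[lineage]) < 4 * est.se_per_100m
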