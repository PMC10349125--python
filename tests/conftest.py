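import numpy as np
import pandas as pd
import pytest

from thermoshift.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A compact default-truth scenario shared across read-only tests."""
    cfg = ScenarioConfig(n_plots=250, seed=11)
    return cfg, generate_scenario(cfg)


@pytest.fixture()
def toy_tables(tmp_path):
    """Three-row hand-written tables on disk."""
    plots = tmp_path / "plots.csv"
    plots.write_text(
        "plot_id,elevation_m,land_use\n"
        "p1,514,managed_grassland\n"
        "p2,1200,forest\n"
        "p3,2500,unmanaged_open\n"
    )
    traits = tmp_path / "traits.csv"
    traits.write_text(
        "species_id,lineage,temperature_value,strategy_code\n"
        "s1,bryophyte,2.5,colonist\n"
        "s2,vascular,3.0,ccc\n"
        "s3,vascular,,crs\n"
    )
    occ = tmp_path / "occurrences.csv"
    occ.write_text(
        "plot_id,year,species_id\n"
        "p1,2001,s1\n"
        "p1,2001,s2\n"
        "p2,2006,s3\n"
    )
    return plots, traits, occ


def make_lmm_data(rng, n_groups=50, n_per=4, slope=0.5, tau=1.0, sigma=0.7):
    """Random-intercept regression data with known fixed effects."""
    g = np.repeat(np.arange(n_groups), n_per)
    x = rng.normal(size=n_groups * n_per)
    b = rng.normal(0.0, tau, n_groups)
    y = 1.0 + slope * x + b[g] + rng.normal(0.0, sigma, g.size)
    X = pd.DataFrame({"intercept": np.ones(g.size), "x": x})
    return X, y, g
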