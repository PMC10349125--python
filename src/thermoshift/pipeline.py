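"""End-to-end orchestration: simulate → CTI → trends → models → report.

Every stage reads and writes flat CSVs in one run directory, so each
number in the final report can be traced to a file.  A single seed governs
all randomness; rerunning with the same config and seed reproduces every
output byte for byte.

Standard file names inside a run directory:

    plots.csv traits.csv occurrences.csv temperature.csv truth.csv
    surveys.csv surveys_short_lived.csv surveys_long_lived.csv
    trends.csv exclusions.csv lapse.csv isotherms.csv
    models/coefficients_<model_id>.csv models/models_index.csv
    models/anova_nes_full.csv models/skipped_strata.csv
    report.md manifest.yaml
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import CRYO_MAX, THERMO_MIN, build_surveys
from .datamodel import DEFAULT_ZONE_THRESHOLDS, TemperatureSeries
from .io import (
    read_occurrences,
    read_plots,
    read_temperature,
    read_traits,
    write_occurrences,
    write_plots,
    write_temperature,
    write_traits,
    _write_csv,
)
from .models import (
    MIN_PLOTS_DEFAULT,
    ModelFit,
    fit_cti_trend,
    fit_count_trend,
    fit_life_strategy,
    fit_nes_full,
    fit_nes_lineage,
    iter_strata,
)
from .simulate import ScenarioConfig, generate_scenario, truth_table
from .strategies import subset_traits
from .trends import (
    DEFAULT_ADIABATIC_BOUNDS,
    build_trends,
    estimate_lapses,
    estimate_warming,
    isotherm_shift,
)

log = logging.getLogger(__name__)

_AFFINITY_COUNT_COLS = {
    "cryophilic": "n_cryo",
    "mesophilic": "n_meso",
    "thermophilic": "n_thermo",
}


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    #: Either a synthetic scenario ...
    scenario: ScenarioConfig | None = None
    #: ... or paths to real input tables.
    plots_csv: str | None = None
    traits_csv: str | None = None
    occurrences_csv: str | None = None
    temperature_csv: str | None = None
    out_dir: str = "run"
    seed: int = 0
    adiabatic_bounds: tuple[float, float] = DEFAULT_ADIABATIC_BOUNDS
    cryo_max: float = CRYO_MAX
    thermo_min: float = THERMO_MIN
    zone_thresholds: tuple[float, float, float] = DEFAULT_ZONE_THRESHOLDS
    bootstrap_b: int = 1000
    min_plots: int = MIN_PLOTS_DEFAULT
    count_models_by_zone: bool = False
    make_figures: bool = False
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        has_paths = all(
            p is not None
            for p in (self.plots_csv, self.traits_csv, self.occurrences_csv)
        )
        if self.scenario is None and not has_paths:
            raise ValueError(
                "RunConfig needs either a scenario or the three input table paths"
            )
        if self.scenario is not None and has_paths:
            raise ValueError("give either a scenario or input paths, not both")
        return self


# ------------------------------------------------------------------ stages


def stage_simulate(scenario: ScenarioConfig, seed: int, out_dir: str | Path) -> None:
    """Generate the four input tables plus the truth table into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate_scenario(scenario, seed=seed)
    write_plots(data.plots, out / "plots.csv")
    write_traits(data.traits, out / "traits.csv")
    write_occurrences(data.occurrences, out / "occurrences.csv")
    write_temperature(data.temperature, out / "temperature.csv")
    _write_csv(
        truth_table(scenario),
        out / "truth.csv",
        float_cols=[
            "nes_true_m_per_decade", "slope_true_per_yr", "lapse_per_100m",
            "cryo_count_trend", "meso_count_trend", "thermo_count_trend",
            "warming_slope_per_yr",
        ],
    )
    if data.clamp_fraction > 0.01:
        log.warning(
            "indicator draws clamped to the [1, 5] grid in %.2f%% of cases "
            "(>1%%): the latent gradient saturates", 100 * data.clamp_fraction,
        )
    log.info(
        "simulate: %d plots, %d occurrence rows, clamping %.3f%%",
        len(data.plots), len(data.occurrences), 100 * data.clamp_fraction,
    )


def _survey_float_cols() -> list[str]:
    return ["cti"]


def stage_cti(run_dir: str | Path, cryo_max: float = CRYO_MAX,
              thermo_min: float = THERMO_MIN,
              zone_thresholds=DEFAULT_ZONE_THRESHOLDS) -> pd.DataFrame:
    """Build the community table (all species) and per-longevity subsets."""
    run = Path(run_dir)
    plots = read_plots(run / "plots.csv", zone_thresholds)
    traits = read_traits(run / "traits.csv")
    occurrences = read_occurrences(run / "occurrences.csv", plots)
    surveys = build_surveys(plots, traits, occurrences, cryo_max, thermo_min)
    _write_csv(surveys, run / "surveys.csv", float_cols=_survey_float_cols())
    for longevity in ("short_lived", "long_lived"):
        tr = subset_traits(traits, longevity)
        occ = occurrences[occurrences["species_id"].isin(tr["species_id"])]
        sub = build_surveys(plots, tr, occ, cryo_max, thermo_min)
        _write_csv(
            sub, run / f"surveys_{longevity}.csv", float_cols=_survey_float_cols()
        )
    return surveys


def stage_trends(
    run_dir: str | Path,
    adiabatic_bounds: tuple[float, float] = DEFAULT_ADIABATIC_BOUNDS,
    zone_thresholds=DEFAULT_ZONE_THRESHOLDS,
) -> pd.DataFrame:
    """Lapse estimates, per-community trends/NES, warming and isotherms."""
    run = Path(run_dir)
    plots = read_plots(run / "plots.csv", zone_thresholds)
    surveys = pd.read_csv(run / "surveys.csv")
    lapses = estimate_lapses(surveys, plots)

    all_trends, all_excl = [], []
    trends, excl = build_trends(surveys, lapses, subset="all")
    all_trends.append(trends)
    all_excl.append(excl)
    for longevity in ("short_lived", "long_lived"):
        path = run / f"surveys_{longevity}.csv"
        if path.exists():
            sub = pd.read_csv(path)
            tr, ex = build_trends(sub, lapses, subset=longevity)
            all_trends.append(tr)
            all_excl.append(ex)
    trends_df = pd.concat(all_trends, ignore_index=True)
    _write_csv(
        trends_df, run / "trends.csv",
        float_cols=["mean_n_with_t", "slope_per_yr", "nes_m_per_decade"],
    )
    _write_csv(pd.concat(all_excl, ignore_index=True), run / "exclusions.csv")

    lapse_df = pd.DataFrame(
        [
            {
                "lineage": lap.lineage,
                "lapse_per_100m": lap.lapse_per_100m,
                "se_per_100m": lap.se_per_100m,
                "intercept": lap.intercept,
                "r_squared": lap.r_squared,
                "p_value": lap.p_value,
                "n_plots": lap.n_plots,
            }
            for lap in lapses.values()
        ]
    )
    _write_csv(
        lapse_df, run / "lapse.csv",
        float_cols=["lapse_per_100m", "se_per_100m", "intercept", "r_squared", "p_value"],
    )

    temp_path = run / "temperature.csv"
    if temp_path.exists():
        series = read_temperature(temp_path)
        warming, r2, p = estimate_warming(series)
        shift = isotherm_shift(warming, adiabatic_bounds)
        iso_df = pd.DataFrame(
            [
                {
                    "warming_c_per_decade": warming,
                    "r_squared": r2,
                    "p_value": p,
                    "adiabatic_low": shift.adiabatic_lapse_low,
                    "adiabatic_high": shift.adiabatic_lapse_high,
                    "shift_low_m_per_decade": shift.shift_low,
                    "shift_high_m_per_decade": shift.shift_high,
                    "shift_low_rounded": shift.rounded[0],
                    "shift_high_rounded": shift.rounded[1],
                }
            ]
        )
        _write_csv(
            iso_df, run / "isotherms.csv",
            float_cols=[
                "warming_c_per_decade", "r_squared", "p_value", "adiabatic_low",
                "adiabatic_high", "shift_low_m_per_decade", "shift_high_m_per_decade",
            ],
        )
    return trends_df


def _fit_to_rows(fit: ModelFit) -> pd.DataFrame:
    coef = fit.coefficients.copy()
    coef.insert(0, "model_id", fit.model_id)
    if fit.ci is not None:
        coef = coef.merge(fit.ci, on="term", how="left")
        coef["ci_method"] = fit.ci_method
    return coef


def stage_models(
    run_dir: str | Path,
    families: tuple[str, ...] = ("cti", "nes-lineage", "nes-full", "counts", "life-strategy"),
    bootstrap_b: int = 1000,
    min_plots: int = MIN_PLOTS_DEFAULT,
    seed: int = 0,
    count_models_by_zone: bool = False,
    zone_thresholds=DEFAULT_ZONE_THRESHOLDS,
) -> dict[str, ModelFit]:
    """Fit the requested model families; write tidy CSVs per model."""
    run = Path(run_dir)
    mdir = run / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    plots = read_plots(run / "plots.csv", zone_thresholds)
    surveys = pd.read_csv(run / "surveys.csv")
    trends = pd.read_csv(run / "trends.csv")
    trends_all = trends[trends["subset"] == "all"]

    fits: dict[str, ModelFit] = {}
    skipped: list[dict] = []
    seed_seq = np.random.SeedSequence(seed)

    if "cti" in families:
        sv = surveys.merge(plots[["plot_id", "zone", "land_use"]], on="plot_id")
        eligible, skipped_df = iter_strata(plots, min_plots)
        for row in skipped_df.itertuples():
            skipped.append(
                {"family": "cti", "stratum": f"{row.zone}/{row.land_use}",
                 "reason": row.reason}
            )
        for lineage in sorted(sv["lineage"].unique()):
            for zone, lu in eligible:
                stratum = sv[
                    (sv["lineage"] == lineage) & (sv["zone"] == zone)
                    & (sv["land_use"] == lu)
                ][["plot_id", "year", "cti"]]
                model_id = f"cti_{lineage}_{zone}_{lu}"
                child = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                res = fit_cti_trend(
                    stratum, bootstrap_b=bootstrap_b, min_plots=min_plots,
                    random_state=child, model_id=model_id,
                )
                if isinstance(res, str):
                    skipped.append(
                        {"family": "cti", "stratum": model_id, "reason": res}
                    )
                else:
                    fits[model_id] = res

    if "nes-lineage" in families:
        fits["nes_lineage"] = fit_nes_lineage(trends_all)

    if "nes-full" in families:
        full, reduced = fit_nes_full(trends_all, plots)
        fits["nes_full"] = full
        fits["nes_reduced"] = reduced
        _write_csv(
            full.anova, mdir / "anova_nes_full.csv",
            float_cols=["f_value", "df_den", "p"],
        )

    if "counts" in families:
        sv = surveys.merge(plots[["plot_id", "zone"]], on="plot_id")
        zone_groups = [("all", sv)]
        if count_models_by_zone:
            zone_groups += [(z, g) for z, g in sv.groupby("zone", sort=True)]
        for lineage in sorted(sv["lineage"].unique()):
            for zname, zdata in zone_groups:
                for affinity, col in _AFFINITY_COUNT_COLS.items():
                    stratum = zdata[zdata["lineage"] == lineage][
                        ["plot_id", "year", col]
                    ].rename(columns={col: "n"})
                    model_id = f"counts_{lineage}_{zname}_{affinity}"
                    res = fit_count_trend(stratum, model_id=model_id)
                    if isinstance(res, str):
                        skipped.append(
                            {"family": "counts", "stratum": model_id, "reason": res}
                        )
                    else:
                        fits[model_id] = res

    if "life-strategy" in families:
        subsets = trends[trends["subset"].isin(["short_lived", "long_lived"])]
        for lineage in sorted(subsets["lineage"].unique()):
            try:
                fits[f"life_strategy_{lineage}"] = fit_life_strategy(
                    subsets, plots, lineage
                )
            except ValueError as err:
                skipped.append(
                    {"family": "life-strategy", "stratum": lineage, "reason": str(err)}
                )

    index_rows = []
    for model_id in sorted(fits):
        fit = fits[model_id]
        _write_csv(
            _fit_to_rows(fit), mdir / f"coefficients_{model_id}.csv",
            float_cols=[
                c for c in ("estimate", "se", "t", "z", "p", "ddf", "lower", "upper")
                if c in _fit_to_rows(fit).columns
            ],
        )
        index_rows.append(
            {
                "model_id": model_id,
                "formula": fit.formula,
                "n_obs": fit.n_obs,
                "n_groups": fit.n_groups,
                "converged": fit.converged,
                "variance_power": np.nan if fit.variance_power is None else fit.variance_power,
                "notes": "; ".join(fit.notes),
            }
        )
    _write_csv(
        pd.DataFrame(index_rows), mdir / "models_index.csv",
        float_cols=["variance_power"],
    )
    _write_csv(
        pd.DataFrame(skipped, columns=["family", "stratum", "reason"]),
        mdir / "skipped_strata.csv",
    )
    return fits


# ------------------------------------------------------------------ report


def _fmt(x: float, nd: int = 2) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{nd}f}"


def _md_table(df: pd.DataFrame, nd: int = 2) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        cells = [
            _fmt(v, nd) if isinstance(v, (float, np.floating)) else str(v)
            for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def stage_report(run_dir: str | Path, make_figures: bool = False) -> str:
    """Assemble report.md from the stage outputs; returns the text."""
    run = Path(run_dir)
    plots = pd.read_csv(run / "plots.csv")
    surveys = pd.read_csv(run / "surveys.csv")
    trends = pd.read_csv(run / "trends.csv")
    lapse = pd.read_csv(run / "lapse.csv")
    mdir = run / "models"

    parts: list[str] = []
    parts.append("# Thermophilisation analysis report\n")
    parts.append(
        f"Plots: {plots['plot_id'].nunique()}; communities (plot x lineage x "
        f"year): {len(surveys)}; communities with a defined CTI: "
        f"{int(surveys['cti'].notna().sum())}.\n"
    )

    parts.append("## Elevational CTI lapse\n")
    parts.append(_md_table(
        lapse[["lineage", "lapse_per_100m", "r_squared", "p_value", "n_plots"]], nd=4
    ) + "\n")

    iso_path = run / "isotherms.csv"
    if iso_path.exists():
        iso = pd.read_csv(iso_path).iloc[0]
        parts.append("## Shift of isotherms\n")
        parts.append(
            f"Warming {_fmt(iso['warming_c_per_decade'])} °C/decade "
            f"(R² = {_fmt(iso['r_squared'], 4)}, p = {_fmt(iso['p_value'], 3)}); "
            f"adiabatic lapse {iso['adiabatic_low']}–{iso['adiabatic_high']} °C/100 m "
            f"→ isotherm shift {int(iso['shift_low_rounded'])} to "
            f"{int(iso['shift_high_rounded'])} m per decade.\n"
        )

    t_all = trends[trends["subset"] == "all"].merge(
        plots[["plot_id", "zone", "land_use"]], on="plot_id"
    )
    nes_means = (
        t_all.groupby(["lineage", "land_use", "zone"])["nes_m_per_decade"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "nes_mean", "std": "nes_sd", "count": "n"})
    )
    parts.append("## Mean NES per lineage, land use and zone (m/decade)\n")
    parts.append(_md_table(nes_means, nd=1) + "\n")

    lineage_path = mdir / "coefficients_nes_lineage.csv"
    if lineage_path.exists():
        co = pd.read_csv(lineage_path).set_index("term")
        intercept = co.loc["intercept", "estimate"]
        effect = co.loc["vascular", "estimate"]
        ratio = intercept / (intercept + effect)
        parts.append("## NES lineage model\n")
        parts.append(
            f"Bryophyte NES (intercept): {_fmt(intercept, 1)} ± "
            f"{_fmt(co.loc['intercept', 'se'], 1)} SE m/decade; vascular − "
            f"bryophyte: {_fmt(effect, 1)} ± {_fmt(co.loc['vascular', 'se'], 1)} SE. "
            f"Bryophyte:vascular mean-NES ratio: {_fmt(ratio, 1)}.\n"
        )

    reduced_path = mdir / "coefficients_nes_reduced.csv"
    if reduced_path.exists():
        parts.append("## NES full model (after interaction pruning)\n")
        co = pd.read_csv(reduced_path)
        parts.append(_md_table(co[["term", "estimate", "se", "p"]], nd=3) + "\n")

    count_ids = sorted(p.stem.replace("coefficients_", "")
                       for p in mdir.glob("coefficients_counts_*.csv"))
    if count_ids:
        rows = []
        for mid in count_ids:
            co = pd.read_csv(mdir / f"coefficients_{mid}.csv").set_index("term")
            _, lineage, zone, affinity = mid.split("_", 3)
            rows.append(
                {
                    "lineage": lineage, "zone": zone, "affinity": affinity,
                    "trend_log_per_yr": co.loc["year", "estimate"],
                    "se": co.loc["year", "se"],
                    "p": co.loc["year", "p"],
                }
            )
        parts.append("## Affinity-class count trends (log scale per year)\n")
        parts.append(_md_table(pd.DataFrame(rows), nd=4) + "\n")

    cti_rows = []
    for path in sorted(mdir.glob("coefficients_cti_*.csv")):
        co = pd.read_csv(path).set_index("term")
        mid = path.stem.replace("coefficients_cti_", "")
        cti_rows.append(
            {
                "stratum": mid,
                "cti_trend_per_yr": co.loc["year", "estimate"],
                "ci_lower": co.loc["year", "lower"],
                "ci_upper": co.loc["year", "upper"],
            }
        )
    if cti_rows:
        parts.append("## CTI trends per stratum (bootstrap 95% CI)\n")
        parts.append(_md_table(pd.DataFrame(cti_rows), nd=4) + "\n")

    strategy_rows = []
    for path in sorted(mdir.glob("coefficients_life_strategy_*.csv")):
        co = pd.read_csv(path).set_index("term")
        strategy_rows.append(
            {
                "lineage": path.stem.replace("coefficients_life_strategy_", ""),
                "long_vs_short": co.loc["long_lived", "estimate"],
                "se": co.loc["long_lived", "se"],
                "p": co.loc["long_lived", "p"],
            }
        )
    if strategy_rows:
        parts.append("## Life-strategy contrast (long- vs short-lived NES)\n")
        parts.append(_md_table(pd.DataFrame(strategy_rows), nd=2) + "\n")

    skipped_path = mdir / "skipped_strata.csv"
    if skipped_path.exists():
        sk = pd.read_csv(skipped_path)
        parts.append("## Skipped strata and warnings\n")
        if len(sk):
            parts.append(_md_table(sk) + "\n")
        else:
            parts.append("None.\n")
        idx = pd.read_csv(mdir / "models_index.csv")
        notes = idx[idx["notes"].notna() & (idx["notes"] != "")]
        for row in notes.itertuples():
            parts.append(f"- {row.model_id}: {row.notes}")
        if len(notes):
            parts.append("")

    text = "\n".join(parts)
    (run / "report.md").write_text(text, encoding="utf-8")

    if make_figures:
        _trend_figures(run, surveys)
    return text


def _trend_figures(run: Path, surveys: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for lineage, grp in surveys.groupby("lineage"):
        med = grp.groupby("year")["cti"].median()
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(med.index, med.to_numpy(), "o-", color="tab:green")
        ax.set_xlabel("survey year")
        ax.set_ylabel("median CTI")
        ax.set_title(f"CTI trend, {lineage}")
        fig.tight_layout()
        fig.savefig(run / f"cti_trend_{lineage}.png", dpi=120)
        plt.close(fig)


# -------------------------------------------------------------------- run


def run_full_analysis(config: RunConfig) -> str:
    """Run every stage; returns the report text."""
    config = config.validate()
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)

    if config.scenario is not None:
        stage_simulate(config.scenario, config.seed, run)
    else:
        import shutil

        for src, name in (
            (config.plots_csv, "plots.csv"),
            (config.traits_csv, "traits.csv"),
            (config.occurrences_csv, "occurrences.csv"),
            (config.temperature_csv, "temperature.csv"),
        ):
            if src is None:
                continue
            if not Path(src).exists():
                raise FileNotFoundError(f"input table not found: {src}")
            if Path(src).resolve() != (run / name).resolve():
                shutil.copy(src, run / name)

    stage_cti(run, config.cryo_max, config.thermo_min, config.zone_thresholds)
    stage_trends(run, config.adiabatic_bounds, config.zone_thresholds)
    stage_models(
        run,
        bootstrap_b=config.bootstrap_b,
        min_plots=config.min_plots,
        seed=config.seed,
        count_models_by_zone=config.count_models_by_zone,
        zone_thresholds=config.zone_thresholds,
    )

    manifest = {
        "thermoshift_version": __version__,
        "seed": config.seed,
        "adiabatic_bounds": list(config.adiabatic_bounds),
        "affinity_bounds": {"cryo_max": config.cryo_max, "thermo_min": config.thermo_min},
        "zone_thresholds": list(config.zone_thresholds),
        "bootstrap_b": config.bootstrap_b,
        "min_plots": config.min_plots,
        "scenario": None if config.scenario is None else config.scenario.to_dict(),
        "inputs": None
        if config.scenario is not None
        else {
            "plots": config.plots_csv,
            "traits": config.traits_csv,
            "occurrences": config.occurrences_csv,
            "temperature": config.temperature_csv,
        },
    }
    (run / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
    )
    return stage_report(run, config.make_figures)
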