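"""Synthetic plot-network generator with a known thermophilisation signal.

The generator emulates the statistical structure of a national
permanent-plot resurvey network: ~1146 plots spanning 268–3060 m a.s.l.,
three land-use types, two lineages (bryophytes, vascular plants) surveyed
at 5-year intervals over 2001–2021, with lineage-specific richness and
indicator-value availability.

For plot *p*, lineage *l* and survey year *t* the latent community mean
indicator value is

    mu(p, l, t) = beta0(l) - lapse(l) * elev(p)/100
                  + b(p, l)
                  + NES(stratum) * lapse(l)/1000 * (t - t0)

so the per-year CTI trend equals ``NES * lapse / 1000`` — the inversion of
the NES formula — and the cross-sectional CTI gradient equals the
configured lapse.  ``b(p, l)`` is a plot-level intercept deviation
(microhabitat); species-level spread around the community mean is
``sd_species_t``.  Member indicator values are Normal(mu, sd) draws rounded
to the 0.5 grid and clamped to [1, 5] (implemented exactly via the grid-cell
probabilities of that rounded-and-clamped normal).  Species identities are
drawn from a fixed per-lineage pool so each species keeps one indicator
value and one life-strategy code everywhere; identities are reused between
consecutive surveys of a plot with a configurable persistence probability.

With ``infill=True`` the affinity-class counts are generated directly:
cryophilic counts stay flat over time while mesophilic and thermophilic
counts grow log-linearly at ``infill_rate`` — community change purely by
gain of warm-adapted species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .datamodel import (
    DEFAULT_ZONE_THRESHOLDS,
    TEMPERATURE_GRID,
    TemperatureSeries,
    assign_zone,
)

_LINEAGES = ("bryophyte", "vascular")
_LAND_USES = ("managed_grassland", "forest", "unmanaged_open")
_CLASSES = ("short_lived", "long_lived", "unclassified")

_BRYO_CODES = {
    "short_lived": ("fugitive", "annual_shuttle", "colonist", "short_lived_shuttle"),
    "long_lived": ("long_lived_shuttle", "perennial", "competitive_perennial", "dominant"),
    "unclassified": (),
}
_VASC_CODES = {
    "short_lived": ("rrr", "rrs", "crr"),
    "long_lived": ("ccc", "ccs", "ccr"),
    "unclassified": ("sss", "css", "rss", "crs"),
}

#: Half-step cell edges of the rounded indicator grid (0.75, 1.25, ..., 5.25).
_EDGES = np.arange(0.75, 5.5, 0.5)
_GRID = np.asarray(TEMPERATURE_GRID)


def _default_land_use_rule() -> dict[str, dict[str, float]]:
    # unmanaged open areas are rare below the treeline, forests absent in
    # the alpine zone — reproduces the low-representation strata of the
    # monitoring design.
    return {
        "colline": {"managed_grassland": 0.55, "forest": 0.44, "unmanaged_open": 0.01},
        "montane": {"managed_grassland": 0.45, "forest": 0.54, "unmanaged_open": 0.01},
        "subalpine": {"managed_grassland": 0.51, "forest": 0.45, "unmanaged_open": 0.04},
        "alpine": {"managed_grassland": 0.45, "forest": 0.01, "unmanaged_open": 0.54},
    }


@dataclass
class ScenarioConfig:
    """Full parameterisation of one synthetic scenario.

    Defaults reproduce the study conditions: plot network size and
    elevation span, survey calendar, lineage richness (12.9 / 27.3 species
    per survey), indicator-value missingness (26% / 4% of species),
    elevational CTI lapses (0.082 / 0.098 per 100 m) and lineage NES
    (29.8 / 14.0 m per decade).  Noise scales (``sd_species_t``,
    ``plot_cti_sd``) are calibrated so that grid clamping stays below 1% of
    draws over the full elevation span while per-community NES dispersion
    remains of the order reported for the real network (~100 m/decade).
    """

    n_plots: int = 1146
    elevation_range: tuple[float, float] = (268.0, 3060.0)
    survey_years: tuple[int, ...] = (2001, 2006, 2011, 2016, 2021)
    zone_thresholds: tuple[float, float, float] = DEFAULT_ZONE_THRESHOLDS
    land_use_rule: dict[str, dict[str, float]] = field(default_factory=_default_land_use_rule)
    richness_mean: dict[str, float] = field(
        default_factory=lambda: {"bryophyte": 12.9, "vascular": 27.3}
    )
    #: CTI-lapse magnitude per 100 m (positive; the latent gradient is -lapse).
    lapse_true: dict[str, float] = field(
        default_factory=lambda: {"bryophyte": 0.082, "vascular": 0.098}
    )
    #: True NES per lineage, m/decade, at the reference elevation.
    nes_true: dict[str, float] = field(
        default_factory=lambda: {"bryophyte": 29.8, "vascular": 14.0}
    )
    nes_land_use_offset: dict[str, float] = field(
        default_factory=lambda: {lu: 0.0 for lu in _LAND_USES}
    )
    #: Increment of true NES per +100 m of elevation above the reference;
    #: a scalar applies to both lineages, a per-lineage mapping injects a
    #: lineage x elevation interaction.
    nes_elevation_per_100m: float | dict[str, float] = 0.0
    #: Additive NES offset per longevity class (life-strategy scenarios).
    nes_longevity_offset: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in _CLASSES}
    )
    reference_elevation: float = 514.0
    #: SD (m/decade) of a plot-level NES deviation shared by both lineages
    #: (local microclimate or management trends); induces the between-plot
    #: variance the NES models' random intercept absorbs.
    plot_nes_sd: float = 30.0
    sd_species_t: float = 0.35
    plot_cti_sd: dict[str, float] = field(
        default_factory=lambda: {"bryophyte": 0.22, "vascular": 0.12}
    )
    trait_missingness: dict[str, float] = field(
        default_factory=lambda: {"bryophyte": 0.26, "vascular": 0.04}
    )
    strategy_mix: dict[str, float] = field(
        default_factory=lambda: {"short_lived": 0.30, "long_lived": 0.55, "unclassified": 0.15}
    )
    pool_size: dict[str, int] = field(
        default_factory=lambda: {"bryophyte": 546, "vascular": 1244}
    )
    persistence: float = 0.8
    infill: bool = False
    infill_rate: float = 0.03  # log-count increase per year for meso/thermo
    warming_true: float = 0.42  # °C per decade
    temp_base: float = 6.0  # °C in the first year
    temp_noise_sd: float = 0.5  # °C annual deviation around the trend
    temp_years: tuple[int, int] = (2001, 2021)
    #: Latent CTI at elevation 0; when None, chosen per lineage so the
    #: gradient is centred at 3 mid-range (colline plots near the top of
    #: the scale, no saturation).
    beta0: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        if self.n_plots <= 0:
            raise ValueError("n_plots must be positive")
        lo, hi = self.elevation_range
        if not (0 <= lo < hi):
            raise ValueError(f"invalid elevation_range {self.elevation_range!r}")
        if len(self.survey_years) == 0:
            raise ValueError("survey_years must not be empty")
        if any(b <= a for a, b in zip(self.survey_years, self.survey_years[1:])):
            raise ValueError("survey_years must be strictly increasing")
        for lin in _LINEAGES:
            if self.richness_mean[lin] < 0:
                raise ValueError(f"negative richness mean for {lin}")
            if self.lapse_true[lin] <= 0:
                raise ValueError(f"lapse_true must be > 0, got {self.lapse_true[lin]}")
            if not 0 <= self.trait_missingness[lin] <= 1:
                raise ValueError("trait_missingness must be in [0, 1]")
        for zone, probs in self.land_use_rule.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"land-use probabilities for {zone!r} do not sum to 1")
        if abs(sum(self.strategy_mix.values()) - 1.0) > 1e-9:
            raise ValueError("strategy_mix must sum to 1")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must be in [0, 1]")
        if self.sd_species_t <= 0:
            raise ValueError("sd_species_t must be > 0")
        return self

    def beta0_for(self, lineage: str) -> float:
        if self.beta0 is not None and lineage in self.beta0:
            return float(self.beta0[lineage])
        mid = 0.5 * (self.elevation_range[0] + self.elevation_range[1])
        return 3.0 + self.lapse_true[lineage] * mid / 100.0

    def nes_total(self, lineage: str, land_use: str, elevation_m: float, longevity: str = "") -> float:
        elev_inc = (
            self.nes_elevation_per_100m.get(lineage, 0.0)
            if isinstance(self.nes_elevation_per_100m, dict)
            else self.nes_elevation_per_100m
        )
        nes = (
            self.nes_true[lineage]
            + self.nes_land_use_offset.get(land_use, 0.0)
            + elev_inc * (elevation_m - self.reference_elevation) / 100.0
        )
        if longevity:
            nes += self.nes_longevity_offset.get(longevity, 0.0)
        return nes

    def slope_true(self, lineage: str, land_use: str, elevation_m: float, longevity: str = "") -> float:
        """Latent per-year CTI trend: NES x lapse / 1000."""
        return (
            self.nes_total(lineage, land_use, elevation_m, longevity)
            * self.lapse_true[lineage]
            / 1000.0
        )

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("elevation_range", "survey_years", "zone_thresholds", "temp_years"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d).validate()

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """Generated tables plus generator diagnostics."""

    plots: pd.DataFrame
    traits: pd.DataFrame
    occurrences: pd.DataFrame
    temperature: TemperatureSeries
    clamp_fraction: float
    n_draws: int

    def __iter__(self) -> Iterator:
        return iter((self.plots, self.traits, self.occurrences, self.temperature))


def _quota_counts(n: int, proportions: list[float]) -> list[int]:
    """Largest-remainder allocation of n items to proportions."""
    raw = [n * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _build_pool(cfg: ScenarioConfig, lineage: str, rng: np.random.Generator):
    """Species pool: traits rows plus a (class, grid value) -> ids index."""
    n = cfg.pool_size[lineage]
    n_missing = int(round(cfg.trait_missingness[lineage] * n))
    n_valued = n - n_missing
    prefix = "bryo" if lineage == "bryophyte" else "vasc"
    codes = _BRYO_CODES if lineage == "bryophyte" else _VASC_CODES
    mix = [cfg.strategy_mix[c] for c in _CLASSES]

    rows = []
    cells: dict[tuple[str, float], list[str]] = {}
    per_value = _quota_counts(n_valued, [1.0 / 9.0] * 9)
    idx = 0
    for value, n_v in zip(_GRID, per_value):
        for cls, n_c in zip(_CLASSES, _quota_counts(n_v, mix)):
            for _ in range(n_c):
                sid = f"{prefix}{idx:05d}"
                idx += 1
                pool = codes[cls]
                code = pool[rng.integers(len(pool))] if pool else None
                rows.append((sid, lineage, float(value), code))
                cells.setdefault((cls, float(value)), []).append(sid)
    missing_ids: dict[str, list[str]] = {c: [] for c in _CLASSES}
    for cls, n_c in zip(_CLASSES, _quota_counts(n_missing, mix)):
        for _ in range(n_c):
            sid = f"{prefix}{idx:05d}"
            idx += 1
            pool = codes[cls]
            code = pool[rng.integers(len(pool))] if pool else None
            rows.append((sid, lineage, np.nan, code))
            missing_ids[cls].append(sid)
    traits = pd.DataFrame(
        rows, columns=["species_id", "lineage", "temperature_value", "strategy_code"]
    )
    return traits, cells, missing_ids


def _cell_probs(mu: np.ndarray, sd: float) -> np.ndarray:
    """(n, 11) probabilities: low tail, 9 grid cells, high tail.

    Exactly the law of a Normal(mu, sd) draw rounded to the 0.5 grid, with
    the two tail columns marking clamp events (rounded value off [1, 5]).
    """
    z = (_EDGES[None, :] - mu[:, None]) / sd
    cdf = ndtr(z)
    probs = np.empty((mu.size, 11))
    probs[:, 0] = cdf[:, 0]
    probs[:, 1:10] = np.diff(cdf, axis=1)
    probs[:, 10] = 1.0 - cdf[:, 9]
    return probs


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a probability matrix."""
    totals = probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs / totals, axis=1)
    u = rng.random(probs.shape[0])
    return np.minimum((u[:, None] > cum).sum(axis=1), probs.shape[1] - 1)


_CLASS_COLUMNS = {
    # tail columns belong to the class owning the adjacent boundary value
    "cryophilic": np.arange(0, 5),  # low tail + values 1 .. 2.5
    "mesophilic": np.array([5]),  # value 3
    "thermophilic": np.arange(6, 11),  # values 3.5 .. 5 + high tail
}


def _choose_species(
    cell_key: tuple[str, float],
    k: int,
    cells: dict[tuple[str, float], list[str]],
    prev: dict[tuple[str, float], list[str]],
    persistence: float,
    rng: np.random.Generator,
) -> list[str]:
    """k distinct species for one (strategy, value) cell, reusing the
    previous survey's identities with the persistence probability."""
    pool = cells[cell_key]
    k = min(k, len(pool))
    reuse = [s for s in prev.get(cell_key, ()) if rng.random() < persistence][:k]
    need = k - len(reuse)
    if need > 0:
        taken = set(reuse)
        avail = [s for s in pool if s not in taken]
        picked = rng.choice(len(avail), size=need, replace=False)
        reuse += [avail[j] for j in sorted(picked)]
    return reuse


def generate_scenario(
    config: ScenarioConfig, seed: int | None = None
) -> SyntheticDataset:
    """Generate plots, traits, occurrences and a temperature series.

    Identical config and seed give identical output.  ``seed`` overrides
    ``config.seed`` when given.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    years = np.asarray(cfg.survey_years)
    t0 = years[0]

    # ---- plots -----------------------------------------------------------
    lo, hi = cfg.elevation_range
    width = max(2, len(str(cfg.n_plots)))
    elev = rng.uniform(lo, hi, size=cfg.n_plots)
    zones = [assign_zone(e, cfg.zone_thresholds).value for e in elev]
    land_use = [
        _LAND_USES[
            _sample_rows(
                np.array([[cfg.land_use_rule[z].get(lu, 0.0) for lu in _LAND_USES]]), rng
            )[0]
        ]
        for z in zones
    ]
    plots = pd.DataFrame(
        {
            "plot_id": [f"p{i:0{width}d}" for i in range(cfg.n_plots)],
            "elevation_m": elev,
            "land_use": land_use,
            "zone": zones,
        }
    )
    # plot-level NES deviation, shared by the two lineages of a plot
    plot_nes_dev = rng.normal(0.0, cfg.plot_nes_sd, size=cfg.n_plots)

    # ---- species pools ---------------------------------------------------
    traits_parts, cells_by_lin, missing_by_lin = {}, {}, {}
    for lin in _LINEAGES:
        tr, cells, missing_ids = _build_pool(cfg, lin, rng)
        traits_parts[lin], cells_by_lin[lin], missing_by_lin[lin] = tr, cells, missing_ids
    traits = pd.concat([traits_parts[lin] for lin in _LINEAGES], ignore_index=True)

    # ---- occurrences -----------------------------------------------------
    occ_plot, occ_year, occ_species = [], [], []
    n_clamped = 0
    n_draws = 0
    mix_p = np.array([cfg.strategy_mix[c] for c in _CLASSES])

    for lin in _LINEAGES:
        lapse = cfg.lapse_true[lin]
        beta0 = cfg.beta0_for(lin)
        sd = cfg.sd_species_t
        cells = cells_by_lin[lin]
        missing_ids = missing_by_lin[lin]
        plot_effect = rng.normal(0.0, cfg.plot_cti_sd[lin], size=cfg.n_plots)
        richness = cfg.richness_mean[lin]
        miss = cfg.trait_missingness[lin]

        for p_idx in range(cfg.n_plots):
            pid = plots["plot_id"].iat[p_idx]
            lu = plots["land_use"].iat[p_idx]
            e = float(elev[p_idx])
            base_mu = beta0 - lapse * e / 100.0 + plot_effect[p_idx]
            prev: dict[tuple[str, float], list[str]] = {}
            prev_missing: dict[str, list[str]] = {}
            for year in years:
                dt = float(year - t0)
                cur: dict[tuple[str, float], list[str]] = {}
                cur_missing: dict[str, list[str]] = {}
                species_here: list[str] = []

                if cfg.infill:
                    probs0 = _cell_probs(np.array([base_mu]), sd)[0]
                    p_class = {
                        a: probs0[cols].sum() for a, cols in _CLASS_COLUMNS.items()
                    }
                    grow = float(np.exp(cfg.infill_rate * dt))
                    lam = {
                        "cryophilic": richness * (1 - miss) * p_class["cryophilic"],
                        "mesophilic": richness * (1 - miss) * p_class["mesophilic"] * grow,
                        "thermophilic": richness * (1 - miss) * p_class["thermophilic"] * grow,
                    }
                    n_missing_t = rng.poisson(richness * miss)
                    for aff in ("cryophilic", "mesophilic", "thermophilic"):
                        n_aff = rng.poisson(lam[aff])
                        if n_aff == 0:
                            continue
                        cls_draw = rng.choice(len(_CLASSES), size=n_aff, p=mix_p)
                        cols = _CLASS_COLUMNS[aff]
                        masked = np.zeros((n_aff, 11))
                        masked[:, cols] = probs0[cols]
                        cats = _sample_rows(masked, rng)
                        n_draws += n_aff
                        n_clamped += int(((cats == 0) | (cats == 10)).sum())
                        values = _GRID[np.clip(cats, 1, 9) - 1]
                        cell_counts: dict[tuple[str, float], int] = {}
                        for cls_i, v in zip(cls_draw, values):
                            key = (_CLASSES[cls_i], float(v))
                            if key in cells:
                                cell_counts[key] = cell_counts.get(key, 0) + 1
                        for key, k in cell_counts.items():
                            chosen = _choose_species(
                                key, k, cells, prev, cfg.persistence, rng
                            )
                            cur[key] = chosen
                            species_here.extend(chosen)
                else:
                    s_total = rng.poisson(richness)
                    if s_total == 0:
                        prev, prev_missing = {}, {}
                        continue
                    n_missing_t = int(rng.binomial(s_total, miss))
                    n_valued = s_total - n_missing_t
                    if n_valued > 0:
                        cls_draw = rng.choice(len(_CLASSES), size=n_valued, p=mix_p)
                        slope_dev = plot_nes_dev[p_idx] * lapse / 1000.0
                        offs = np.array(
                            [
                                (cfg.slope_true(lin, lu, e, _CLASSES[c]) + slope_dev) * dt
                                for c in cls_draw
                            ]
                        )
                        mu = base_mu + offs
                        cats = _sample_rows(_cell_probs(mu, sd), rng)
                        n_draws += n_valued
                        n_clamped += int(((cats == 0) | (cats == 10)).sum())
                        values = _GRID[np.clip(cats, 1, 9) - 1]
                        cell_counts: dict[tuple[str, float], int] = {}
                        for cls_i, v in zip(cls_draw, values):
                            key = (_CLASSES[cls_i], float(v))
                            if key in cells:
                                cell_counts[key] = cell_counts.get(key, 0) + 1
                        for key, k in cell_counts.items():
                            chosen = _choose_species(
                                key, k, cells, prev, cfg.persistence, rng
                            )
                            cur[key] = chosen
                            species_here.extend(chosen)

                # species without indicator values
                if n_missing_t > 0:
                    cls_counts = rng.multinomial(n_missing_t, mix_p)
                    for cls, k in zip(_CLASSES, cls_counts):
                        pool = missing_ids[cls]
                        if not pool or k == 0:
                            continue
                        k = min(k, len(pool))
                        reuse = [
                            s
                            for s in prev_missing.get(cls, ())
                            if rng.random() < cfg.persistence
                        ][:k]
                        need = k - len(reuse)
                        if need > 0:
                            taken = set(reuse)
                            avail = [s for s in pool if s not in taken]
                            picked = rng.choice(len(avail), size=need, replace=False)
                            reuse += [avail[j] for j in sorted(picked)]
                        cur_missing[cls] = reuse
                        species_here.extend(reuse)

                for sid in species_here:
                    occ_plot.append(pid)
                    occ_year.append(int(year))
                    occ_species.append(sid)
                prev, prev_missing = cur, cur_missing

    occurrences = pd.DataFrame(
        {"plot_id": occ_plot, "year": occ_year, "species_id": occ_species}
    )

    # ---- temperature series ---------------------------------------------
    ty0, ty1 = cfg.temp_years
    t_years = tuple(range(ty0, ty1 + 1))
    noise = rng.normal(0.0, cfg.temp_noise_sd, size=len(t_years))
    temps = tuple(
        float(cfg.temp_base + cfg.warming_true / 10.0 * (y - ty0) + n)
        for y, n in zip(t_years, noise)
    )
    temperature = TemperatureSeries(t_years, temps)

    return SyntheticDataset(
        plots=plots,
        traits=traits,
        occurrences=occurrences,
        temperature=temperature,
        clamp_fraction=(n_clamped / n_draws) if n_draws else 0.0,
        n_draws=n_draws,
    )


def truth_table(config: ScenarioConfig) -> pd.DataFrame:
    """True per-stratum quantities implied by a config (pure function).

    One row per lineage × land-use type, evaluated at the reference
    elevation: true NES (m/decade), the implied latent CTI slope per year,
    the latent lapse per 100 m (negative), the log-scale affinity-class
    count trends (defined only for infill scenarios) and the true
    temperature slope (°C per year).
    """
    cfg = config.validate()
    rows = []
    for lin in _LINEAGES:
        for lu in _LAND_USES:
            nes = cfg.nes_total(lin, lu, cfg.reference_elevation)
            rows.append(
                {
                    "lineage": lin,
                    "land_use": lu,
                    "nes_true_m_per_decade": nes,
                    "slope_true_per_yr": nes * cfg.lapse_true[lin] / 1000.0,
                    "lapse_per_100m": -cfg.lapse_true[lin],
                    "cryo_count_trend": 0.0 if cfg.infill else np.nan,
                    "meso_count_trend": cfg.infill_rate if cfg.infill else np.nan,
                    "thermo_count_trend": cfg.infill_rate if cfg.infill else np.nan,
                    "warming_slope_per_yr": cfg.warming_true / 10.0,
                }
            )
    return pd.DataFrame(rows)


def scenario_with(config: ScenarioConfig, **changes) -> ScenarioConfig:
    """A copy of ``config`` with fields replaced (validated)."""
    return replace(config, **changes).validate()
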