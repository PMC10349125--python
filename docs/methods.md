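# Methods

`thermoshift` quantifies thermophilisation — the progressive replacement of
cold-adapted by warm-adapted species — in permanent-plot resurvey data of
bryophyte and vascular plant communities, and validates every stage against
a synthetic plot network with known ground truth.

## Community temperature index (CTI)

Each species carries an ordinal temperature indicator value on a 0.5-step
grid from 1 (most cryophilic) to 5 (most thermophilic), expressing its
realised thermal optimum. The CTI of a community — one lineage on one plot
in one survey year — is the unweighted arithmetic mean of the indicator
values of the species present. Occurrence data are presence/absence, so a
species contributes once regardless of how often it is listed; species
without an indicator value contribute to richness but not to the CTI, and a
community whose members all lack values has an undefined CTI. Indicator
values of 1–2.5 are classed cryophilic, 3 mesophilic, and 3.5–5
thermophilic; the class bounds are configurable but partition the grid
under any valid setting.

## Thermophilisation rate, lapse and NES

The thermophilisation rate of a community is the OLS slope of CTI on
calendar survey year (CTI/yr), computed per plot × lineage from all surveys
with a defined CTI; communities with fewer than two such surveys are
excluded and logged. The elevational CTI lapse per lineage is the OLS slope
of per-plot mean CTI on elevation, expressed per 100 m; it is expected to
be negative and the pipeline aborts with a diagnostic if it is not, since
the normalisation below presupposes a declining gradient.

The notional elevation shift (NES) converts a temporal CTI trend into the
equivalent displacement along the elevational gradient:

    NES [m/decade] = rate [CTI/yr] / |lapse| [CTI per 100 m] × 1000

i.e. the elevation difference at which communities of equal CTI are found
ten years apart. A rate of 0.01/yr over a lapse of 0.1 per 100 m gives
100 m/decade. NES is linear in the rate and invariant under common
rescaling of rate and lapse. Life-strategy subsets (short- vs long-lived
species, classified from During categories for bryophytes and
competitive/stress-tolerant/ruderal attribute codes for vascular plants)
reuse the lineage-wide lapse rather than subset-specific lapses; lapses are
defined per lineage and subset communities are often sparse, so a
subset-specific gradient would be poorly determined. This is a documented
choice, configurable in principle by passing subset lapses to
`build_trends`.

The expected NES under perfect temperature tracking is the isotherm shift:
the warming rate (OLS slope of annual mean temperature × 10, °C/decade)
divided by the adiabatic lapse rate. With bounds of 0.5–0.67 °C per 100 m
the window is reported both raw and half-up rounded to whole metres.

## Mixed models

Four model families, all with a plot-level random intercept:

* **CTI trend LMMs** — `CTI ~ year + (1 | plot)` per lineage × elevational
  zone × land-use stratum. Strata with fewer than 14 plots are skipped and
  logged. 95% CIs for the trend come from a nonparametric cluster bootstrap
  (plots resampled with replacement, B = 1000 by default, configurable).
  The bootstrap scheme resamples whole plots because plots are the
  independent sampling units of the design.
* **NES lineage model** — `NES ~ lineage + (1 | plot)`. The intercept is
  the mean bryophyte NES; the lineage coefficient the vascular-minus-
  bryophyte difference.
* **NES full model** — adds centred elevation ((elevation − 514 m)/100 m),
  land-use type and all two- and three-way interactions. The intercept is
  thus the bryophyte NES in managed grasslands at 514 m a.s.l. and the
  elevation coefficient is per +100 m. Marginal Wald F-tests are computed
  per term on the full model; every interaction with p ≥ 0.05 is removed in
  a single step and the model refitted once (main effects always retained).
* **Number-of-species models** — Poisson GLMMs, log link,
  `n ~ year + (1 | plot)` per lineage × affinity class (optionally × zone),
  with year centred at the first survey (intercept-only effect).
* **Life-strategy models** — `NES ~ longevity + elevation + land use +
  (1 | plot)` per lineage on the short-/long-lived subset trends.

The NES and life-strategy models use a power variance function: residual
SD = σ·v^δ with v the community's mean number of species contributing to
its CTI across surveys, δ estimated. NES is a per-community statistic, so
its sampling noise shrinks with the number of contributing species; δ is
therefore expected negative. The variance covariate is configurable.

### Estimation engine

No Python library offers a frequentist random-intercept LMM with a power
variance function, so `lmm.py` implements one: β and σ² are profiled out,
and (log(τ²/σ²), δ) maximised by Nelder–Mead on the REML criterion, with
group-wise covariance inverses via the rank-one Woodbury identity (cost
linear in observations). The homoscedastic case is verified against
statsmodels MixedLM and the power-variance case against R `nlme::lme` with
`varPower` (agreement to ≤1e-3 in all parameters and the log-likelihood on
a fixture). Inference uses Wald t/F statistics with between–within
denominator degrees of freedom — an approximation chosen for transparency:
covariates varying within plots use n − G − p_within, purely between-plot
covariates G − p_between. With zero between-plot variance the profile
pushes τ² to its lower bound, the fit is flagged singular, and the
estimates coincide with the marginal regression — this is the documented
fallback for degenerate strata. With a single observation per group the
fixed effects equal OLS exactly.

`glmm.py` implements the Poisson random-intercept GLMM by maximum
likelihood with adaptive Gauss–Hermite quadrature (15 nodes; the group
integral depends on the data only through per-group sums, and the grid is
centred at each group's Laplace mode). The slope agrees with the
conditional-likelihood Poisson estimator (which eliminates plot effects
exactly) to ≤5e-5 on simulated panels, and with `lme4::glmer` to 4 digits.

### Numerical choices

Optimiser tolerances 1e-8 (parameters) / 1e-10 (objective); three fixed
starting points against local optima, a single warm start for bootstrap
refits. log γ is bounded in [−23, 14] and δ in [−5, 5]. Rank-deficient
fixed-effect designs raise immediately; the full NES model additionally
drops the highest-order rank-deficient interaction (empty stratum cells)
with a note. Integer isotherm shifts round half-up; all raw values are
retained. CTI and NES are carried at full float precision and rounded only
in the report.

## Synthetic plot network

The generator emulates the statistical structure of the national
monitoring design: 1146 plots uniform over 268–3060 m, zones by a single
national threshold rule (colline < 800 m ≤ montane < 1500 m ≤ subalpine
< 2200 m ≤ alpine, nival pooled into alpine), land-use frequencies per zone
chosen so that unmanaged open areas are rare below the alpine zone and
forests absent within it (reproducing the low-representation strata),
surveys every five years 2001–2021, Poisson richness with means 12.9
(bryophytes) and 27.3 (vascular plants), and indicator-value missingness of
26% / 4% of species.

The latent community mean for plot p, lineage l, year t is

    μ(p,l,t) = β₀(l) − lapse(l)·elev(p)/100 + b(p,l)
               + [NES(stratum) + u(p)]·lapse(l)/1000·(t − t₀)

with β₀ set so the gradient is centred at 3 mid-range (colline communities
near the top of the scale without saturation), b(p,l) a plot-level
intercept deviation and u(p) a plot-level NES deviation shared by the two
lineages (this shared component is what the NES models' random intercept
absorbs). Member indicator values are Normal(μ, sd) draws rounded to the
0.5 grid and clamped to [1, 5], implemented exactly through the grid-cell
probabilities of that law; clamp events are counted and stay below 1% of
draws at defaults. Species identities come from a fixed pool (546 / 1244
species) in which each species keeps one value and one strategy code
everywhere; identities are reused between consecutive surveys of a plot
with probability 0.8 per species (values are drawn fresh each survey, so
persistence changes turnover, not the CTI signal — the thermophilisation
trend is never attenuated by community inertia). An infill mode instead
draws affinity-class counts directly: cryophilic counts time-constant,
meso-/thermophilic counts growing log-linearly — community change purely by
gain of warm-adapted species.

Noise defaults were calibrated a priori to the printed summaries of the
real network: species-level spread sd = 0.35 and plot-level CTI sd 0.22 /
0.12 keep clamping under 1% across the full elevation span while giving
per-community NES dispersion of order 100 m/decade and model standard
errors of the same order as reported (≈4 / ≈5 for the lineage-model
intercept and contrast at ~1100 plots); the plot-level NES deviation SD is
30 m/decade. The temperature series is a 0.42 °C/decade trend over 2001–
2021 plus annual N(0, 0.5 °C) noise, which reproduces the reported modest
explanatory power of the warming regression (R² ≈ 0.2).

What the generator does *not* emulate: spatial autocorrelation and
region-dependent zonation, abundance structure, observer effects, uneven
survey calendars (every plot gets all five surveys), and real species'
uneven indicator-value distribution (the pool is uniform over the grid).
Passing recovery tests therefore demonstrate that the estimators are
consistent and approximately unbiased under the declared sampling
structure, not that field estimates are free of the confounders discussed
for real data.

## Problem sizes used in validation

Recovery tests run at 250–600 plots; interval-coverage checks use 200–220
replicates of compact 25–30-plot panels with bootstrap B = 99; the
acceptance script averages 16 independent replicates of the full
1146-plot design. These sizes keep Monte-Carlo error well inside the
tolerances being asserted while the whole suite stays desk-scale.

## Known limitations

* Denominator degrees of freedom are between–within approximations, not
  Satterthwaite/Kenward–Roger; p-values for small numbers of plots are
  approximate.
* The power variance function supports a single positive covariate; zero
  covariate values are floored at 0.5 with-species communities.
* The Poisson GLMM fits a random intercept only — no overdispersion beyond
  the intercept, no random slopes, matching the target model family.
* Life-strategy NES reuses the lineage-wide lapse (see above).
* The interaction-pruning step is a single refit at α = 0.05; no further
  model selection is performed.
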