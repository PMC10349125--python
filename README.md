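# thermoshift

Thermophilisation analysis for permanent-plot resurvey data: community
temperature indices, notional elevation shifts, and the mixed-model layer
around them — with a synthetic plot-network generator so the whole
pipeline can be validated against known ground truth.

## The problem

Climate warming replaces cold-adapted with warm-adapted species in plant
communities ("thermophilisation"). Monitoring programmes that resurvey
permanent plots along elevational gradients — such as the Swiss national
network of ~1100 plots between ~270 and ~3060 m a.s.l., surveyed every
five years for bryophytes and vascular plants — let us measure that
process and compare it between lineages, land-use types and elevations.
This package is for ecologists and biostatisticians who want those
statistics as tested, reusable code.

## The statistics

* **CTI** — the community temperature index of one lineage on one plot in
  one survey: the unweighted mean of the species' ordinal temperature
  indicator values (1 = most cryophilic … 5 = most thermophilic, 0.5
  steps). Values 1–2.5 / 3 / 3.5–5 define cryophilic / mesophilic /
  thermophilic species.
* **Thermophilisation rate** — the OLS slope of CTI on survey year
  (CTI/yr), per community.
* **NES** (notional elevation shift) — the rate normalised by the
  elevational CTI lapse (slope of per-plot mean CTI on elevation, per
  100 m):

  `NES [m/decade] = rate / |lapse| × 1000`

  the elevation difference at which equal-CTI communities sit ten years
  apart. A rate of 0.01/yr over a lapse of 0.1 per 100 m is 100 m/decade.
* **Isotherm shift** — the expected NES under perfect tracking: warming
  rate (°C/decade) divided by the adiabatic lapse rate (0.5–0.67 °C per
  100 m).
* **Mixed models** — CTI-trend LMMs per stratum with cluster-bootstrap
  CIs; NES lineage/full models and life-strategy models with a plot-level
  random intercept and a power variance function (residual SD ∝ v^δ in the
  number of contributing species); Poisson GLMMs for affinity-class
  counts. The LMM engine (random intercept + `varPower`, REML) and the
  adaptive Gauss–Hermite Poisson GLMM are implemented here and verified
  against statsmodels, R `nlme` and `lme4` — see `docs/methods.md`.

## Worked example

Simulate a 600-plot network with the default scenario (its truths are the
study's reference estimates: lapses −0.082/−0.098 per 100 m, bryophyte NES
29.8 m/decade, vascular 14.0) and re-estimate everything:

```python
import thermoshift as ts

cfg = ts.ScenarioConfig(n_plots=600, seed=1)
data = ts.generate_scenario(cfg)
surveys = ts.build_surveys(data.plots, data.traits, data.occurrences)

lapses = ts.estimate_lapses(surveys, data.plots)
trends, excluded = ts.build_trends(surveys, lapses)
fit = ts.fit_nes_lineage(trends)

warming, r2, p = ts.estimate_warming(data.temperature)
shift = ts.isotherm_shift(warming, (0.5, 0.67))
```

Output of this exact script (printing the fitted quantities):

```
bryophyte: lapse -0.082 per 100 m (R² = 0.90)
vascular: lapse -0.099 per 100 m (R² = 0.97)
1200 community trends, 0 excluded
bryophyte NES: 26.7 ± 4.4 m/decade
vascular − bryophyte: -17.2 ± 4.7
variance power δ: -0.78
warming 0.15 °C/decade → isotherm shift 23–31 m/decade
```

Reading: both lapses recover their truths; bryophyte communities shift
notionally upward by ~27 m/decade against ~9.5 for vascular plants
(26.7 − 17.2) — a higher ratio than the 2.1 truth in this single
replicate, with both coefficients within two standard errors of their
truths. δ < 0 confirms that NES noise shrinks with species number. The warming estimate (0.15 here vs the 0.42 truth)
shows how uncertain a 21-year OLS warming trend is at realistic annual
noise — its standard error is ~0.18 °C/decade.

## Command line

```sh
thermoshift simulate --config scenario.yaml --seed 1 --out run/
thermoshift cti --run-dir run/
thermoshift trends --run-dir run/ --adiabatic-low 0.5 --adiabatic-high 0.67
thermoshift models --run-dir run/ --bootstrap 1000 --min-plots 14
thermoshift report --run-dir run/
# or everything at once:
thermoshift run --config scenario.yaml --seed 1 --out run/
```

Every stage writes flat CSVs into the run directory; `report.md`
summarises stratum CTI trends, lapses, NES means per lineage × land use ×
zone, the lineage ratio, the isotherm window and any skipped strata.
Reruns with the same config and seed are byte-identical.

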