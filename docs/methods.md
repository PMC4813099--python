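# Methods notes

## The system being modeled

In a shallow subtropical wetland, wading-bird prey availability is set by
hydrology operating at nested time scales: years of inundation build the
prey base (tracked by hydroperiod and days since drydown), weeks of
dry-season recession concentrate prey into shrinking pools (recession
rate), and the day's water depth decides whether a bird can physically
forage (availability within a species-specific depth range). A mid-season
"reversal" — rain re-raising stage after cells have dried — disperses or
kills concentrated prey and is tracked as days since rewetting. The
package's chain (hydrology → foraging-condition models → seasonal indices
→ breeding responses) quantifies how the timing of these processes maps
onto nesting effort and nest success.

## Hydrologic covariates

| covariate | units | default | notes |
|---|---|---|---|
| dry threshold | cm | 0 | ground-surface intercept; configurable |
| recession window | days | 14 | two-point difference (d(t−w) − d(t))/w; simplest oracle-checkable estimator of an intermediate-scale drying rate |
| DSD cap | days | 600 | beyond this, prey production is treated as saturated |
| hydroperiod horizon | years | 10 | mean annual inundated days over the most recent complete calendar years; fewer years allowed with a warning |

Missing depth days are never interpolated; operations flag insufficient
history (recession NaN before the window fills; DSD carries a
`left_censored` flag before a cell's first observed drydown, where the
value is days-since-series-start, capped). The reversal covariate encodes
event *timing* (days since rewetting, 0 = no completed event) rather than
a binary, and resets every dry season (Nov 1–May 31 window).

## TFC: two-stage regional chain

Stage 1 is a linear model per resource: use ~ three availability means +
their three pairwise interactions + three SDs (10 parameters; least
squares; requires ≥ 3 rows per parameter; rank deficiencies are reported
with the aliased column names). Observed use is the count-weighted mean of
the resource over occupied available cells — count-weighting (not
presence-weighting) is a deliberate choice. Stage 2 regresses region-day
individual totals (Σ counts) and flock totals (occupied-cell counts) on
the three predicted use values with a negative-binomial log-link model.
The two stages feed forward point predictions only; no uncertainty is
propagated, matching the framework being implemented. Days without
surveys are predicted, never fitted. Availability SDs use the n−1
denominator; a single-cell region has SD 0. The foraging depth interval
is closed on both ends.

## SFC: occurrence frequency with a spatial autocovariate

Spatial correlation is handled by the simplest published device — an
autocovariate equal to the 8-neighborhood mean of the frequency grid
(edge cells renormalize over available neighbors) — rather than spatial
eigenvector or CAR models, which are out of scope. Cell covariates are
averaged over all survey dates covering the cell, unconditional on
detection. The number of surveys enters as an exposure offset, so the
fitted response is an occurrence rate per survey.

**Daily evaluation of a study-period model.** Patch abundance multiplies
into the daily FI, yet the SFC is fitted to cumulative frequencies. We
resolve this by evaluating the fitted per-survey rate on each day's
covariate layers with the autocovariate held at its fitted-period mean —
and, critically, with each standardized covariate clamped to the min/max
seen in the fitted records. The log-linear surface with interactions is
descriptive inside the hull of the data that built it; unclamped daily
extrapolation (e.g. DSD at 600 days ≈ 50 fitted SDs out) produces
astronomically large rates that are artifacts of the functional form, not
predictions.

## Indices

FI is the exact product of individual abundance and patch abundance. The
flocking ratio is floored at 1.0 because separately fitted flock and
individual regressions can predict individuals < flocks, which is
physically impossible (a flock is one or more birds in a cell); 0/0 is
missing and excluded from season means. Monthly Δ uses the cross-boundary
difference for a month's first day (the daily series is continuous across
months), so a linear series of slope m has monthly Δ exactly m. Season
SEs are sample SD/√n over non-missing daily values; SE, not SD, is the
variability measure carried into the candidate models. The Decade label
splits at 1999/2000 (the wetter early regime vs the recent one). Rows
with > 20 % of season days missing are flagged, not dropped.

## Nest metrics

Exposure days follow the midpoint rule: intervals ending in survival
contribute their full span, intervals ending in failure contribute half,
fractions retained. Daily survival s = 1 − F/E with Hensler variance
s(1 − s)/E; period success s^T. T defaults: ibis 21 + 14 = 35 days, egret
26 + 21 = 47 days, stork 30 + 21 = 51 — the posthatching success ages (14
or 21 days) are field-standard; the incubation lengths are package
defaults, and T is configurable because whether the period should span
the full cycle or only part of it is genuinely ambiguous. Colonies are
weighted equally in the annual mean (no exposure weighting). Annual
effort is the maximum active-nest count across survey rounds.

## Multimodel inference

All candidates are fitted by maximum likelihood (never REML) so AICc is
comparable across fixed-effect sets. K counts the intercept, fixed
slopes, the residual variance, and the random-intercept variance when
retained. If the Decade random-intercept variance estimate collapses
(< 1e-6 × residual variance) the model is refitted without it and
flagged. Averaging is *natural* (conditional on containment): weights
renormalized over containing models, averaged coefficient Σω̃β,
unconditional SE Σω̃√(SE² + (β − β̄)²); full-model-set shrinkage averaging
is not implemented. Δ < 2 is annotated plausible, Δ > 4 unsupported.
Model-averaged predictions are ω-weighted over all models on the fitting
scale, then back-transformed (x⁴ inverts the fourth-root used for stork
effort); R² is the squared Pearson correlation of observed vs averaged
predictions. The shipped candidate sets (27 models each) draw effort
terms from the early dry season (Jan–Mar) and success terms from the late
dry season (Feb–Apr); the exact historical 27-model lists are not public,
so the shipped sets cover the named variable families and are
user-editable YAML.

## What the synthetic generator does and does not emulate

It emulates: a nearly flat landscape (slope a few cm/km) with correlated
microtopography; a seasonal stage cycle with per-year redraws of initial
stage and recession rate, Poisson reversal events, and a wetter 1993–1999
regime; a spatially correlated AR(1) stage anomaly (SD 2 cm, ρ 0.95)
standing in for patchy rainfall — without it, within-day recession would
be spatially constant and its SD term degenerate; belt transects every
5th row (2 km at 400 m cells) with negative-binomial counts (size 2,
Poisson in the limit) from a log-linear truth on standardized depth /
recession / DSD, zero outside the depth range; nest checks every 5–7 days
with daily survival invlogit(a + b·FI_scaled) — the link is placed on
survival (not hazard) so b > 0 means better foraging raises survival, and
FI is scaled by a fixed reference (mean 60, SD 40) so that between-
scenario FI contrasts translate into survival contrasts rather than being
standardized away per run. Nest starts fall in Mar 1–15, putting
incubation in March and chicks in April–May, the phase of the cycle the
system is sensitive to; start intensity is log-linear in March FI
(bounded at e^±3).

It does not emulate: real topography or gauge interpolation, observer or
detection error (perfect detection within transects is assumed; the field
protocol's detection probability is unknown), rainfall/ET water budgets,
colony-site selection, or density dependence in nest survival. Passing
recovery tests therefore demonstrates the estimators are correct under
the stated generating model, not that the models are adequate for any
particular field dataset.

## Problem sizes and numerics

Default scale: 25 × 25 cells (125 surveyed transect cells, satisfying the
10-cells-per-parameter precondition of the 10-term SFC design), 21
breeding years, weekly surveys Jan–May, 3 colonies per species-year. A
full scenario runs in about a minute on one core. Count models try
negative-binomial MLE first and fall back to a Poisson GLM when the
optimizer fails or diverges (recorded in the fit object). Linear-predictor
exponentials are clipped at 50 on the log scale as an overflow guard.
Recovery tests use fixed seeds; joint 2-SE checks over many coefficients
are expected to fail for a fraction of arbitrary seeds at nominal
coverage, which is why the seeds are pinned.

## Known limitations

The SFC's daily patch abundance inherits the tension between a
cumulative-occurrence fit and daily evaluation; the clamped-hull
evaluation is a documented convention, not a derived quantity. The
two-stage TFC chain understates uncertainty (point predictions between
stages). Gaussian models on the Mayfield success scale ignore its
bounded, heteroscedastic nature; a binomial-scale treatment is out of
scope. Effort and success in the generator both respond to FI, so their
simulated Spearman correlation is higher than field values by
construction.
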