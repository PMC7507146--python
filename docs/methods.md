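# Methods

This note documents the models and procedures implemented in
`streamstoich`, the defaults and why they were chosen, the numerical
conventions, and the limitations a user should know before trusting the
output.

## Censoring Monte Carlo

Water-quality records carry qualifier flags. The pipeline replaces each
qualified concentration with one Monte-Carlo draw per realization:

* **measured** — unchanged.
* **estimated** — Normal(value, cv x value), truncated at zero *by
  resampling* rather than clipping, so no point mass accumulates at 0.
  Default `cv_estimated = 0.10` (unitless): a typical analytical relative
  error near detection limits. Results should be (and in our synthetic
  experiments are) insensitive to this knob at realistic censoring rates.
* **less than** — Uniform(`lower_bound_lt`, limit), where the stored value
  is the reporting limit. Default floor 0: maximally agnostic below the
  limit. This is deliberate: no censored-likelihood model (e.g. MLE for a
  left-censored lognormal) and no half-limit substitution.

One draw per qualified value per pipeline realization; the number of
realizations R defaults to 1. With R > 1 the derivation stages are pooled
across realizations while the mixed models use realization 0 only, to
avoid pseudo-replicating observations.

## Particulate derivation

DIN = NH3-N + NH4-N + (NO3+NO2)-N. If a component is missing it is treated
as zero and the record flagged "partial" (a strict mode propagates the
missingness instead); an all-missing sum is missing. Records with
DIN > TN or DIP > TP are removed before any ratio work and reported as
counts and fractions per analyte.

The dissolved-organic share is defined **relative to the residual**:
p = (TDN - DIN)/(TN - DIN), and analogously for P. This is the only
definition under which "total minus dissolved inorganic minus dissolved
organic" subtracts a fraction of the residual. Shares outside [0, 1]
(including non-positive residuals) are excluded and counted; fewer than 10
valid pairs is an error. The share pool is global across sites (a
site-stratified option exists); a diagnostic regression of site-mean
shares on each land-use proportion guards the pooling assumption.

For each record, `n_boot` = 1,000 shares are resampled with replacement,
candidates residual x (1 - p_b) are formed, and the particulate estimate
is a single uniform draw within the candidates' interquartile range. A
non-positive draw means the residual is plausibly all dissolved organic:
the record's PN (or PP) is set missing, excluded pairwise from ratio
analyses, and counted. A zero residual short-circuits to 0; a point-mass
share distribution collapses the IQR and returns the deterministic value.

## Homeostasis and discharge power laws

1/H is the OLS slope of log10(particulate molar N:P) on log10(dissolved
molar N:P); the intercept log10 c is reported in log10 units (the slope is
base-invariant). Plain OLS is used even though both ratios are noisy —
no errors-in-variables correction — so 1/H should be read as a descriptive
congruence slope, not a causal regulation parameter. TP-binned fits use
strict inequalities (TP < 0.025, TP > 0.10 mg/L) with the middle band
excluded; per-site fits require strictly more than 100 complete ratio
pairs. Power-law exponents b come from OLS of log10(N:P) on log10(Q) for
sites with strictly more than 10 usable records; b is invariant to
discharge unit changes.

Numerical convention: a constant response in any log-log regression
short-circuits to slope exactly 0 (p = 1), so the degenerate limits
("static particles", "chemostatic ratio") are exact rather than
floating-point residue of mean-centering.

## Land-use mixed models

Each response (log10 TN, DIN, PN, TP, DIP, PP) is fitted as

    response ~ log10 Q + pCRO + pHAY + pFOR + pURB + (1 | site)

by REML (statsmodels MixedLM) on complete cases, with Wald 95% CIs and
p-values (profile CIs are not provided by the backend). Standardized
coefficients are raw x sd(predictor) with the n-1 sample sd — identical to
refitting on z-scored predictors, and asserted to 1e-8 in the tests.
Marginal and conditional R² follow Nakagawa–Schielzeth for Gaussian
identity-link models: var(fixed) is the variance of the fixed-effect
linear predictor, var(site) the random-intercept variance, var(resid) the
residual variance. A site variance collapsing to ~0 is retained and
flagged singular. The percent-particulate side models use
100 x PN/TN (or PP/TP) as the response with land-use *percentages* as
predictors, so a slope of -0.02 reads "0.02 percentage points per 1% land
use"; zero-total records are excluded and counted. A constant response
(e.g. PN exactly proportional to TN) short-circuits to zero slopes with a
singular flag rather than a degenerate variance fit.

## Synthetic generator

The generator emulates the structure the analysis assumes, with full
ground truth. Defaults (all chosen once, before any recovery test was
run, by the power analysis below):

| parameter | default | meaning |
|---|---|---|
| `n_sites`, `obs_per_site` | 200 x 20 | short-record monitoring panel |
| `n_timeseries_sites`, `timeseries_obs` | 13 x 150 | long sequential records for per-site fits |
| `landuse_concentration` | (0.27, 0.18, 0.21, 0.375, 0.465) | Dirichlet over (crop, hay, urban, forest, other); means 18/12/14/25/31%, matching ~30% agriculture, 14% urban, 25% forest, with realistically sparse mixes |
| `discharge_logmean`, `discharge_logsd` | 3.0, 0.8 (log10 L/s) | baseflow-dominated discharge, independent of land use |
| `effects` | see `simulate._default_effects` | log10-concentration linear models for DIN, DIP and PN, keyed to continental-scale mixed-model estimates (e.g. crop -> log10 DIN effect 1.183) |
| `site_sd`, `resid_sd` | 0.12, 0.2 (log10 mg/L) | site heterogeneity kept moderate so recovery diagnostics are ~3-sigma checks at 200 sites |
| `true_log_c`, `true_inv_h` | 0.434, 0.096 | imposed particulate–dissolved N:P coupling |
| `np_resid_sd` | 0.25 (log10) | scatter around the coupling |
| `dom_beta_n`, `dom_beta_p` | Beta(4,2), Beta(2,4) | DON-heavy N residual, particle-heavy P residual |
| `detection_limits` | NH3N 0.01, NO3NO2N 0.04, DIP 0.002 mg/L | post-2003-style reporting limits producing a few percent less-than records |
| `censor_estimated_rate` | 0.05 | share of remaining limit-bearing values flagged estimated |

Generation order is fixed: dissolved concentrations from the linear
models, then the particulate ratio from the homeostasis coupling (PP
solved from PN and the ratio), then Beta-distributed organic shares with
DON = p/(1-p) x PN — so TN = DIN + DON + PN and TP = DIP + DOP + PP hold
*exactly* on every record, and the imposed 1/H is exactly the quantity the
estimator measures. Dates are regular sequences; the generator does not
emulate storm events, seasonality, serial correlation, analyte-correlated
reporting limits, or land-use–correlated discharge. Passing recovery tests
therefore demonstrates estimator correctness under the assumed structure,
not robustness to the full messiness of field records.

Power analysis behind the defaults: land-use effects are identified
between sites only, so a coefficient's standard error is roughly
sigma_b / (sd(p) sqrt(n_sites)) with sigma_b² = site_sd² +
resid_sd²/obs_per_site. The chosen Dirichlet gives sd(p_cro) ~ 0.24, so at
200 sites the land-use SEs are ~0.04–0.05 and ±0.1 / ±0.15 recovery bands
are ~2.5–3.5 sigma events; the 1/H standard error at ~6,000 records is
~0.01.

## Determinism

A single global seed is expanded through `SeedSequence` substreams keyed
on (stage, site, date, analyte, realization), so every draw is independent
of record order and of unrelated records, and a pipeline run is
bit-reproducible: two runs with the same config and seed produce
byte-identical outputs (no output embeds a timestamp).

## Known limitations

* **Censoring couples the regression axes.** Imputed DIN and DIP enter
  both the dissolved ratio (x) and the particulate residuals (y). In
  particular, Uniform(0, limit) draws for less-than DIP create
  high-leverage x errors, attenuating the fitted 1/H by roughly -0.01 at
  the default ~1–2% DIP censoring (and more at higher censoring). This is
  a property of the method itself, also present when it is applied to real
  records; the recovery tests use bands wide enough to include it, and the
  censoring-free configuration recovers the true slope without bias.
* Plain OLS for 1/H and b: both variables noisy, slopes mildly attenuated
  in general; no errors-in-variables correction.
* Wald inference throughout the mixed models; no model selection, no
  spatial/temporal correlation structure beyond the site intercept.
* Thresholds are a fixed registry of published values (extensible via
  CSV); the pipeline does not derive thresholds from dose–response data.
* The loess-through-percentiles curves use sliding-window empirical
  percentiles (half-width 5 land-use %, grid step 1, >= 10 points per
  window) smoothed by lowess with span 0.75 and *zero robustness
  iterations* — the smoother is then linear in y, which guarantees the
  10th <= 25th <= ... <= 90th ordering of the curves.
* Quartiles and medians use linear interpolation (numpy default, R
  type-7), stated here for reproducibility.
* Test problem sizes are scaled to run on one CPU in minutes (e.g. 5-seed
  recovery batches, 1,000-seed type-I calibrations at <= 94 sites); the
  full-size calibrations live in `scripts/acceptance.py`.
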