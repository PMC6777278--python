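# Methods

This note records the statistical procedures the package implements, the
defaults and why they were chosen, and what the synthetic-data tests do and
do not establish about real data.

## Study design being emulated

A single participant answers a 4-item EMA by text message twice daily for
28 days (56 twelve-hour measurement periods): motivation to reduce
drinking, perceived usefulness of the app, and perceived lack of time on
1–7 Likert scales, plus a count of alcoholic drinks since the last prompt.
A daily app reminder (at most one per 24 h, coded 1 in the period it
arrives) may be switched off per participant. Engagement outcomes are never
self-reported: they are derived from the app's automatically recorded
screen-view log.

## Outcome derivation

- **Sessionization.** Events are sorted; a session (log-in) begins at the
  first event and at every event whose gap from the previous event is
  **≥ 30 minutes** ("at least 30 min of inactivity" reads as a closed
  threshold, so a gap of exactly 30:00 splits).
- **Windows.** Half-open 12-hour windows abut exactly and are anchored at
  each participant's configured morning EMA time (default 10:00/22:00,
  within the protocol's 06:00–10:00 morning window). A session belongs to
  the window containing its *first* event — a log-in happens when the app
  is opened — and sessions are never split across windows.
- **Amount.** Sum over sessions of (last event − first event) in seconds.
  A one-view session contributes 0 s; no dwell time is invented for the
  final screen of a session (a fixed dwell constant exists as an option but
  is off by default, because any value would be arbitrary).
- **Depth.** Distinct components viewed in a window divided by the size of
  the component set (7). Percentages are rounded half away from zero, the
  convention that reproduces printed values such as 6/7 → 86% and 1/7 → 14%.
- **Compliance.** Per participant, 100·(responses)/(expected), rounded to
  integer percent; across participants the mean and *population* SD of the
  rounded percentages are reported (this is the convention that matches the
  published descriptive, e.g. SD 5.8 rather than the sample-SD 6.1).

## Missing-data handling

Time series with **> 5%** missing self-report cells are multiply imputed;
below that threshold complete cases are used. Imputation is
**EM-with-bootstrapping** under a joint Gaussian model: each of m = 5
imputations bootstraps the 56 records, runs EM (relative log-likelihood
tolerance 1e-6, max 500 iterations, ridge 1e-4 on near-singular
covariances) to obtain a mean/covariance draw, then samples missing cells
from the conditional normal given the record's observed cells. Likert
draws are rounded and clipped to [1, 7], counts rounded and floored at 0,
the binary reminder thresholded at 0.5. Observed cells are never altered.

A polynomial time trend (standardized t, t²) can join the joint model. In
`auto` mode the trend is chosen by imputation precision: for every imputed
cell, the m draws give a t-based 95% CI of that data point's mean; the
average width is compared across trend candidates, and a trend is adopted
only when it narrows the average width by **more than 10%**. The margin is
deliberately larger than the spurious ~5–8% narrowing that two irrelevant
covariates produce on a 56-record series by absorbing residual variance,
while genuine drift narrows the widths severalfold; exact ties go to the
lower-order trend.

Downstream model coefficients are estimated on each completed dataset and
combined by **Rubin's rules**: pooled point = mean of estimates, total
variance T = W + (1 + 1/m)B, df = (m−1)(1 + W/((1+1/m)B))², infinite when
B = 0. Backward-selection results are combined by majority vote on the
retained predictor set, then the voted model is refit on every dataset and
pooled — predictor sets can legitimately differ across imputations, and a
vote is the simplest reproducible reconciliation. A cell-wise combination
(averaging imputed values, for descriptive tables) is also available.

## The count-regression engine

Penalized IRLS for a log-link count model with three blocks:

1. **Parametric terms** for the EMA predictors (reported as IRRs).
2. **Cyclic cubic regression spline** on day-of-week, period 7, basis
   dimension k = 5 (valid range 3–7): the spline interpolates values at
   wrap-around knots; value/second-derivative continuity at the period ends
   is built into the banded construction, the constant function is exactly
   representable with zero penalty, and the penalty is the integrated
   squared second derivative. Identifiability via a sum-to-zero constraint
   (null-space reparameterization). The smoothing parameter is chosen by
   GCV, n·D/(n − edf)², over a 23-point log-spaced grid on the
   independence fit and then held fixed.
3. **ARMA(p, q) working correlation** (p, q ∈ {0, 1, 2}): iterate (i) a
   penalized GLS step solving (XᵀW^{1/2}R⁻¹W^{1/2}X + λS)β = XᵀW^{1/2}R⁻¹W^{1/2}z
   on the working response, (ii) an ARMA refit to the Pearson residuals —
   Yule–Walker for pure AR (fast, used in the power loop), exact ARIMA
   maximum likelihood otherwise — with stationarity/invertibility enforced,
   until the ARMA parameters stabilize (tolerance 1e-3, max 15 sweeps). If
   ARMA estimation fails the fit falls back to independent errors and is
   flagged, mirroring how analyses of this design degrade to an
   uncorrelated additive model when the correlated fit will not converge.

Dispersion is Pearson χ²/(n − edf); the family is promoted to
quasi-Poisson above a threshold of 1.5, scaling the covariance (a
frequentist F⁻¹MF⁻¹ sandwich in the penalized case, which collapses to the
textbook φ(XᵀWX)⁻¹ for unpenalized fits). CIs are Wald with z = 1.96;
p-values are two-sided Wald. With p = q = 0, no smooth and Poisson family
the engine reproduces an ordinary Poisson GLM to numerical precision; this
oracle equivalence is tested against an independent IRLS implementation.

**Structure selection.** Candidates over the (p, q) grid are compared on
the *working-model AIC*: the marginal Gaussian log-likelihood of the
standardized working residuals under the candidate's ARMA covariance with
profiled scale, penalized by 2·(edf + p + q + 1). The count-scale
(quasi-)likelihood is invariant to the working correlation, so it cannot
rank correlation structures — any criterion built on it degenerates to
always choosing (0, 0); the working-model likelihood is what linear
mixed-effects machinery underneath additive-model software effectively
compares. Exact ties break toward smaller p + q, then smaller p. The
count-scale AIC (−2ℓ + 2·edf, QAIC = −2ℓ/φ̂ + 2(k+1) under
overdispersion) is still reported and drives **backward elimination** of
predictors, where the likelihood does respond: at each step the predictor
whose removal improves the criterion most is dropped, until no removal
helps. Predictors absent from the final model are reported as "not
included in the best-fitting model"; a predictor with no within-person
variance (e.g. the reminder for a participant who opted out) is an error
at fit level and excluded upstream by the pipeline.

The *amount* outcome (seconds of engagement per window) is modelled with
identical machinery, treating rounded seconds as counts under
quasi-Poisson; zero-amount windows are retained.

## Synthetic-data generator

What it emulates, and the defaults (which are also the test conditions):

- Likert predictors ride a stationary Gaussian ARMA(1,1) latent process,
  rounded and clipped to [1, 7]; drink counts rounded and floored at 0.
  Default AR coefficient 0.5 — a mid-range positive value consistent with
  measurements resembling those taken 12 hours earlier; the perceived-
  usefulness item uses the canonical mean 3.18, SD 0.93. The process is
  treated as stationary ARMA despite the nominal "integrated" label in the
  design's assumption table, which also states a stationary mean and SD —
  a unit root would contradict both.
- Counts: log μ = intercept + Σβ·(x − mean) + seasonal sinusoid
  (amplitude on the log scale, period 7 days; a parametric truth makes
  smooth-recovery testable, unlike a nonparametric one). Continuous
  predictors are centred at their latent means so the intercept is the
  expected count at average predictor levels; the binary reminder is
  centred at 0 so exp(β) contrasts reminder vs none. Overdispersion d ≥ 1
  via a gamma-Poisson mixture with Var = d·μ exactly; d = 1 is pure
  Poisson. Default intercept log(0.7): per-period log-in means of engaged
  app users run ~0.2–1.2, and the 30-minute gap rule physically caps a
  12-hour window at ~22 sessions, so study-scale baselines — not the
  11.7/period power-analysis assumption, which lives in `PowerConfig` —
  are the realizable regime for event-log generation.
- Event logs invert the sessionizer: sessions sit ≥ 16 min from window
  edges and ≥ 31 min apart, views within a session < 30 min apart (views
  are evenly spaced over the session's duration, with enough views that no
  internal gap reaches the threshold), so `sessionize` recovers the exact
  per-window counts — a property test, not a coincidence. Per-session
  durations are log-normal (median 30 s, σ = 1); amount-specific effects
  shift the log-median so the expected amount follows its own linear
  predictor. Infeasible requests name the offending period.
- Missingness is record-level (a skipped text message loses all four
  self-report items at once; automatically recorded outcomes and the
  reminder indicator are never missing), MCAR or MAR-on-observed (logistic
  in the observed log-in count, intercept calibrated to the target rate).
  Default rate 8%, the midpoint of the 0–16% range seen in compliant
  participants.

What it does **not** emulate: floor effects from participants who abandon
the app, reactivity of self-report to the prompts themselves, reminder
timing changes mid-study, clock changes/time zones, and measurement error
in screen-view capture. Passing recovery tests on this generator therefore
shows the estimator chain is correct under its assumed data-generating
process, not that those assumptions hold in any particular real dataset.

## Power analysis

Each replicate simulates the design (AR(1) Gaussian predictor, Poisson
counts with slope log IRR on the centred predictor) and refits the
analysis model — by default a Poisson regression with lag-1 working
correlation, the simplest specification that converges reliably at n = 56;
the full smooth/quasi machinery is configurable but is not what a
per-replicate power loop needs. Power is the Wald-rejection fraction among
converged replicates (flagged unreliable below 90% convergence), with a
Wilson 95% Monte Carlo interval. Type-I error at IRR = 1 sits at ~0.05–0.06
(the small excess comes from estimating the working correlation at n = 56).

**A calibration caveat.** Under the stated assumptions — outcome mean 11.7
per period, predictor SD 0.93, n = 56, IRR = 1.8 — the Wald statistic for
the slope has expectation ≈ log(1.8)·√(56·11.7·0.93²) ≈ 14, so simulated
power is effectively 100%, regardless of the predictor's AR coefficient
(swept 0.2–0.8) or the analysis model. A power near the historically
reported 80% for this design would require a per-period mean near 0.5 —
the scale actually observed in such studies — suggesting the 11.7 figure
originated as a coarser aggregate. The package reports what the stated
assumptions imply; `scripts/acceptance.py` recomputes this number from
scratch at every run.

## Known limitations

- The ARMA working-correlation covariance is model-based, not a robust
  sandwich; with badly misspecified correlation at n = 56 the CIs can be
  mildly anticonservative (visible as the ~0.06 type-I error above).
- The Gaussian imputation model treats Likert and count items as
  continuous and post-processes draws; with 56 records and whole-record
  missingness this is the standard pragmatic choice, not a congenial model.
- Backward selection inherits the usual instability of stepwise methods on
  short series; the elimination trace and the univariable table are
  reported precisely so that no conclusion rests on the final model alone.
- Complete-case analysis below the 5% threshold leaves small gaps in the
  time index; the ARMA correlation treats the remaining series as
  contiguous, a negligible approximation at ≤ 3 missing periods.
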