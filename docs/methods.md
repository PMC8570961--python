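# Methods

## The model

`aclfjm` implements a shared-random-effects joint model for liver-transplant
waitlist candidates. The longitudinal submodel describes each candidate's
repeated MELD-Na measurements as a noisy patient-specific trajectory,

    y_ij = m_i(t_ij) + e_ij,
    m_i(t) = x_i(t)' beta + z_i(t)' b_i,
    b_i ~ N(0, D),   e_ij ~ N(0, sigma^2),

with a fixed design `x` (intercept, time basis, optional baseline
covariates) and a random design `z` (intercept + time slope by default; the
time basis may be linear or a natural cubic spline so both stable chronic
disease and fast non-linear deterioration in acute-on-chronic liver failure
(ACLF) are representable). The survival submodel ties the death hazard to
the *current* value and *current* slope of that latent trajectory:

    h_i(t) = h0(t) * exp( gamma' w_i
                          + alpha_value * m_i(t)
                          + alpha_slope * m_i'(t) ),

where `w_i` holds baseline covariates (age, sex, cirrhosis, ACLF-grade
indicators, spontaneous bacterial peritonitis, life-support dependency) and
`h0` is piecewise constant on segments cut at event-time quantiles (7 by
default). The two submodels share `b_i`, so the marginal likelihood
integrates it out per patient:

    L_i = Integral  N(y_i | b) * h_i(T_i|b)^delta_i * exp(-H_i(T_i|b)) * N(b; 0, D)  db.

Transplantation and administrative end of follow-up are treated as right
censoring, matching a censor-at-transplant analysis; competing-risk
treatment of transplant is out of scope.

## Estimation and numerics

* The random-effects integral uses adaptive Gauss-Hermite quadrature, 3
  nodes per dimension by default, with the grid placed at the mode of each
  patient's *full* posterior (found by a short damped Newton search — the
  survival factor tilts the posterior away from its longitudinal-only
  Gaussian) and scaled by the full posterior curvature. The test suite
  checks the per-patient accuracy of the 3-node grid (mean gap to a 9-node
  reference well under 1e-3) and the cohort-level convergence of the 5-node
  grid; the 3-node grid retains a small signed per-patient skewness bias
  (~2e-5) that necessarily accumulates over a cohort sum, which is why the
  accuracy contract is stated per patient. Log-sum-exp keeps the node sum
  stable.
* Cumulative hazards integrate `exp(alpha_v m + alpha_s m')` with 5-point
  Gauss-Legendre rules per baseline-hazard segment (exact for the
  piecewise-constant baseline, near-exact for the exponential-of-linear
  integrand of a linear trajectory; the node count is configurable).
* All parameters are estimated jointly by L-BFGS-B on an unconstrained
  parameterization (log-Cholesky for D, log sigma, log segment heights),
  with 2-point numeric gradients and a generous quasi-Newton memory
  (`maxcor=40`, which measurably improves the optimum on this likelihood's
  ill-conditioned directions). Initialization is two-stage: the mixed model
  alone (direct maximization of its closed-form marginal Gaussian
  likelihood, beta profiled out by GLS), then a Cox regression on the
  empirical-Bayes fitted value and slope. Standard errors come from the
  observed information (central-difference Hessian at the optimum).
* The mixed model is estimated by maximum likelihood, not REML, because its
  parameters are re-estimated jointly anyway; for near noise-free data the
  residual SD is floored at 1e-6 so interpolating fits remain well posed.
* Event ties need no special handling: the baseline hazard is continuous
  piecewise-constant, so the likelihood is Breslow-consistent by
  construction.
* Slopes of spline bases use analytic basis derivatives everywhere, never
  finite differences.

Units: time is days since first active listing, trajectories are MELD-Na
points, `alpha_slope` is log-hazard per point/day internally; reports also
express the slope hazard ratio per point/30-days (the published slope
multiplier's time unit is not stated at the source, so the fixture stores
it unit-agnostically and it is used only in worked examples). The published
age multiplier is likewise stored verbatim; the synthetic generator
interprets it per decade of age, since a 38% hazard increase per single
year is not clinically plausible.

## Dynamic prediction

For a patient with history up to a landmark t, the conditional survival is

    pi_i(u|t) = E[ S_i(u|b) / S_i(t|b) | y_i up to t, T_i > t ].

The default estimator is importance sampling: draws from a multivariate t
(df 4) centred at the longitudinal posterior, reweighted by the exact
posterior including the survival-to-t factor (200 draws, seedable;
percentile bands from the weighted draws, widened if needed so the band
always contains the point estimate). A plug-in mode evaluates the ratio at
the empirical-Bayes mode only; it is essentially free and is used wherever
whole-cohort risks are refreshed repeatedly (validation grids, allocation
experiment). pi(t|t) = 1 holds exactly in both modes and curves are
monotone non-increasing by construction. Beyond the last hazard knot the
final segment's hazard is extrapolated, so predictions remain defined past
the training follow-up. Whether a published implementation of this kind of
tool uses simulation or first-order prediction is typically unstated; both
are provided and the choice is an explicit argument.

## Validation metrics

Landmarked discrimination and calibration at landmarks {0, 2, 7, 14} days
and horizons {28, 90} days:

* time-dependent AUC: probability that a patient dying in (t, t+h] carries
  a higher risk score than one surviving past t+h, IPCW-weighted (censoring
  distribution by Kaplan-Meier on the at-risk set, case weight 1/G(T-),
  control weight 1/G(t+h));
* prediction error: IPCW Brier score of pi(t+h|t) against the survival
  indicator, in-window censored subjects contributing through the weights
  rather than being dropped.

These are the closest published conventions for this task; the estimators
sit behind a small metric interface so variants can be swapped in.
Bootstrap CIs are percentile intervals over patient-level resamples, with
resamples shared between models so differences are paired. An undefined
metric (no events, vanished censoring distribution) raises rather than
silently returning 0.5. The benchmark comparator is a Cox model on the
single most recent MELD-Na score — the current-allocation logic, which
ignores all previous measurements. Per-grade AUC summaries stratify by
baseline ACLF grade (landmark-time grade would also be defensible; baseline
is the default because it is always available).

## Synthetic cohorts

The generator (`aclfjm.simulate`) inverts the model above so that every
downstream stage is testable without the restricted registry data it was
designed for:

* covariate marginals: ACLF-grade prevalence 66.7/15.9/10.3/7.1%, grade
  shifts of the trajectory intercept +0/+12/+18/+22 points around a base of
  15 (matching the reported grade-wise median scores), etiology frequencies
  from the reported cohort mix, age ~ N(55, 10) clipped to adulthood;
* survival coefficients default to the logs of the published multipliers
  (age per decade); `alpha_value = ln 1.15`; `alpha_slope` defaults to 6.0
  per point/day so the slope channel is an active risk factor;
* death times by inverse-transform sampling on a trapezoid-rule cumulative
  hazard (0.25-day grid), auditable against the closed form when the
  trajectory is linear and the baseline hazard constant; transplant is an
  independent exponential censoring process (0.008/day), administrative
  horizon 365 days;
* measurement times: listing at t=0 then lognormal gaps with median 7 days
  (the registry's true cadence is not published; this is a modelling
  choice), stopping at the event;
* a registry-style output mode rounds and clamps observed scores to
  integers 6-40; the default continuous mode keeps the Gaussian observation
  for clean parameter-recovery tests.

Named presets freeze the study conditions used by the test suite:
`recovery_config` (1,000 grade-0 patients, two survival covariates, 45-day
horizon giving ~6 measurements each) for parameter recovery and CI
coverage; `slope_effect_config` (`alpha_slope=8`, slope SD 0.08/day) as the
strong-slope condition; `value_only_config` (no slope effect, near
noise-free observations, so the latest score is essentially sufficient) as
the null; `null_association_config` (gamma = alpha = 0) for checking the
event-time distribution against the baseline hazard alone.

What the generator does **not** emulate: informative measurement timing
(sicker patients are re-certified more often in reality), severity-dependent
transplant selection (an optional stress-test mode exists but the default is
independent censoring), measurement error structure beyond iid Gaussian,
re-listing, and regional allocation mechanics. Passing tests therefore
demonstrate internal correctness and qualitative behaviour of the method,
not registry-level performance numbers: headline discrimination values from
the original registry analysis are not reproducible from synthetic data, and
the package's validation targets are directional (joint model beats the
last-value benchmark when history carries signal; ties when it does not).

## Allocation experiment

Graft offers within (0, 28] days (count defaulting to 8.63% of the cohort,
the reported offers-to-candidates ratio; times as uniform order statistics
because only the count is published) are assigned to the top-ranked active
candidate under each rule: joint-model predicted 28-day survival (refreshed
with each measurement up to the offer time; a frozen-at-baseline mode
exists for comparison) versus latest MELD-Na. Candidates leave the pool at
their recorded event time; dying between offers removes a patient from
candidacy (keeping them would inflate the prioritized sets). Ties break by
longer waiting time, then lexicographic id, so the experiment is fully
deterministic given the offer stream. With equal offer counts the two
discordant priority groups have equal size by construction; the scientific
content is in their 28-day mortality contrast. The experiment deliberately
does not represent the complex reality of liver allocation (geography,
blood type, refusals, post-transplant outcomes).

## Problem sizes in the shipped tests

The suite exercises parameter recovery at n=1,000 patients with 20
replicates for CI coverage (pooled over parameters), the directional
validation grid on a 9,000-patient cohort (~3,000 test patients), and the
allocation contrast on the same test cohort. These sizes make the full
suite runnable on a single desktop CPU while leaving the Monte-Carlo error
well below the effect sizes being asserted.

## Known limitations

* Numeric (not analytic) gradients make very large cohorts (tens of
  thousands of patients) slow to fit; the likelihood itself is fully
  vectorized.
* The random-effects dimension is 2 by default; `random="full"` with a
  spline basis grows the Gauss-Hermite grid exponentially and has only been
  exercised lightly.
* IPCW metrics assume censoring independent of the risk score conditional
  on being at risk; severity-dependent transplant censoring violates this
  and is exactly the stress mode the generator can produce.
* The MELD-Na arithmetic implements the standard allocation formula of the
  2016-2019 era; MELD 3.0 and pediatric variants are out of scope, as is
  the CLIF-C ACLF score (it needs leucocyte counts that the motivating
  registry lacks).
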