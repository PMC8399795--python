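# Methods

## Data-generating model

Each simulated trial has `n_subjects = 207` participants entering at t = 0,
assigned to treatment with probability 0.5, and followed to the event or to
administrative censoring at the horizon (50 months; censored records carry
`time = 50` exactly, `event = 0`). The control-arm hazard is Weibull,
h0(t) = λγt^{γ−1}, with three calibrated shapes:

| shape      | λ    | γ   | S0(50)  |
|------------|------|-----|---------|
| decreasing | 0.15 | 0.9 | 0.0063  |
| constant   | 0.10 | 1.0 | 0.0067  |
| increasing | 0.07 | 1.1 | 0.0057  |

The scales are calibrated so the three shapes agree on S0(50) to within
0.002: every scenario observes (in expectation) the same number of events,
and only their timing differs. The treatment hazard is multiplied by a
piecewise factor with one change point: HR = 1 before `t_lag` and
exp(−0.4) ≈ 0.67 after (lag form), or the reverse (early-effect form).
The cumulative hazard is available in closed form on both sides of the
change point, and event times are drawn by inverse-transform sampling:
U ~ Uniform(0,1), solve H_arm(t) = −ln U piecewise. The simulator therefore
follows the analytic survival law exactly (tested by probability-integral
transform), and the analytic event-fraction oracle

  [F0(c) + F1(c)] / [F0(50) + F1(50)],  F = 1 − S,

gives the expected share of events inside the no-effect window.

Why 207 subjects: the design calculation fixes 202 *events*, not
participants. Under the PH design cell the expected event probability per
subject is (0.9933 + 0.9650)/2 ≈ 0.979, and 207 is the smallest n whose
expected event count reaches 202. Because all three shapes are calibrated to
the same S0(50), this holds across scenarios.

What the generator deliberately omits (and hence what passing tests cannot
speak to): staggered accrual, dropout or any non-administrative censoring,
covariates beyond the treatment indicator, frailty, and more than one change
point. Real trials with slow accrual or informative censoring can behave
differently, particularly for the weighted tests whose power depends on the
censoring pattern.

## Estimators

* **Cox / landmark** — lifelines `CoxPHFitter` with Efron tie handling
  (ties occur only through floating-point coincidence in this continuous
  DGM). The landmark fit drops subjects with `time <= t_LM` and keeps the
  original timescale (the partial likelihood only sees risk-set order, so no
  origin reset is needed). Pre-specified landmarks: t_LM = 3 for lag cells,
  t_LM = 10 for early-effect cells.
* **Piecewise exponential** — episode-split data at interior cutpoints
  {1, 3, 10, 20} (chosen to bracket every change time in the grid), fitted
  as a Poisson GLM with log person-time offset (statsmodels); PE1 reports
  the single summary HR, PE2 adds a treatment-by-period interaction at
  t_PE = 3 and reports the HR from events after t_PE. PE2 is computed for
  lag-type and null cells only in the canonical pipeline.
* **Weibull PH/AFT** — own full maximum likelihood in either
  parameterisation (BFGS plus Newton polishing on the closed-form
  log-likelihood; covariance from the finite-difference observed
  information). Fitting both parameterisations separately lets the identity
  β_PH = −β_AFT·γ̂ serve as an internal consistency check (it holds to
  1e−6 on every fit); lifelines' `WeibullAFTFitter` is an independent
  cross-check in the tests.
* **Flexible parametric (spline) model** — ln H(t) = s(ln t) + X·β with a
  restricted cubic spline s: 5 df baseline (boundary knots at the min/max
  uncensored log event time, interior knots at the 20/40/60/80th centiles of
  uncensored log times), optional 2-df spline-by-treatment interaction for a
  time-dependent effect (interior knot at the median). Full likelihood
  maximised by BFGS with the analytic gradient, initialised by projecting a
  Weibull surface onto the basis; a quadratic penalty keeps the fitted
  hazard positive at event times, and a fit whose cumulative hazard is
  non-monotone on the observation grid is flagged non-converged. Covariance
  from finite differences of the analytic gradient.
* **ΔRMST** — both arms' survival predicted on a 2000-point uniform grid to
  t* (halving the grid moves the estimate by < 1e−4 months), trapezoid
  integration, delta-method SE from the analytic gradient
  dS/dθ = −S·H·(∂η/∂θ) propagated through the coefficient covariance.
  Default t* is the last uncensored event time, so the same events inform
  ΔRMST as inform the HR and TR.

Non-converged fits are never silently dropped: they are flagged, excluded
from performance numerators and denominators, and counted in an explicit
`n_nonconverged` column.

## Tests of equal survival functions

The FH(ρ,γ) statistic is Σ w_j(O_j − E_j) / sqrt(Σ w_j² V_j) with
hypergeometric variances and weights from the pooled Kaplan–Meier left
limit; FH(0,0) is the classical logrank.

The versatile (max-combo) test takes Z_m = max(|Z₁|,|Z₂|,|Z₃|) over
FH(0,0), FH(1,0), FH(0,1). Because the three weight functions satisfy
1 = Ŝ(t−) + (1 − Ŝ(t−)) at every event time, the scores obey U₁ = U₂ + U₃
exactly and the null covariance (estimated analytically from the weighted
score cross-products) has rank 2. The p-value is therefore computed exactly
on the two-dimensional support: a Gauss–Legendre integral over Z₂ of the
conditional normal band for Z₃, split at the points where the rectangle
constraints switch. This is deterministic and accurate to ~1e−6; the
general full-rank path (used only for non-degenerate inputs) evaluates the
multivariate normal rectangle with a fixed-seed quasi-Monte-Carlo rule so
repeated calls agree exactly.

The combination test uses a t* grid of 10 equally spaced times between the
10th percentile of pooled event times and the last uncensored event, the
maximal absolute standardised KM ΔRMST over that grid (Greenwood-type RMST
variance), and arm-label permutations. The overall pCT is the permutation
p-value of min(p_cox, p_rmst) under the same permutations, which preserves
the null law of the minimum. Inside the permutation loop the Cox p-value
comes from a Newton solver for the single binary covariate vectorised
across permutations (Breslow ties; ties have probability zero here); the
headline Cox fit remains the Efron/lifelines route, and a test pins the two
routes together to 1e−6. Default 1000 permutations (a dedicated RNG
substream), 500 in the large Type I error sweeps.

The RMST component is estimated nonparametrically (KM integral) rather than
from a fitted spline model: refitting a parametric model inside every
permutation would be orders of magnitude slower at study scale. The cost is
a few percentage points of PH power for the combination test relative to the
Cox comparator (measured ≈6–7 pp in the design cell), which is the price of
its insurance against non-proportionality.

## Performance measures and benchmark

Power = share of replicates with p < 0.05; coverage = share of 95% CIs
containing the design value (log scale for HR/TR, months for ΔRMST);
STE = (1 − mean ĤR)/(1 − 0.67)·100, (mean T̂R − 1)/(e^{0.4} − 1)·100, or
mean Δ̂RMST / ΔRMST_design·100. ΔRMST_design comes from a single large
(default N = 250,000) simulation of the design cell, integrated
nonparametrically under the KM curve at t* = 50 — a model-free benchmark
(≈ 4.47 months, matching the exponential closed form
(1−e^{−3.35})/0.067 − (1−e^{−5})/0.10). The required-events formula is
Freedman's, ((1+HR)/(1−HR))²(z_{1−α/2}+z_{power})², which gives 202 at the
design HR (Schoenfeld's form gives 197 and is not used). Coverage for
ΔRMST is always measured against the PH design benchmark, including in
non-PH cells, mirroring how a trial would be judged against its design
assumptions.

## Seeding and reproducibility

Replicate r of scenario s (indexed in the fixed 27-cell grid order) draws
from `SeedSequence([base_seed, s, r])`; the combination test's permutations
use the child `[base_seed, s, r, 1]`. Simulated data therefore never depend
on which methods or tests are selected, and two runs of the same
configuration produce byte-identical CSVs.

## Replicate counts used by the test suite

The published scale is 2000 replicates per cell (worst-case MCSE 1.1%).
The suite reproduces the design cell at that scale for the Cox model and
uses smaller, fixed sizes elsewhere, chosen so every comparison still has
the Monte Carlo resolution it needs: 500 replicates for the model-agreement
checks, 1000 for Type I error (combination test at 500 permutations), and
150 per cell for the 12-cell lag power surface. Power-ordering comparisons
across change times reuse the same replicate substreams in every cell
(common random numbers), so differences are paired and monotonicity is
assessed against the paired Monte Carlo standard error rather than the much
larger independent-sample one.

## Known limitations

* The spline knot rule and optimiser settings of the original Stata fits are
  not published; agreement of the flexible-parametric results is asymptotic,
  not digit-for-digit.
* The combination test's t* grid and permutation count are design choices
  (the source describes "several prespecified values of t*"); its power is
  comparable to, but not exactly, any particular published figure.
* With 207 subjects and ~98% event probability, the last uncensored event
  falls close to the horizon, so ΔRMST at t* (last event) and at t* = 50 are
  practically indistinguishable — the study's own observation.
* The mean of exponentiated Cox coefficients in the design cell is slightly
  above e^{−0.4} (Jensen's inequality at SE ≈ 0.15); the mean *log* HR is
  unbiased to Monte Carlo resolution.
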