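# Methods

`apcmap` implements the analysis chain used for descriptive cancer-registry
epidemiology of a multi-area country: age-standardized incidence rates,
average-annual-percent-change (AAPC) trends, an age-period-cohort (APC)
decomposition identified by the constant-relative-variation (CRV) rule, and
disease maps of standardized incidence ratios (SIR) and per-area AAPCs
stabilized by empirical-Bayes shrinkage plus ordinary kriging. Because
registry microdata are access-restricted, the package ships a synthetic
registry generator with full ground truth; every statistical claim the test
suite makes is a claim about recovery of that truth.

## Rates and standardization

Age-specific rates are `100000 * O_a / P_a` on inclusive 5-year bands.
Direct standardization uses the WHO 2000 world-standard weights (18 bands,
0-4 ... 85+), re-normalized to the age range in use — analyses restricted
to ages 30-84 use the eleven matching weights rescaled to sum to one. The
ASR variance is the usual Poisson form `sum_a w_a^2 r_a 1e5 / P_a`, with a
gamma (Fay–Feuer-style) confidence interval; this is standard registry
practice rather than a contribution of this package.

Indirect standardization produces per-area expected counts
`E_i = sum_a P_ia R_a` from reference rates `R_a` pooled over a declared
window (default: the last five data years, configurable), and
`SIR_i = O_i / E_i`. The SIR sampling variance is the delta-method Poisson
form with a one-case floor, `sigma_i^2 = max(O_i, 1) / E_i^2`; the floor
gives zero-count areas a finite, large variance so they can still be shrunk
toward the null instead of being dropped. When the observed window equals
the reference window, the person-years-weighted pooled SIR is exactly 1 —
an algebraic conservation the tests assert to 1e-12.

## AAPC

A rate series is modelled as a continuous piecewise log-linear function of
calendar year, fit by Poisson regression on counts with a log person-years
offset (a weighted-least-squares fit on log ASR is available as a config
fallback to mimic common registry software, via `asr_series`). Breakpoints
are placed by exhaustive search over interior integer years with a minimum
segment length of 3 calendar years; the number of joinpoints (default: up
to 2 nationally, 1 per area) is chosen by BIC. This deterministic selection
was chosen over the permutation test deliberately: it is desk-scale,
reproducible, and testable against an independent exhaustive-likelihood
oracle.

The AAPC over `[y0, y1]` is `100 * (exp(sum_j w_j b_j) - 1)` with `b_j` the
segment slopes and `w_j` the fraction of the interval each segment covers.
Its CI is large-sample normal on the log scale; `TrendEstimate.se_log`
carries the log-scale SE so downstream users (the AAPC maps) can build
delta-method variances `((100 + AAPC) * se_log)^2` that stay finite even
when the exponentiated CI overflows on degenerate sparse series.

Per-area series with zero cases over the interval are flagged unestimable
and excluded from mapping input. Sparse per-area series can produce a
minority of wildly unstable AAPCs (a 3-year segment containing two cases);
their variances are correspondingly enormous, and the mapping stage shrinks
them essentially to the null — which is the stabilization's purpose, not a
failure mode.

## APC decomposition under constant relative variation

The grid cross-classifies eleven 5-year age bands (30-84) with 5-year
periods; on the 1997-2016 window this is the 11 x 4 design with 44 cells
and 14 cohorts indexed `c = p - a + (A - 1)`, whose median birth years are
the period midpoint minus the age midpoint (1917, 1922, ..., 1982).

The log rate is `mu + alpha_a + pi_p + gamma_c`. Because
cohort = period - age, a linear trend ("drift") can be moved between the
period and cohort effects, with a compensating linear tilt of the age
curve, without changing any fitted rate — the likelihood is exactly flat
along this direction. Estimation proceeds in two steps:

1. **Reference fit.** Poisson log-linear fit with zero-sum effect coding,
   the period effects additionally constrained to zero linear trend, i.e.
   all drift anchored in the cohort effects. Curvatures (second
   differences) of `pi` and `gamma` and the net drift are identifiable and
   do not depend on this anchor.
2. **CRV balancing.** Define the relative variation of an effect vector as
   the coefficient of variation of its exponentials (rate-ratio scale) —
   scale-free and shift-invariant on the log scale. Search the drift
   allocation `delta` along the exact invariance direction, between the
   two extreme allocations (all drift in cohort; all drift in period), for
   the root of `RV(pi(delta)) - RV(gamma(delta))`, by Brent's method after
   a sign-change check. "Relative variation" is not pinned to a formula by
   the verbal description it comes from; the CV-of-rate-ratios reading was
   chosen as the most literal scale-free one, and the full delta-profile
   of both RVs is returned so users can judge sensitivity.

The reallocation algebra is
`alpha -= delta*(a - abar)`, `pi += delta*(p - pbar)`,
`gamma -= delta*(c - cbar)` with centred indices; the three shifts cancel
cell-by-cell, so fitted rates and the deviance are invariant to machine
precision (asserted to 1e-10 / 1e-8). Note the age tilt is forced by the
algebra: moving drift between period and cohort alone changes fitted
rates by a linear-in-age term that no intercept adjustment can absorb.

**When balancing fails.** If the RV gap does not change sign across the
bracket — typically when the cohort curvature's RV exceeds anything the
period side can reach, as happens for sparse strata whose noisy cohort
estimates inflate the RV — the solver reports the candidate minima of the
absolute gap and raises, rather than silently picking an allocation. The
CRV identification is an assumption about the data; data that violate it
should say so.

**Precision.** The drift allocation is identified only through the CRV
balancing, and its estimation error is amplified at the cohort extremes by
the index spread (about 7 bands). Recovery error on the log scale scales
as `1/sqrt(person-years per cell)`: on the shipped truth the max effect
error is roughly 0.07 at 1e6 person-years/cell, 0.02 at 1e7 and 0.006 at
1e8. The regression test uses 1e8 (cells this dense are instant to
simulate) so that the 0.02 tolerance tests correctness, not luck.

Confidence bands for effect curves are parametric bootstrap: Poisson
resampling of cell counts around the fitted means, full refit including
the balancing step, pointwise percentiles (default 200 replicates; the
analysis driver uses 100).

## Stabilized kriging maps

Per-area values `v_i` (SIR with null 1, AAPC with null 0) are first shrunk
toward the null with weight `w_i = tau^2 / (tau^2 + sigma_i^2)`, where
`tau^2` is the method-of-moments between-area variance
`max(0, mean((v - null)^2) - mean(sigma^2))`. Shrinkage operates on the
raw SIR scale, not the log, so zero-count areas (SIR 0) need no continuity
correction.

The shrunken values get a Matheron empirical semivariogram (default 12-15
bins to half the maximum pairwise distance) and a parametric fit
(exponential by default, spherical available) by weighted least squares
with Cressie weights `N_k / gamma(h_k)^2`. Ordinary kriging then predicts
on a regular grid clipped to the polygon union, with the residual
post-shrinkage measurement error `e_i^2 = w_i * sigma_i^2` added only to
the data-data covariance diagonal (never to the data-prediction
covariances), so the surface smooths through noisy points instead of
reproducing them; setting `error_mode="raw"` uses `sigma_i^2` unshrunk.
Shrinkage and kriging are two explicit stages rather than one joint
estimator; a joint formulation is possible future work. Kriging is done
from area centroids (not polygon averages). Surfaces are classified
above/near/below the null with a symmetric tolerance band (multiplicative
about SIR 1, additive about AAPC 0) and rendered as red/white/blue filled
maps with contour lines at fixed, configurable levels (SIR
0.8/0.9/1.0/1.1/1.25; AAPC -2...2 percent); areas excluded from the
kriging input are hatched.

## Synthetic registry

The generator draws person-years per area from a log-normal (sigma 0.8
across areas, mean 18,000 per sex-year over ages 30-84 — the scale of a
country of ~300 administrative areas and ~20M inhabitants), with a fixed,
gently declining age mix. Each (sex, histology) stratum has a realistic
log age-rate curve, zero-sum banded period/cohort curvature, an annual
log-linear drift, a spatially correlated log-relative-risk field (GRF by
Cholesky factorization of an exponential-variogram covariance, partial
sill 0.05, range 4 areas, nugget 0.005) and an area-level trend
perturbation (SD 0.006/yr). Counts are Poisson at (sex, histology, area,
year, band) granularity — the pipeline never needs single-year ages. The
default scenario has 306 areas, years 1997-2017, adenocarcinoma rising
(+4.0%/yr men, +5.5%/yr women) and squamous falling (-1.1%/yr men,
-3.4%/yr women), with the squamous strata roughly five to twenty times
sparser.

The exact true SIR per area is computed from the expectation arrays (the
stratum's expected counts against pooled-rate expected counts), so the
mapping stage's mean squared error against truth is well defined. "True"
per-area AAPC is `100*(exp(annual_trend + v_i) - 1)`; it is exact because
the default scenario's banded effects are curvature-only (drift-free), so
they wiggle but do not trend the annual series.

For APC recovery tests, grids are generated directly "under the CRV
condition": arbitrary smooth period/cohort shapes are rebalanced with the
exact reallocation algebra until their rate-ratio CVs agree, before any
counts are drawn.

What the generator does **not** emulate: real geography (areas are unit
squares), migration, population ageing over time, registry artefacts
(death-certificate-only cases, late registration, morphology re-coding),
or covariates such as smoking and air pollution. Passing tests therefore
demonstrate correctness of the estimators under a clean Poisson/GRF world,
not robustness to real-registry data quality.

## Numerical choices and degenerate inputs

- Zero-sum bases are orthonormal null-space bases computed by SVD; the
  GLM design is full rank by construction (the one APC dependency is
  removed with the period linear constraint).
- CRV root search: Brent with xtol 1e-13, gap tolerance 1e-8; a pure age
  model (no drift, no curvature) short-circuits to the reference fit.
- Variogram fit: bounds `c0, c1 >= 0`, `0 < phi <= max distance`; model
  semivariances floored at 1e-12 of the mean for the Cressie weights.
- Kriging: one LU factorization of the augmented system serves all grid
  points; coincident centroids are rejected by name; weight sums are
  checked to 1e-6 at runtime and asserted to 1e-10 in tests.
- `tau^2 = 0` is legal (total shrinkage); `sigma^2 = tau^2 = 0` returns
  the null with a degeneracy flag.
- Histology classification is total: unmatched 4-digit morphology codes
  fall through to "other specified or unspecified carcinoma". The shipped
  code ranges are standard ICD-O-3 groupings and fully overrideable from
  config, since registry conventions differ in the allied-code tails.

## Known limitations

- The CRV identification is a point-estimate balancing rule, not a full
  random-effects likelihood; the delta-profile diagnostic is provided
  precisely because the two need not coincide.
- BIC joinpoint selection is consistent but differs from the permutation
  test used by common registry software; segment CIs ignore breakpoint
  selection uncertainty.
- Kriging assumes second-order stationarity of the shrunken field and
  Euclidean distance in a planar CRS; no reprojection is performed.
- Problem sizes in tests and drivers (306 areas, 11 x 4 grids, 1e8
  person-years per cell for the recovery regression) were chosen as the
  smallest at which each property is cleanly decidable.
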