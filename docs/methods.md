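# Methods

## Model

Central mortality rates m_xt = d_xt / L_xt on an age-group × calendar-year
grid are modelled with the Lee–Carter decomposition

    log m_xt = alpha_x + beta_x * kappa_t,        sum_x beta_x = 1,

where alpha_x is the age profile of log mortality, beta_x the age-specific
sensitivity to the common trend kappa_t. Instead of the classic two-stage
SVD-plus-ARIMA treatment, kappa_t is the time-varying parameter of a
score-driven — GAS(1,1) — recursion

    kappa_{t+1} = omega + A * s_t + B * kappa_t,
    s_t = I_t^{-1/2} * sum_x grad_xt,     I_t = sum_x I_xt,

with grad_xt the derivative of the cell's conditional log mass in kappa_t
and I_xt its Fisher information. The filter is strictly causal: kappa_{t+1}
uses data only up to year t, and the final observed year updates nothing
in-sample (it delivers the first out-of-sample trend value instead).

Four count families are supported for the deaths d_xt:

| family             | cell parameters                               | partial score                           | partial information |
|--------------------|-----------------------------------------------|-----------------------------------------|---------------------|
| COM-Poisson        | lambda = L e^(alpha+beta*kappa), dispersion nu | beta (d − lambda + (nu−1)/(2 nu))       | beta² lambda        |
| Poisson            | lambda = L e^(alpha+beta*kappa)               | beta (d − lambda)                       | beta² lambda        |
| binomial           | q = logistic(alpha+beta*kappa), denominator l | beta (d − l q)                          | beta² l q (1−q)     |
| negative binomial  | h = r / (r + L e^(alpha+beta*kappa)), r per age | beta (d h − (1−h) r)                   | beta² (1−h) r       |

The COM-Poisson score carries an optional dispersion offset (nu−1)/(2 nu);
a `score_form="plain"` switch drops it (the two coincide at nu = 1,
where the family is exactly Poisson). The binomial link is the plain
logistic in the linear predictor — the unique choice under which the
tabulated score and information are the exact derivative and Fisher
information of the binomial log mass, and under which fitted death
probabilities can be small.

### COM-Poisson numerics

The pmf is P(Y=y) = lambda^y / ((y!)^nu Z(lambda, nu)) with
Z = sum_s lambda^s/(s!)^nu. nu = 1 is Poisson (Z = e^lambda), nu = 0 with
lambda < 1 is geometric (Z = 1/(1−lambda); divergent otherwise, and
construction fails), and nu → infinity approaches a Bernoulli with success
probability lambda/(1+lambda). nu < 1 is overdispersion, nu > 1
underdispersion.

log Z is evaluated by truncated summation in log space. The sum is centred
on the largest term (index near lambda^(1/nu)); the window half-width comes
from the local curvature of the log terms (−nu/s), sized so the discarded
tails are below the requested relative tolerance (default 1e-10), and the
endpoint terms are verified and the window doubled if the check fails.
Summation is capped at 1e6 terms per cell; beyond that a
`SummationLimitError` is raised (the optimiser treats that region as a
penalty). Log-factorials come from a cached cumulative table. A closed-form
moment recursion exists in the literature for this family but is numerically
treacherous near nu = 1; all moments here are computed by direct truncated
summation (`exact_moment`), which also serves as the test oracle. The
asymptotic approximations E(Y) ≈ lambda^(1/nu) − (nu−1)/(2 nu) and
Var(Y) ≈ lambda^(1/nu)/nu (stated region: nu ≤ 1 or lambda > 10^nu) are
exposed with an explicit in-region flag and used for conditional-mean rate
output; inference always goes through the pmf. Sampling is by inversion of
the truncated cmf, which makes draws reproducible from a seed.

Note a structural quirk of this family in the mortality context: the
implied death mean is lambda^(1/nu), so for nu away from 1 the sensitivity
of log mean rates to the trend is beta/nu, not beta, and the mapping is not
scale-consistent in the exposure. Fitted dispersion well below 1 therefore
amplifies forecast sensitivity; this is a property of the model, not of the
implementation.

## Estimation

All static parameters theta = (alpha, beta, omega, A, B, kappa_init,
dispersion) are estimated jointly by maximising the filtered log-likelihood
sum_xt log p(d_xt | kappa_t) in a single step.

* Identification: sum(beta) = 1 is imposed by eliminating beta_N; one
  location constraint is needed because shifting kappa by c while moving
  alpha_x by −beta_x c and omega by c(1−B) is likelihood-invariant. The
  first intercept is pinned to its starting value and kappa_init estimated
  freely. Effective parameter counts: 2N+2 (Poisson, binomial), 2N+3
  (COM-Poisson), 3N+2 (negative binomial), minus one when B is fixed at 1.
* Initialisation: alpha from mean log rates (+0.5 continuity correction
  inside the log for zero-death cells only), (beta, kappa) from the leading
  singular pair of the centred log-rate matrix, (omega, B) from an AR(1)
  regression on the SVD trend (|B| clipped below 1), dispersion from nu = 1
  or a per-age method-of-moments r. The score weight A is grid-picked from
  a small candidate set at the start: the filter's error-feedback gain
  B − A·sqrt(I_t) must lie inside the unit circle, and the likelihood is
  extremely sensitive to A near that boundary.
* Optimiser: quasi-Newton (BFGS) on transformed coordinates (log A, log nu,
  log r, tanh-bounded B when free), with an exact analytic gradient obtained
  by forward-mode differentiation of the recursion — the tangent of kappa_t
  in every static parameter is propagated alongside the filter, with the
  normalizing-constant derivatives supplied by E[Y] and E[log Y!] from the
  same truncated series. Coordinates are rescaled by inverse square-root
  diagonal curvature before each (re)start: the likelihood is orders of
  magnitude stiffer in the loadings than in the recursion coefficients,
  and an unscaled quasi-Newton run stalls in the curved valley. COM-Poisson
  fits are warm-started from the Poisson maximum (its exact nu = 1
  submodel), and their internal coordinates carry the intercepts and trend
  coefficients divided by nu with the log exposure folded in, so the nu
  direction holds the implied death means fixed — without this the
  optimiser crawls along a curved (nu, alpha) valley.
* Contracts: the returned log-likelihood is never below the starting value
  (the start is returned, flagged, if an optimiser run ends worse);
  non-convergence is reported explicitly in the results object; the reported
  gradient norm is measured in the optimiser's rescaled metric.

## Forecasting

Multi-step projection simulates the same recursion forward. The first
out-of-sample trend value is deterministic (observation-driven models make
one-step-ahead prediction exact); each subsequent step draws synthetic
deaths per cell from the family's conditional distribution at the current
trend, recomputes the scaled score from those draws, and advances the
recursion. Point forecasts are across-path means of the conditional
expected rate (exp(alpha+beta*kappa) for Poisson and negative binomial,
l·q/L for binomial, the asymptotic mean over exposure for COM-Poisson);
uncertainty bands are empirical across-path quantiles. A `mean_path` mode
freezes future scores at zero for diagnostics. Exposures (and binomial
denominators) are held at their last observed values unless projected
values are supplied.

## Classic Lee-Carter baseline

Three stages: (1) SVD of the centred log-rate matrix under sum(beta) = 1,
sum(kappa) = 0; (2) per-year re-fit of kappa so fitted total deaths match
observed totals (Brent root-find; the death-weighted variant of the
adjustment, chosen for determinism); (3) ARIMA(0,1,1)-with-drift projection
of the adjusted trend via statsmodels, falling back to a random walk with
drift when the MA coefficient is non-invertible or the fit fails
(zero-variance differences short-circuit directly to the fallback).

## Evaluation

AIC = −2 LL + 2 n_p and BIC = −2 LL + n_p ln(n_d), with n_p the effective
parameter count above and n_d = N·T. Forecast accuracy is MAPE on central
rates, stored in percent; quartile summaries (min/Q1/mean/Q3/max across
populations) use the inclusive linear-interpolation quantile convention.
The Diebold–Mariano statistic divides the mean loss differential by its
long-run-variance standard error with rectangular weights to lag h−1 and a
two-sided normal p-value; identical losses return (0, 1) with a warning and
a constant differential returns a signed infinity. Winner maps code the
argmin family per (population, age) cell — 1 COM-Poisson, 2 Poisson,
3 binomial, 4 negative binomial, 5 Lee-Carter — with ties broken toward
the lower code and reported separately.

## Synthetic data

The generator draws surfaces from the model itself: the trend follows the
same score recursion with scores computed from the freshly drawn deaths, so
the fitted family is correctly specified by construction, and a
misspecification mode (e.g. generate negative binomial, fit Poisson) drives
the model-selection experiments. Defaults emulate grouped national
mortality surfaces: 20 age groups 0, 1–4, …, 85–89, 90+; age intercepts on
the canonical profile (elevated infant mortality, childhood minimum near
log-rate −9, Gompertz-like rise to about −1 at 90+, all rates in
(1e-4, 0.5)); positive loadings summing to one; a downward random-walk
trend (B = 1, drift −0.5 over the sample); integer exposures between 1e3
and 1e6 person-years. The score weight defaults to A = 0.08 so that the
feedback gain B − A·sqrt(I_t) stays inside the unit circle at default
exposures — an explosive filter is not a meaningful data-generating
process. Binomial denominators are set to l = L/(1 − q/2), the
self-consistent version of the l = L + d/2 convention at the expected death
count.

What the generator does not emulate: cohort effects, age-correlated
residual shocks, migration-driven exposure dynamics, wars/pandemics, or
cross-population dependence. Passing tests therefore demonstrate correct
recovery and ranking behaviour under the model's own assumptions, not
robustness to the ways real mortality data violate them.

## Experiment sizes and numerical choices

Recovery experiments use panels of 10 age groups × 30 years at exposure
1e5 with 20 replicates; the model battery uses 4 populations with
negative-binomial deaths at r = 2000 (cell variance-to-mean between about
1 and 20, the mild overdispersion typical of national death counts) split
1990–2009 / 2010–2019; the model-selection experiment uses r = 5 at
exposure 5e3 (strong overdispersion; exposures small enough to keep counts
moderate, large enough that no age row is all-zero). Trend-reconstruction
error is computed after mean-aligning fitted and true paths, because the
trend is identified only up to location. Information sums are floored at
1e-12 before the inverse square root; linear predictors are clamped at ±50
before exponentiation; both events log a warning once. Zero-death cells
are handled exactly by the likelihood; the +0.5 correction exists only
inside initialisation's logarithm.

## Known limitations

* The COM-Poisson mean-to-rate mapping is not exposure-scale-consistent
  (see above); fitted nu far from 1 makes long-horizon rate forecasts very
  sensitive to the trend.
* No standard errors for the static parameters are provided.
* The binomial family needs start-of-year populations; when absent they are
  approximated as L + d/2 with a logged notice.
* Fitting near nu → 0 is blocked only by the summation cap (treated as a
  penalty region), not by an explicit prior; heavily overdispersed data can
  drive nu to very small values.
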