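# Methods

## Variable derivation

All analysis variables are deterministic functions of the raw person-wave
record. Smoking status is five-valued: never (fewer than 100 lifetime
cigarettes), current light / current heavy split at a smoking index
(cigarettes per day × years smoked) of 200, and former smokers split at
5 years since quitting. Two boundary readings are undefined in the source
definitions and are fixed here once: an index of exactly 200 is classified
heavy (closing the partition with the more conservative class), and
"drinks more than once a month" is a strict inequality, so exactly-monthly
drinkers are non-drinkers. Poverty is at least two of four deprivation
indicators (traditional cooking fuel, non-flushable toilet, no running
water, fewer than two household assets). BMI classes use the Chinese normal
range 18.5–23.9 kg/m², inclusive at both ends. Records younger than 45 are
excluded with a logged count. Nominal expenditures are deflated with the
medical-care CPI to 2015 levels and divided by a configured
currency-per-dollar rate; all internal computation is in constant 2015
dollars.

The design matrix is a fixed contract (`measurement.DESIGN_COLUMNS`):
constant, four smoking dummies, then male, two age-group dummies (55–64,
65+), urban, education, partnered, poverty, insured, two region dummies,
two BMI dummies, drinker, and the eight interaction columns IT1–IT8 — the
products of the four non-reference smoking levels (in the order light,
heavy, quit < 5 yr, quit ≥ 5 yr) with the two non-reference age groups.
Every fit, prediction and counterfactual indexes columns by this order, so
column mismatches fail loudly rather than silently misalign.

## Estimators

**Use equation.** The random-intercept logit likelihood integrates
`α_i ~ N(0, σ_α²)` out of each individual's contribution. The integral is
approximated by adaptive Gauss–Hermite quadrature: for each individual the
posterior mode and curvature of the integrand are found by Newton steps
(the log integrand is strictly concave in α), and the nodes are centred and
scaled there. Defaults: 15 nodes, relative log-likelihood tolerance 1e-6,
L-BFGS-B ascent with an analytic score (the node re-adaptation term is
neglected in the score; it is second order because the modes are stationary
points of the integrand). σ is optimized on the log scale with a floor of
1e-4, so the pooled-logit limit is reachable. Standard errors come from a
finite-difference observed-information matrix at the optimum, inverted by
pseudo-inverse so an unidentified direction (an empty design cell) does not
poison the rest. On a seeded fixture the estimator agrees with
`lme4::glmer(nAGQ = 15)` to about 1e-4 in every coefficient, σ̂ and the log
likelihood, and on small panels the quadrature log likelihood matches dense
trapezoid integration to better than 1e-6.

**Cost equation.** Among person-waves with positive spending, `ln Exp` is
fitted by the classic random-effects estimator: σ_u² from the within
(fixed-effects) regression residuals, σ_α² from the between (group-means)
regression with the Swamy–Arora correction (harmonic-mean group size for
unbalanced panels), negative estimates clamped to zero with a log message;
then feasible GLS via quasi-demeaning. Standard errors are cluster-robust
by individual. Empty or collinear design cells are handled by
pseudo-inverse, pinning the unidentified coefficient at zero — the analogue
of Stata's dropped-term behaviour. Duan's smearing factor, the mean of
exponentiated level residuals `ln y − x'β̂`, is stored on the fit for
retransformation.

Sampling weights enter the descriptive tables only; model fits are
unweighted, matching the quoted estimation commands of the study design.
Wave dummies are excluded by default (the two equations list only smoking,
covariates and interactions).

## Counterfactual and attributable fraction

Expected cost per person-wave is `Pr(use) × exp(x'β̂) × R`. `Pr(use)` is by
default the population-average probability — the logit probability averaged
over `N(0, σ̂_α²)` with 31-node quadrature — with an intercept-at-zero
option for comparability with naive single-level prediction. `R` is Duan's
smearing factor by default, or `exp((σ̂_α'² + σ̂_u'²)/2)` under the lognormal
normal-theory option; the SAF ratio cancels any constant factor, which the
tests assert, so this choice barely moves the headline fraction. The
hypothetical scenario zeroes all four smoking dummies and all eight
interaction columns — former smokers are reset to never along with current
smokers — and replays the identical coefficient vectors. SAF is computed
from totals within stratum × service; subgroup SAFs (sex, residency) reuse
the pooled fit rather than refitting per stratum, which keeps subgroup
contrasts attributable to composition rather than to coefficient
instability in small strata; per-stratum refits remain possible by
filtering the panel before fitting. No uncertainty intervals are attached
to SAF (a bootstrap can wrap `run_pipeline`, but that surface is untested).

## National aggregation

Total health expenditure per service is built from survey means — spend per
outpatient visit (PV) and per-person monthly visit rate (QV), the same for
inpatient episodes over a 12-month recall (PH, QH), and the mean positive
self-medication spend (PM) with its positive-spend share (QM) — annualized
by the recall window (×12 for the 1-month windows) and scaled by the 45+
population. Because self-reported spending levels drift from administrative
totals, PV/PH/PM are first multiplied by a calibration factor =
(official all-ages expenditure × 45+ share) / (survey-implied national
total). The textual definition of this factor in the source material reads
inverted relative to the reported value (1.23, i.e. scaling survey
undercounts up); this package implements official/survey and offers an
`invert` flag. The 45+ share (default 0.5999) is configuration, not code.
SAME per service is THE × SAF; the overall figure is the exact sum of the
three services, and per-smoker figures divide by configured smoker counts
(service-specific denominators when available, since the published
per-smoker figures imply denominators that are not printed).

Survey use flags stand in for visit counts (the record schema carries
any-use indicators per recall window), so QV and QH are per-person use
rates; when every user has exactly one visit the two definitions coincide.

## Synthetic panel generator

The generator emulates the study conditions: a balanced 3-wave panel
(default 2000 individuals; national surveys of this design follow an order
of magnitude more) of adults 45+
with time-invariant covariates at the published baseline weighted
prevalences (never smokers 64.4%, males 44.56%, rural 57.52%, …; the
published shares sum to 99.71% and are renormalized at draw time), ages
advancing with the calendar, and smoking status following an absorbing-ish
Markov chain — never smokers stay never, current smokers quit with
per-wave probability 0.06, recent quitters cross the 5-year mark with
probability 0.5 per 2-year wave — echoing the published drift toward more
quitters; the transition rates are generator defaults, not published
values. Outcomes follow the estimators' own data-generating process: per
service, a Bernoulli use flag at `logit^-1(x'γ + α_i)` and, given use, cost
`exp(x'β + α'_i + u)`. The generating γ are the logs of the published
adjusted odds ratios and the generating β the published semi-elasticities
for all six equations (e.g. aOR 1.421 / β 0.886 for recent quitters in the
outpatient pair), so recovery tests are anchored at realistic magnitudes.
The intercept and residual scales are not published; the defaults
(σ_α = 0.8 for use, σ_α' = 0.7 and σ_u = 1.2 for log cost) are typical
magnitudes for log health-expenditure panel data. Use- and cost-equation
intercepts are independent by default with a correlation knob for
sensitivity checks. Raw record fields are back-filled so the measurement
module's classifications reproduce the intended categories exactly.

The `TruthBundle` stores the realized intercepts and the ground-truth SAF:
each person-wave's expected cost conditional on the drawn covariates and
intercepts, with the lognormal residual integrated analytically, under the
factual and the zeroed-smoking design. Identical (config, seed) reproduces
the panel byte-for-byte.

What the generator does **not** emulate: multi-stage cluster sampling and
attrition, under-reporting of expenditures (so the calibration factor on
synthetic data is exercise machinery, not a realistic 1.23), visit counts
beyond any-use flags, and item missingness. Passing recovery tests
therefore demonstrate estimator correctness under the model's assumptions,
not robustness to those real-data features.

## Problem sizes and numerical choices

Recovery tests use 200 replications of the default n = 2000 panel with
7-node quadrature for the published-magnitude smoking coefficients
(asserted within 2 Monte-Carlo SEs of truth) and 20 full end-to-end
replications for per-service SAF (within 3 MC SEs). The variance-component
consistency check runs at n = 1200 individuals because three binary
observations per person carry little information about σ_α: the MLE's
O(1/n) small-sample bias — shared with lme4, which this implementation
matches replication-by-replication — only falls below Monte-Carlo
resolution once the panel is that wide. Ties and degenerate inputs:
constant outcomes, non-positive expenditures, zero factual totals and
mismatched designs raise typed exceptions rather than returning NaN.
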