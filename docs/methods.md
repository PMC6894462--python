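# Methods

## Model and estimator

The package estimates adjusted risk ratios for a binary outcome under the
log-linear risk model `P(Y=1|E,X) = exp(βᵀZ)` with `Z = (1, E, Xᵀ)ᵀ`, plus
optional exposure-by-covariate interaction columns `E·Xⱼ`. The regressor
order is fixed: intercept, exposure, covariates in declared order,
interactions in declared order. Without interactions `exp(β_E)` is the
risk ratio comparing exposed with unexposed at any covariate value; with
interactions the exposure effect is `exp(β_E + β_EXᵀ x)` and must be
reported at stated covariate values (done by a linear-combination /
delta-method standard error on the log scale).

Estimation solves the Poisson score equations — unbiased estimating
equations for this model whatever the true outcome distribution — and
variance estimation uses the sandwich `H⁻¹BH⁻¹` rather than the Poisson
information, because the outcome is Bernoulli. The estimator is an
M-estimator: consistent and asymptotically normal when the risk model is
correctly specified, with the sandwich consistent for its variance. The
test suite cross-checks both the root and the sandwich against an
independent GLM implementation (Poisson family, log link, HC0 robust
covariance) to 1e-6 relative on randomized small datasets.

Assumptions worth stating: individuals are independent (no clustering
between outcomes within a site beyond what covariates capture — correlated
outcomes would need a GEE-style extension, out of scope here); the log link
does **not** bound fitted risks at 1. Fitted values above 1 are a known,
documented property of the model, reported as a logged warning, never an
error; only genuine `exp` overflow (|linear predictor| > 700) raises.

## Newton solver and convergence rule

Newton–Raphson iterates `β⁽ʳ⁾ = β⁽ʳ⁻¹⁾ − H⁻¹S` with the update obtained by
a symmetric linear solve (`H` is never inverted; the final covariance is
assembled by solving against `B`'s columns). The default start is `β⁽⁰⁾ = 0`
and is user-overridable. Convergence is declared when
`max_l |δ_l| < tol` with `tol = 1e-8`, where `δ_l` is the absolute
coefficient change when `|β_l| < 0.01` (strict inequality, so a coefficient
sitting exactly at 0.01 is judged relatively) and the relative change
`(β_l⁽ᴿ⁺¹⁾ − β_l⁽ᴿ⁾)/β_l⁽ᴿ⁾` otherwise. The switch avoids dividing by
near-zero coefficients; the denominator keeps its sign. One "iteration"
means one Newton update, and the update that satisfies the criterion is
counted. `max_iterations` defaults to 50 — an order of magnitude more than
the 7 updates the default simulated design needs, since Newton on this
strictly concave objective is quadratically convergent near the root.

Degenerate inputs are rejected before fitting: non-binary `Y` or `E`, a
missing intercept column, fewer rows than regressors, or any constant
non-intercept column (which makes `H` structurally singular). During
fitting, a reciprocal condition number of `H` below 1e-12 raises a
singular-system error that names the columns loading on the smallest
singular direction — usually the collinear culprits. These pooled-fit
validations deliberately do **not** apply to a single partner's local data:
a site may well have zero local variance in a shared covariate (the site
indicators of the built-in network are the standing example), and its
summary messages are still valid; rank questions belong to the aggregated
Hessian at the center.

## Distributed protocol

Partners compute `S_k, H_k` per iteration and `H_k(β̂), B_k(β̂)` once;
the center sums them **in fixed site-registration order** (floating-point
addition is not associative; a fixed order makes runs bit-reproducible),
takes the Newton step, checks convergence, and broadcasts. Exact additivity
of the sums makes the distributed estimates and standard errors equal to
the pooled ones; tests assert equality at 1e-10 relative and additivity at
1e-12. A round must contain exactly one message per registered site for
exactly the current iteration — anything else (missing, duplicate, stale,
wrong dimension) aborts the round as a protocol error, since the aggregate
needs all K terms.

Messages are JSON files with a fixed schema (protocol version, kind,
site id, iteration, payload); floats serialize via shortest round-trip
representation, so file transport is bit-exact, and payloads are validated
on read (shape, symmetry, finiteness). The transcript records every
exchange with payload dimensions and a SHA-256 digest; `verify()` replays
recorded broadcasts through the partners and re-derives each digest. The
privacy claim is structural, not cryptographic: payload sizes depend only
on `p` and the iteration count, never on any site's `n_k`. No minimum-cell
or disclosure-limitation rules are enforced on the summary matrices; the
transcript exists precisely so such payloads can be audited. Transport
security (encryption, authentication) is out of scope — the file exchange
emulates the manual transfer step of a real network.

## Synthetic network

The generator emulates a non-randomized 3-partner study, n = 10000 split
5000/2000/3000. Covariates: `X1 ~ Bernoulli(0.6)`, `X2 ~ Uniform(0,1)`,
`X3 ~ Exponential(1)`, `X4`/`X5` indicators of partners 1 and 2. Exposure:
`P(E=1|X) = 1/(1 + exp(0.73 − X1 − X2 + X3 − 0.2X4 + 0.2X5))`, giving
≈40% exposed overall and ≈43/34–35/38–39% by site. Outcome:
`P(Y=1|E,X) = exp(−0.1 − 0.5E − 0.4X1 − 0.6X2 − 0.5X3 − 0.1X4 + 0.1X5)`,
true adjusted RR `exp(−0.5) ≈ 0.61`, incidence ≈30% overall and
≈27/34–35/31% by site — a *common*-outcome regime, where the odds ratio
overstates the risk ratio. Generation order is fixed (X, then E, then Y) so
a seed pins the network; site assignment is by block, and the indicator
covariates derive from it. Under the default coefficients the outcome
linear predictor is ≤ 0 for every row; the generator nonetheless checks at
run time and rejects configurations producing probabilities above 1, naming
the maximal linear predictor.

What the generator does *not* emulate: within-site outcome correlation,
covariate distributions beyond the fixed design above, measurement error,
missing data. Passing tests therefore demonstrate the algebraic
pooled≡distributed identity (which holds for any data) and estimator
calibration under a correctly specified model — not robustness to the
messiness of real claims data.

The replication harness draws each replicate from a seed derived from
`(base_seed, replicate index)`, so results cannot depend on execution
order, and reports per-coefficient mean bias, empirical SE, mean sandwich
SE and 95% Wald coverage. At the default design over 200 replicates the
exposure coefficient is unbiased within Monte-Carlo error, the mean
sandwich SE is within 10% of the empirical SE, and coverage sits in the
binomial band around 95% — the standard evidence for "consistent and
asymptotically normal with valid intervals" at this sample size. These
sizes (200 replicates of n = 10000) run in seconds and give Monte-Carlo
standard errors around 0.0025 on the exposure coefficient, tight enough for
the calibration bands used in the tests.

## Comparators

Logistic regression (Newton on the Bernoulli-logit likelihood) reports
`exp(β_E)` as an odds ratio: close to the RR when incidence is rare (~1%),
and progressively further from the null as incidence grows — the package's
tests check the divergence is monotone across incidences of 1%, 10% and
30%. Log-binomial regression (Fisher scoring on the binomial log-link
likelihood) shares the Newton framework so its failures are attributable to
the model: its score divides by `1 − exp(Zᵢᵀβ)`, hence the all-zero start
fails at iteration 1 with an exact zero denominator; any iterate with a
non-negative linear predictor is a boundary failure (fitted risk ≥ 1);
singular information and plain non-convergence are also surfaced as
structured categories rather than exceptions. A per-start outcome table
(`starting_value_report`) makes the starting-value sensitivity a
first-class result. Where log-binomial does converge, it agrees with an
independent GLM binomial/log fit and with the modified Poisson estimates
up to sampling error — both are consistent for the same log risk model.

## Numerical and reporting choices

- Confidence intervals are Wald intervals on the log scale, exponentiated.
  The default critical value is the exact normal quantile
  (`norm.ppf(1 − α/2)` = 1.959964 at 95%); `z_value` lets callers use the
  conventional rounded 1.96 when reconstructing hand-computed intervals.
- Report tables print 8 decimal places.
- CSV dialect: comma-separated, UTF-8, header required; `Y`/`E` strictly
  0/1; extra columns ignored with a logged notice; reading uses
  round-trip float parsing so write/read preserves values bit-exactly.
- Aggregation and summation orders are fixed everywhere results could
  depend on them.

## Known limitations

- Clustered or correlated outcomes are not supported (no GEE extension).
- No weights, offsets, or missing-data handling.
- Fitted risks above 1 are possible under the log link and only warned
  about.
- The privacy guarantee is "summary-level only", with an auditable
  transcript; it is not differential privacy, and a determined center
  could still learn about small sites from repeated low-rank summaries.
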