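# Methods

## Estimands

All effects are differences in success probability, marginal over the
empirical covariate distribution of the analysed table and over the
population of surgeons. Writing `P(t, t')` for the mean of the potential
outcome `Y(t, M(t'))` over patients and simulation replicates:

| quantity | definition |
|---|---|
| natural indirect effect | `δ(t) = P(t,1) − P(t,0)` |
| natural direct effect | `ζ(t) = P(1,t) − P(0,t)` |
| total effect | `τ = P(1,1) − P(0,0)` |
| averages | `δ(a*) = (δ(0)+δ(1))/2`, `ζ(a*) = (ζ(0)+ζ(1))/2` |
| controlled direct effect | `ζc(m) = E[Y(1,m) − Y(0,m)]` |

On the difference scale the composition `τ = δ(1) + ζ(0) = δ(0) + ζ(1)`
holds exactly; the engine computes all effects from one `P(t,t')` table, so
the identity holds to floating-point accumulation error (≤1e-12) in every
run, not merely in expectation. This would not hold for odds-ratio or
risk-ratio versions of these estimands, which the package deliberately does
not provide.

Identification requires the stable-unit-treatment-value assumption and
sequential ignorability: (1) treatment independent of potential outcomes and
mediators given baseline covariates — guaranteed by randomisation; (2)
mediator independent of potential outcomes given treatment and covariates —
not guaranteed, not testable, and the reason the sensitivity module exists.
Reports render these as documented caveats; nothing computes them.

## Component models

Mediator: `logit P(M=1|T,X,v_s) = α0 + α1 T + α2'X + v_s`, `v_s ~ N(0, σv²)`.
Outcome: `logit P(Y=1|T,M,X,u_s) = θ0 + θ1 T + θ2 M + θ3 TM + θ4'X + u_s`.
The treatment-by-mediator interaction is included by default and can be
disabled. Clusters are surgeons; labels are opaque strings. Tables are
complete-case by contract — rows with missing values are rejected at read.

### Fitting

Maximum likelihood with the random intercept integrated by adaptive
Gauss–Hermite quadrature (default 7 nodes; 1 node = Laplace). Nodes are
recentred at each cluster's conditional mode and rescaled by the conditional
curvature at every evaluation. The reported estimate is the root of this
continuously re-adapted score, found by damped Newton with a
finite-difference Jacobian; covariates are centred and scaled internally for
conditioning. This estimator matches `lme4::glmer` at nAGQ=15 to five
decimals on trial-scale data (one test runs that cross-check through
`Rscript`); at 7 nodes the two differ by a few 1e-3 — far below any standard
error — which is genuine quadrature truncation, not optimiser noise.

Numerical guards: σ is optimised on the log scale with a floor at 1e-6 and
reported as 0 (ICC 0) below 1e-4. Because the log-scale score vanishes as
σ→0, a solution at the floor is probed against restarts at σ ∈ {0.5, 1, 2}
and re-solved if any has higher likelihood — without this, trajectories that
dip early can report σ̂=0 on data whose MLE is strongly positive. Rank
deficiency raises an error naming the aliased columns; apparent complete
separation (a coefficient beyond ±25) raises an error stating that penalised
regression is out of scope; a fit that merely fails to converge returns with
`converged=False` rather than raising. Wald intervals (no small-sample
corrections) back the odds-ratio tables; the ICC uses the latent-scale
level-1 variance π²/3.

## Monte Carlo engine

For each of `n_sims` replicates (default 2000): draw one mediator-model and
one outcome-model random intercept (rule `draw`: fresh `N(0, σ̂²)` per
replicate — the population-of-surgeons marginal; `zero` and cluster
posterior `mode` rules are selectable); simulate `M(0)` and `M(1)` for every
patient from the mediator model with a shared uniform draw; simulate the
four `Y(t, M(t'))` from the outcome model with another shared uniform draw.
Common random numbers across the four cells make structural zeroes exact:
if `θ2 = θ3 = 0`, the indirect effect is exactly 0, not merely centred on 0.
Coefficients stay fixed at their estimates — uncertainty enters only through
the bootstrap, not through parameter draws. Per-replicate cell means are
retained so the Monte Carlo standard error of any effect is available as
`SD(replicate effects)/√n_sims`.

Moderation: both models add moderator-by-treatment (and the outcome model
moderator-by-mediator) interactions; the engine then recomputes the effects
with every patient's moderator forced to each grid value, all other
covariates at observed values, yielding a pointwise effect profile.

## Bootstrap

Default: patients resampled with replacement within each arm (cluster
bootstrap — whole surgeons with replacement, duplicated surgeons treated as
distinct — is the alternative for stronger dependence). Each replicate refits
both models (warm-started from the full-data fit) and reruns the engine with
a replicate-specific sub-seed. Intervals are percentile intervals; the
percentile interval need not contain the point estimate in finite samples
and no such constraint is asserted. Non-converged refits are dropped and
counted; more than 20% failures is an error. Default 999 replicates (tests
and the acceptance script use 199 to keep runtimes sensible).

Calibration, checked by the test suite: under a global-null generator the
95% interval for τ excludes zero in 2–9% of 200 runs; over 200 simulated
trials (n=1000, 20 clusters) GLMM coefficient bias is within 2 Monte Carlo
SEs of zero and Wald coverage within [90%, 98%].

## Sensitivity to unmeasured mediator–outcome confounding

The postulated confounder `U` has unit variance, log odds ratio `β` on the
outcome given `(T, M)`, and mediator association
`E(U|M=1,T=t) − E(U|M=0,T=t) = λ0 + λ1 t`; `(0,0,0)` is no confounding.

The fitted outcome model estimates `E[Y|T,M,X]`, which under the postulated
`U` is the causal `E[Y(t,m)|X]` tilted by the conditional mean of `U` given
`(M,T)`. The adjusted engine therefore evaluates every potential-outcome
cell `(t, m)` as

```
expit( θ̂'z(t,m,X) + RE − β (λ0 + λ1 t)(m − p̄_t) / s )
```

with `p̄_t` the observed mediator prevalence in arm `t` (centring `U` to
mean zero within each randomised arm, as randomisation implies) and
`s = sqrt(1 + c²β²)`, `c = 16√3/(15π)`, the usual logistic–normal
marginalisation constant mapping the conditional-scale tilt onto the
marginal scale of the fitted coefficients. Equivalently: the mediator
coefficient absorbs a `βλ0`-type shift and the interaction a `βλ1` shift,
plus the arm-level centring terms.

Properties, all enforced by tests: exactly no-op at `β = 0` and at
`λ0 = λ1 = 0`; first-order correct — against an exact enumeration oracle
with `U ∈ {−1,+1}` the adjustment removes the bulk of the confounding bias
(error reduced severalfold even at `β = λ0 = 1`), with a higher-order
residual; and it preserves the randomisation-identified total effect to
first order, so confounding reallocates effect between the direct and
indirect components rather than manufacturing total effect. The adjustment
is a first-order correction, documented as an approximation — it is not an
exact deconfounding for large `βλ`.

The surface scans `β, λ0 ∈ {−1, −0.75, …, 1}` at fixed `λ1` (default 0).
Its significance mask translates the unadjusted bootstrap interval for
`ζ(a*)` by the (deterministic) adjustment rather than re-bootstrapping every
grid cell; this assumes the adjustment shifts the sampling distribution
without reshaping it, which is exact to first order and keeps the surface
computable in seconds. With a positive direct effect and higher uptake in
the treated arm, erosion of the direct effect requires `β` and `λ0` of
opposite signs; the frontier report lists cells that change sign or lose
significance.

## Synthetic-data generator

Patients are dealt round-robin to surgeons; treatment is randomised at the
patient level (as in the motivating trial — patients, not surgeons, were
randomised); random intercepts are drawn per cluster; `M` then `Y` follow
the two logistic models above. Defaults (the package's reference
conditions): n=352, allocation 1/2, 20 surgeons, `α1 = log 4.78`,
`σv = 2.05` (mediator ICC ≈ 0.56), `θ1 = log 1.59`, `θ2 = log 0.75`,
`θ3 = log 2.57`, `σu = 0.61` (outcome ICC ≈ 0.10), age ~ Normal(71.9, 7.5)
with log-odds slopes −0.062 (mediator) and −0.041 (outcome), baseline sinus
rhythm ~ Bernoulli(0.2) with slopes −0.67 and 2.15; intercepts chosen so
marginal uptake is ≈55%/30% and control-arm success ≈45%. The surgeon count
is a stand-in — the motivating trial does not report one.

An optional confounder `U ~ N(0,1)` enters the outcome linear predictor as
`β_true·U` and the mediator model with an arm-specific coefficient found by
one-dimensional root-finding (nested Gauss–Hermite over `U` and the cluster
intercept) so the realised `E(U|M,T)` contrast matches `λ0 + λ1 t` at the
covariate means — the sensitivity parameters are defined by that contrast,
not by a structural coefficient.

`true_effects` computes ground truth by direct Monte Carlo from the
generating model (fresh covariates and per-patient intercepts, common random
numbers across cells), enabling recovery tests: engine estimates from fitted
models agree with generator truth over replicated trials within combined
Monte Carlo and sampling error.

What the generator does not emulate: informative cluster sizes, non-normal
random effects, missing data (the data model is complete-case by contract),
multi-arm designs, and time-varying treatments or mediators. Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated model, not robustness to these violations.

## Problem sizes used in the test suite

Calibration studies are sized to run comfortably on one CPU: the bootstrap
type-I study uses 200 trials × 199 replicates at n=120 with 150 engine
draws; parameter recovery uses 200 trials at n=1000 with 20 clusters;
engine-vs-oracle comparisons use the production default of 2000 draws. The
acceptance script uses the full default trial (n=352) with 199 bootstrap
replicates and 1000 engine draws.

## Known limitations

- Single mediator, single random intercept; no random slopes or crossed
  effects, no penalised/Firth or Bayesian fitting.
- Percentile intervals only (no BCa); pointwise moderation profiles (no
  simultaneous bands).
- The sensitivity correction is first-order in `βλ`; exact formulas for the
  binary–binary case are not implemented.
- Probability-difference estimands only, by design.
- Laplace (1-node) fits can be unstable at mediator-level ICCs; the default
  7-node quadrature should be used for real analyses.
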