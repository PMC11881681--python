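# Methods

## The coarsened-data problem

A categorical covariate X with sample space Ω = (a, b, c, …) is *coarsened*
when an observation is a non-empty subset X′ ⊆ Ω known to contain the true
value.  Singletons are fully observed values, X′ = Ω is a completely
missing value, and proper subsets (e.g. `{b,c}`) carry partial information.
The package works under *coarsening at random* (CAR): the probability of
each coarsening pattern depends only on observed data — every value inside
an observed subset is equally likely to have produced it, conditional on
the other observed variables.  CAR is the subset-valued analogue of MAR
and, like MAR, is untestable from the data alone.

The scientific question is a regression: a substantive model
f(Y | X, Z; ψ) — linear for a continuous outcome, Cox proportional hazards
for a right-censored one — whose coefficient vector is the estimand.  The
first sample-space label is the reference level throughout and fixes the
coefficient order.

## Coarsening-compatible SMC-FCS

Substantive-model-compatible FCS imputes X from the density proportional to
f(Y | X, Z; ψ) · f(X | Z; φ), which by construction is compatible with the
analysis model.  For categorical X the density is an explicit multinomial:
for each candidate label k,

    w_k ∝ P(X = k | Z; φ) · f(Y | X = k, Z; ψ),

normalized over Ω.  The coarsening-compatible variant makes two changes:

1. candidate labels outside the observation's subset S get weight zero
   before normalization (imputation from f(X | X ∈ S, Z, Y), which under
   CAR is the correct conditional), and
2. chains are initialized by drawing each non-singleton observation from
   the observed values compatible with S.

Together these guarantee — not just encourage — that no imputation
contradicts the coarsening information; the per-dataset incompatible count
is exactly zero.  Because the restriction only re-weights an explicit
multinomial, arbitrary proper subsets (`{a,c}`, four-level spaces, …) are
handled with no extra machinery.  A rejection-sampling formulation
(draw unrestricted, reject outside S) defines the same distribution and is
kept as a test oracle only.

Each of the m imputations runs its own chain: default 20 iterations, all
but the last discarded as burn-in, the final state kept.  One iteration
draws ψ from its approximate posterior given the current completed data,
then φ, then redraws every non-singleton X from the candidate weights.
Convergence is not formally tested; a per-iteration coefficient trace is
exposed for inspection.

Parameter draws use maximum likelihood plus a multivariate-normal
perturbation with the inverse observed information (flat priors):

* covariate model — multinomial logistic X ~ (1, Z) via statsmodels;
* linear substantive model — σ² from its scaled inverse-χ² conditional,
  then β | σ² ~ N(β̂, σ²(X'X)⁻¹);
* Cox substantive model — β ~ N(β̂, I⁻¹) with a Breslow step-function
  baseline cumulative hazard re-evaluated at the drawn β each iteration.
  The baseline factor h₀(t)^D cancels across candidate labels, so the
  per-label outcome factor is exp(D·lp − H₀(T)·e^lp).

Numerical safeguards: outcome likelihoods are computed on the log scale and
shifted by the per-row maximum before exponentiation; a row whose weights
all vanish raises rather than silently uniformizing; a multinomial fit that
fails to converge, produces non-finite parameters, or exceeds |coef| > 30
is treated as separation and recorded as a chain failure.

The Cox partial-likelihood maximizer (Newton-Raphson, Efron ties, Breslow
baseline) is implemented in-package: the sampler calls it thousands of
times per study and needs the MLE, the observed information and the
baseline hazard together on every iteration.  It is pinned against
lifelines (coefficients and standard errors to ~1e-4, with and without
ties) in the test suite.

## Comparator methods

* **CCA** — rows without a directly observed X are discarded.  Selection
  then depends on (X, Z); because both are covariates of the substantive
  model, the regression coefficients remain consistent (at reduced
  efficiency), while an imputation model *fit* to those rows does not.
* **Naive MICE** — coarsened and missing rows alike are treated as fully
  missing; X is imputed by polytomous (multinomial-logistic) regression on
  Z and the outcome terms.  For survival outcomes the imputation model uses
  the Nelson-Aalen marginal cumulative hazard at the subject's own time
  plus the event indicator, never the raw time.
* **MICE with C** — the coarsening column C (Table-style encoding: the
  coarse group of the observation) enters the imputation model as a
  categorical predictor.  Two dialects for rows with X completely missing:
  C is missing too and is itself imputed each cycle (binary logistic with a
  proper coefficient draw), or C's missing rows form an extra factor level
  and C is complete.  Since C = a identifies X = a exactly, rows whose
  value is pinned by C alone are kept fixed rather than re-imputed (an
  imputation model would return a with probability ≈ 1).
* **Two-step** — defined for the single pattern `{b,c}`: step 1 restricts
  to rows known to be b or c and imputes the coarsened rows by binary
  logistic regression fitted on the observed b/c rows (compatible by
  construction); step 2, if completely missing rows exist, imputes them
  once per step-1 dataset with a three-category model.
* **SMC-FCS with C as predictor** — putting C into the covariate model
  creates complete separation with X (among complete rows C = a iff
  X = a).  These variants exist only to demonstrate the failure mode: fits
  abort per chain and the failures are recorded, never raised out of a
  study loop.

Parameter-uncertainty conventions follow the reference chained-equations
implementation: the polytomous step draws from the fitted category
probabilities without a parameter draw (its known behaviour — and a cause
of the degraded interval coverage the naive methods show), while binary
logistic steps perturb the coefficients with a multivariate-normal draw.
A nonparametric-bootstrap refit is available for the polytomous step
(`param_draw="bootstrap"`); it widens pooled intervals noticeably.
Fits with categorical predictors add small-weight pseudo-observations
covering every (target category × predictor level) cell — weight
0.01·n/(number of cells), fitting only — to keep estimates finite under
separation.  MICE runs 10 cycles by default, visit order X then C; when C
is not used there is no chained feedback (the model is fit on the fixed
complete rows), so a single cycle draws from the identical distribution
and the implementation skips the redundant ones.

## Pooling and performance measures

Per completed dataset the substantive model is refitted (OLS; Cox with
Efron ties — inert for the simulated continuous event times but pinned for
reproducibility).  Rubin's rules pool m fits: Q̄ the mean estimate,
W the mean squared SE, B the between-imputation variance,
T = W + (1 + 1/m)B, degrees of freedom (m−1)(1 + W/((1+1/m)B))² (the
classic formula, without the small-sample correction; B = 0 or m = 1 gives
infinite df, flagged).  Across replications the package reports bias,
RMSE, mean SE, 95% coverage using the normal quantile z₀.₉₇₅ applied to
each replication's SE (a t variant is available behind a flag), and the
Monte-Carlo SE of the bias (primary form √(var/n_sim); the squared form is
also exposed because both appear in the study-design literature and the
printed sample-size arithmetic there is not internally consistent —
this package does not attempt to re-derive it).

The *incompatible-imputation percentage* is the share of imputations that
contradict a coarsened observation (an `a` imputed where `{b,c}` was
recorded), averaged over the m datasets.  It is reported relative to the
number of rows the method imputed (coarsened plus completely missing) —
the scale on which the simulation tables report it; a
`denominator="coarsened"` option rescales to the coarsened rows alone.

## The synthetic-data generator

One replicate draws, for n_obs individuals (default 2000):

* (X̃, Z1, Z2) trivariate normal, unit marginals, correlations
  (ρ_XZ1, ρ_XZ2, ρ_Z1Z2) with defaults 0; the study grid uses
  {0, 0.7} × {0, 0.3} × {0, 0.7} minus the two cells with
  ρ_XZ1 = 0, ρ_XZ2 = 0.3;
* X by thresholding X̃ at Φ⁻¹(p_a) and Φ⁻¹(p_a + p_b) (upper thresholds
  inclusive); frequency sets: uniform (⅓,⅓,⅓), bc-uniform (½,¼,¼),
  skewed (½,⅓,⅙);
* outcome: Y = β₀ + β₁1{X=b} + β₂1{X=c} + β₃Z1 + β₄Z2 + ε with ε ~ N(0,1),
  or an exponential event time with rate exp(of the same linear predictor),
  censored at Unif(5, 10), T = min, D the event indicator.  Defaults
  β₁ = β₃ = β₄ = 0.5, β₂ = 1, β₀ = 0 (continuous) or log 0.1 (survival);
  an effect multiplier {0.5, 1, 2} scales β₁, β₂;
* a pattern indicator R per row from a multinomial logistic model on
  (1, Z1, Z2): P(R=0|Z) = 1/(1 + e^{γ₁'Z} + e^{γ₂'Z}), slopes
  γ₁ = (·, 1, 0), γ₂ = (·, 0, 1).  R = 0 makes the row completely missing,
  R = 2 coarsens it to `{b,c}` — except that rows with X = a are exempt
  from coarsening and remain fully observed (their group-level value
  already identifies them).  The exemption makes the mechanism CAR with
  respect to the subsets but leaves the *direct* X record informatively
  missing for methods that discard the subsets — which is exactly the
  wedge the method comparison is about.

The intercepts γ₁₀, γ₂₀ are calibrated so the marginal pattern
probabilities E_Z[P(R=r|Z)] hit requested targets — study settings
(0.2, 0.4, 0.4) and (0.0, 0.4, 0.6) — by damped Newton iteration on a
fixed 10⁶-draw Monte-Carlo expectation (dedicated seed, steps clipped to
±2, residual < 1e-10, verified to 0.002; cached per setting).  A zero
missing-probability target is degenerate — no finite intercept zeroes a
softmax category — so that case drops the missing category and solves a
one-dimensional binary-logistic root (Brent).

Replication seeding: a scenario seed spawns independent per-replication
`SeedSequence` children, and each replication spawns one stream for data
generation plus one per method, so replications are reproducible and
order-independent.

What the generator does *not* emulate: real cohorts' non-normal covariates
and non-proportional hazards; coarsening of more than one covariate at a
time or multiple coarse patterns within one variable (the data model and
the restricted sampler accept them; the two-step method and the C encoding
are defined for a single pattern); coarsening-not-at-random.  Passing tests
therefore show correctness of the machinery under the stated generating
model, not robustness to model misspecification in real data.

## Problem sizes and reproduction

The desk-scale reruns (test suite and `scripts/acceptance.py`) use n = 2000
per replicate with m = 20 imputations for the chained-equations and
restricted-sampler runs, m = 10 for the survival SMC-FCS runs, and
40–165 replications per batch — chosen so a full rerun takes a few minutes
on one CPU while keeping the Monte-Carlo SE of each reported mean small
relative to its comparison band (coverage estimates get the largest
replication counts, being the noisiest per replication).  The full factorial
grid (216 cells) is exposed through `run-grid` and is intended to be run at
whatever n_sim the user's budget allows.

## Known limitations

* The approximate-posterior draws (MLE + normal perturbation) are standard
  for FCS samplers but are not exact Bayes; with small n or rare categories
  they can misrepresent tail uncertainty.
* The restricted sampler requires at least one observed value compatible
  with each subset for initialization.
* Interval-censored continuous covariates are out of scope (they would
  need true rejection sampling against the substantive density).
* The Rubin degrees of freedom omit the small-sample correction;
  with very small n and large missing fractions intervals may be slightly
  narrow.
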