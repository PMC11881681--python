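# coarsemi — multiple imputation for coarsened categorical covariates

Clinical and omics datasets often record a categorical variable only
*partially*: instead of the exact level, a subset of levels is observed that
is known to contain the true value.  The motivating example is a three-level
pathology score (absent / focally present / substantially present) that some
cohorts record only as absent vs *present*, where "present" pools the two
non-absent levels.  Such observations are **coarsened** — a strict
generalization of missing data: a singleton subset is a fully observed
value, the full sample space is a completely missing one, and anything in
between (e.g. `{b,c}` over the space `(a,b,c)`) carries partial information.
Feeding coarsened values into a standard multiple-imputation pipeline is not
straightforward, and treating them as fully missing can impute values the
data already rule out.

`coarsemi` is aimed at biostatisticians studying (or handling) this problem.
It provides:

* **SMC-FCS-style imputation with a coarsening-compatible restriction**
  (`SmcfcsImputer`).  Substantive-model-compatible fully conditional
  specification imputes a covariate X from the density

  f(X | Z, Y) ∝ f(Y | X, Z; ψ) · f(X | Z; φ),

  the product of the substantive (analysis) model likelihood and a covariate
  model.  Because X is categorical the draw is an explicit multinomial over
  the sample space.  With `restrict=True`, candidate labels outside an
  observation's coarse subset S get probability zero before normalization —
  equivalently, imputation from f(X | X∈S, Z, Y) — and chains are
  initialized from compatible observed values only, so an imputation can
  never contradict the coarsening information.  With `restrict=False` the
  standard algorithm runs, ignoring the subsets (the naive comparator).
* **Comparator methods**: complete-case analysis; chained-equations (MICE)
  variants that ignore the coarsening column C, include it as a predictor
  (NA or extra-level dialect for missing rows), or impute coarsened rows in
  two steps within the subset known to be b or c (`MiceImputer`,
  `TwoStepImputer`).
* **Analysis and pooling**: linear or Cox proportional-hazards substantive
  fits per completed dataset and Rubin's rules
  (T = W + (1 + 1/m)·B) with 95% intervals (`fit_substantive`,
  `rubin_pool`, `complete_case`).
* **A full simulation study engine** mirroring the evaluation design:
  trivariate-normal covariates with configurable correlations, a thresholded
  three-level X, linear-Gaussian and exponential-survival outcomes, a
  calibrated multinomial-logistic coarsening/missingness mechanism, a
  216-cell factorial grid, and performance metrics (bias, RMSE, z-interval
  coverage, Monte-Carlo SEs, incompatible-imputation percentage).

Imputers follow scikit-learn conventions (`fit`/`transform`,
`get_params`/`set_params`, fitted state in `result_`), with plain functions
(`smcfcs_impute`, `mice_run`, `two_step_impute`) as thin wrappers.

## Worked example

Simulate one reference-scenario dataset (n = 2000; X correlated with Z1 and
Z2 at 0.7/0.3; 20% of rows completely missing and a further ~25% coarsened
to `{b,c}`), impute with the coarsening-compatible sampler and pool:

```python
from coarsemi import (ScenarioConfig, simulate_replicate, smcfcs_impute,
                      rubin_pool, incompatible_pct)
from coarsemi.inference import fit_completed_frame

cfg = ScenarioConfig(n_obs=2000, rho_xz1=0.7, rho_xz2=0.3,
                     coarsen_probs=(0.2, 0.4, 0.4),
                     outcome_kind="continuous")
rep = simulate_replicate(cfg, 7)
print(rep.dataset.classification_counts())

res = smcfcs_impute(rep.dataset, m=10, n_iter=20, restrict=True,
                    random_state=7)
fits = [fit_completed_frame(df, ("a", "b", "c"), "continuous")
        for df in res.completed]
print(rubin_pool(fits).to_frame().round(3).to_string(index=False))
print("incompatible imputations:", incompatible_pct(res))
```

Output:

```
{'observed': 1092, 'coarsened': 507, 'missing': 401}
coefficient  estimate    se  ci_low  ci_high       df
  intercept     0.004 0.049  -0.092    0.100  416.719
        x_b     0.448 0.063   0.324    0.572  366.049
        x_c     0.944 0.091   0.762    1.125   92.043
         z1     0.527 0.032   0.465    0.590  420.566
         z2     0.465 0.024   0.418    0.512 1532.369
incompatible imputations: 0.0
```

The generating coefficients were (0, 0.5, 1, 0.5, 0.5): every pooled
estimate sits within its 95% interval, and — by construction — none of the
507 coarsened observations was imputed with the excluded level `a`.
Running the same data through the unrestricted sampler or naive MICE
typically imputes `a` for roughly a fifth of the imputed rows and
attenuates the `x_c` coefficient.

## Command line

```sh
coarsemi make-fixture table1 table1.csv        # the 8-row worked example
coarsemi make-fixture scenario3_small s3.csv   # a small seeded replicate
coarsemi impute s3.csv --method smcfcs_c --outcome continuous -m 10 --seed 1
coarsemi run-scenario --config scenario.yaml --methods cca,smcfcs_c \
    --n-sim 20 -m 10 --out-dir out/
coarsemi run-grid --out-dir grid/ --limit 4    # slices of the 216-cell grid
```

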