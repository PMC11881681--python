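"""Orchestration: run one method on one dataset, run a replication study,
run the factorial grid; seeding, manifests and fixtures.

Method failures (separation, non-convergence) inside a replication are
first-class results: they are recorded in the output records and the run
manifest instead of aborting the study.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .coarse import AnalysisDataset, CoarseValue, SampleSpace, parse_token
from .fcs import mice_run, two_step_impute
from .inference import complete_case, fit_completed_frame, rubin_pool
from .metrics import incompatible_pct, summarize_replications
from .simulate import (LABELS, SPACE, ScenarioConfig, scenario_grid,
                       simulate_replicate)
from .smcfcs import ImputationResult, SmcfcsImputer

__all__ = ["METHODS", "MethodOutcome", "apply_method", "run_method",
           "run_scenario", "make_fixture", "TABLE1_ROWS"]

METHODS = ("cca", "mice_naive", "mice_c_na", "mice_c_cat", "mice_2step",
           "smcfcs", "smcfcs_c")

# Infeasible-by-separation variants, kept only to demonstrate and record the
# failure mode of putting C directly into an SMC-FCS covariate model.
INFEASIBLE_METHODS = ("smcfcs_c_na", "smcfcs_c_cat")


@dataclass
class MethodOutcome:
    method: str
    pooled: dict | None = None           # coefficient -> (estimate, se)
    incompatible_pct: float | None = None
    n_failures: int = 0
    failed: bool = False
    error: str | None = None


def _pool_imputations(result: ImputationResult, space_labels, outcome_kind):
    fits = [fit_completed_frame(df, space_labels, outcome_kind)
            for df in result.completed]
    pooled = rubin_pool(fits)
    return {k: (pooled.coef[k], pooled.se[k]) for k in pooled.coef}


def apply_method(method: str, dataset: AnalysisDataset, m: int = 5,
                 n_iter: int = 20, n_cycles: int = 10,
                 random_state=None) -> MethodOutcome:
    """Impute (where applicable), fit and pool; failures are recorded."""
    labels = dataset.space.labels
    kind = dataset.outcome_kind
    try:
        if method == "cca":
            fit = complete_case(dataset)
            return MethodOutcome(method=method,
                                 pooled={k: (fit.coef[k], fit.se[k])
                                         for k in fit.coef})
        if method in {"mice_naive", "mice_c_na", "mice_c_cat"}:
            res = mice_run(dataset, variant=method, m=m, n_cycles=n_cycles,
                           random_state=random_state)
        elif method == "mice_2step":
            res = two_step_impute(dataset, m=m, random_state=random_state)
        elif method in {"smcfcs", "smcfcs_c"}:
            imp = SmcfcsImputer(m=m, n_iter=n_iter,
                                restrict=(method == "smcfcs_c"),
                                random_state=random_state)
            res = imp.fit(dataset).result_
        elif method in INFEASIBLE_METHODS:
            dialect = "na" if method.endswith("_na") else "full_set"
            imp = SmcfcsImputer(m=m, n_iter=n_iter, restrict=False,
                                c_predictor=dialect, random_state=random_state)
            res = imp.fit(dataset).result_
        else:
            raise ValueError(f"unknown method {method!r}")
    except Exception as e:  # noqa: BLE001 - a method failure is a result
        return MethodOutcome(method=method, failed=True, error=str(e))

    n_fail = len(res.failures)
    if not res.completed:
        return MethodOutcome(method=method, failed=True, n_failures=n_fail,
                             error=res.failures[-1]["error"] if res.failures
                             else "no completed datasets")
    out = MethodOutcome(method=method, n_failures=n_fail)
    try:
        out.pooled = _pool_imputations(res, labels, kind)
    except Exception as e:  # noqa: BLE001
        out.failed = True
        out.error = str(e)
    if res.n_coarsened:
        out.incompatible_pct = incompatible_pct(res)
    return out


def run_method(dataset_path, method: str, outcome_kind: str, m: int = 5,
               seed: int = 0, out_prefix=None) -> pd.DataFrame:
    """Run one method on a CSV dataset; write tidy CSV + JSON diagnostics."""
    from .coarse import read_dataset_csv
    dataset = read_dataset_csv(dataset_path, SPACE, outcome_kind)
    outcome = apply_method(method, dataset, m=m, random_state=seed)
    if outcome.failed:
        raise RuntimeError(f"method {method} failed: {outcome.error}")
    rows = [{"coefficient": k, "estimate": v[0], "se": v[1], "method": method}
            for k, v in outcome.pooled.items()]
    df = pd.DataFrame(rows)
    if out_prefix is not None:
        df.to_csv(f"{out_prefix}.csv", index=False)
        with open(f"{out_prefix}.json", "w") as fh:
            json.dump({"method": method, "m": m, "seed": seed,
                       "incompatible_pct": outcome.incompatible_pct,
                       "n_failures": outcome.n_failures}, fh, indent=2)
    return df


def run_scenario(config: ScenarioConfig, methods=METHODS, n_sim=None,
                 m=None, n_iter: int = 20, n_cycles: int = 10,
                 progress: bool = False):
    """Run a replication study for one scenario.

    Returns (records, summary, manifest): tidy per-replication records, the
    per-method performance summary and a reproducibility manifest.  Seeds
    are spawned per replication from the scenario seed, so replications are
    reproducible independently of execution order.
    """
    n_sim = config.n_sim if n_sim is None else n_sim
    m = config.m if m is None else m
    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.spawn(n_sim)
    records, failures = [], []
    t0 = time.time()
    for i, seq in enumerate(rep_seeds):
        child = seq.spawn(1 + len(methods))
        rep = simulate_replicate(config, np.random.default_rng(child[0]))
        for j, method in enumerate(methods):
            outcome = apply_method(method, rep.dataset, m=m, n_iter=n_iter,
                                   n_cycles=n_cycles,
                                   random_state=np.random.default_rng(child[1 + j]))
            if outcome.failed:
                failures.append({"replication": i, "method": method,
                                 "error": outcome.error})
                continue
            for coefficient, (est, se) in outcome.pooled.items():
                records.append({
                    "replication": i, "method": method,
                    "coefficient": coefficient, "estimate": est, "se": se,
                    "incompatible_pct": outcome.incompatible_pct,
                    "n_failures": outcome.n_failures,
                })
        if progress:
            print(f"replication {i + 1}/{n_sim} "
                  f"({time.time() - t0:.1f}s)", flush=True)
    records = pd.DataFrame(records)
    beta_true = config.true_coefficients.as_dict(config.outcome_kind)
    summary = (summarize_replications(records, beta_true)
               if len(records) else pd.DataFrame())
    manifest = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "n_sim": n_sim, "m": m, "n_iter": n_iter, "n_cycles": n_cycles,
        "methods": list(methods),
        "rep_seeds": [list(map(int, s.entropy if isinstance(s.entropy, tuple)
                               else [s.entropy])) + list(s.spawn_key)
                      for s in rep_seeds],
        "elapsed_s": time.time() - t0,
        "failures": failures,
    }
    return records, summary, manifest


def reference_subscenario(outcome_kind: str = "continuous", seed: int = 0,
                          n_sim: int = 40, m: int = 20) -> ScenarioConfig:
    """The headline factorial cell used for desk-scale method comparison:
    X correlated with both covariates (0.7 and 0.3, Z1-Z2 uncorrelated),
    uniform category frequencies, medium effect sizes, and both coarsening
    and missingness (pattern probabilities 0.2/0.4/0.4)."""
    return ScenarioConfig(rho_xz1=0.7, rho_xz2=0.3, rho_z1z2=0.0,
                          category_probs=(1 / 3, 1 / 3, 1 / 3),
                          effect_multiplier=1.0, coarsen_probs=(0.2, 0.4, 0.4),
                          outcome_kind=outcome_kind, seed=seed,
                          n_sim=n_sim, m=m)


# -- fixtures -----------------------------------------------------------------

# the printed worked example: 8 individuals with true value, observed value,
# covariates and continuous outcome
TABLE1_ROWS = [
    # (id, x_compl, x_obs, z1, z2, y)
    (1, "a", "a", -0.966, -0.166, -0.170),
    (2, "b", "b", 1.097, -0.619, 1.592),
    (3, "c", "c", 0.714, 2.389, 4.592),
    (4, "b", "b|c", -0.291, 0.743, -0.543),
    (5, "c", "b|c", 0.729, 0.456, 2.270),
    (6, "a", "", 1.035, 0.204, 1.387),
    (7, "b", "", -0.351, -0.317, 0.637),
    (8, "c", "", 0.224, -0.150, 0.430),
]


def table1_dataset() -> AnalysisDataset:
    x = [parse_token(r[2], SPACE) for r in TABLE1_ROWS]
    z = pd.DataFrame({"z1": [r[3] for r in TABLE1_ROWS],
                      "z2": [r[4] for r in TABLE1_ROWS]})
    y = np.array([r[5] for r in TABLE1_ROWS])
    return AnalysisDataset(x=x, z=z, outcome_kind="continuous", y=y)


def make_fixture(name: str, path) -> None:
    """Write a named fixture dataset to CSV."""
    if name == "table1":
        df = table1_dataset().to_frame()
        df.insert(1, "x_true", [r[1] for r in TABLE1_ROWS])
        df.to_csv(path, index=False)
    elif name == "scenario3_small":
        config = ScenarioConfig(n_obs=300, rho_xz1=0.7, rho_xz2=0.3,
                                coarsen_probs=(0.2, 0.4, 0.4), seed=42)
        rep = simulate_replicate(config, np.random.default_rng(42))
        df = rep.dataset.to_frame()
        df.insert(1, "x_true", rep.x_true)
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown fixture {name!r}")
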