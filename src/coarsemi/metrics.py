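"""Performance measures across simulation replications.

Per coefficient and method: bias (mean estimate minus truth), RMSE
(root mean squared error of the estimates), 95% interval coverage using the
normal quantile z_{0.975} applied to the per-replication standard errors, and
the Monte-Carlo standard error of the bias.  Per method: the percentage of
coarsened observations imputed with a label outside their coarse subset,
averaged over imputed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .smcfcs import ImputationResult

__all__ = ["bias_rmse_coverage", "incompatible_pct", "mcse_bias",
           "summarize_replications"]

Z975 = stats.norm.ppf(0.975)


def bias_rmse_coverage(estimates, ses, beta_true: float,
                       interval: str = "z", df=None):
    """(bias, rmse, coverage) over replications.

    Coverage counts replications whose interval estimate +/- q * SE contains
    the truth, with q = z_{0.975} by default; ``interval="t"`` uses the
    t-quantile with the supplied per-replication degrees of freedom (a
    sensitivity variant for pooled estimates).
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if estimates.shape != ses.shape:
        raise ValueError("estimates and ses must have equal length")
    if interval == "z":
        q = Z975
    elif interval == "t":
        if df is None:
            raise ValueError("t intervals need degrees of freedom")
        q = stats.t.ppf(0.975, np.minimum(np.asarray(df, dtype=float), 1e12))
    else:
        raise ValueError(f"unknown interval type {interval!r}")
    bias = estimates.mean() - beta_true
    rmse = float(np.sqrt(np.mean((estimates - beta_true) ** 2)))
    covered = (estimates - q * ses < beta_true) & (beta_true < estimates + q * ses)
    return float(bias), rmse, float(covered.mean())


def incompatible_pct(result: ImputationResult, denominator: str = "imputed"
                     ) -> float:
    """Percentage of imputations that contradict a coarsened observation,
    averaged over the m imputed datasets.

    Incompatible imputations can only occur on coarsened rows (a completely
    missing row is compatible with everything).  The percentage is taken
    relative to the number of rows the method imputed (coarsened plus
    completely missing), the scale on which the simulation tables report it;
    ``denominator="coarsened"`` rescales to the coarsened rows alone.
    """
    if result.n_coarsened == 0:
        raise ValueError("no coarsened observations: percentage undefined")
    denom = {"imputed": result.n_imputed or result.n_coarsened,
             "coarsened": result.n_coarsened}[denominator]
    per_dataset = 100.0 * np.asarray(result.incompatible_counts,
                                     dtype=float) / denom
    return float(per_dataset.mean())


@dataclass
class McseBias:
    """MCSE of the bias: sqrt(var/nsim) primary, var/nsim secondary."""

    value: float          # sqrt(var(estimates) / nsim)
    squared: float        # var(estimates) / nsim


def mcse_bias(estimates) -> McseBias:
    estimates = np.asarray(estimates, dtype=float)
    if len(estimates) < 2:
        raise ValueError("MCSE needs at least 2 replications")
    v = estimates.var(ddof=1) / len(estimates)
    return McseBias(value=float(np.sqrt(v)), squared=float(v))


def summarize_replications(records: pd.DataFrame, beta_true: dict,
                           interval: str = "z") -> pd.DataFrame:
    """Per (method, coefficient) performance table from replication records.

    ``records`` needs columns method, replication, coefficient, estimate, se
    (one row per coefficient per replication) and optionally
    incompatible_pct (one value per replication, repeated across
    coefficients).
    """
    rows = []
    for (method, coefficient), g in records.groupby(["method", "coefficient"],
                                                    sort=False):
        if coefficient not in beta_true:
            continue
        bias, rmse, cov = bias_rmse_coverage(
            g["estimate"], g["se"], beta_true[coefficient], interval=interval)
        row = {
            "method": method, "coefficient": coefficient,
            "bias": bias, "rmse": rmse, "coverage": cov,
            "mean_se": float(g["se"].mean()),
            "mcse_bias": mcse_bias(g["estimate"]).value,
            "n_sim": len(g),
        }
        if "incompatible_pct" in g:
            vals = g["incompatible_pct"].dropna()
            if len(vals):
                row["incompatible_mean"] = float(vals.mean())
                row["incompatible_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
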