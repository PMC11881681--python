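"""Substantive-model fitting, Rubin pooling and complete-case analysis.

The substantive model is a linear regression (continuous outcome) or a Cox
proportional-hazards model (survival outcome) of the outcome on the
categorical covariate (indicator-coded against the first sample-space label)
and the continuous covariates.  Estimates from the m completed datasets are
combined with Rubin's rules: pooled estimate = mean, total variance
T = W + (1 + 1/m) B with W the mean squared standard error and B the
between-imputation variance, degrees of freedom by the classic
(m - 1)(1 + W / ((1 + 1/m) B))^2 formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coarse import AnalysisDataset
from .cox import fit_cox

__all__ = ["FitResult", "PooledFit", "fit_substantive", "fit_completed_frame",
           "rubin_pool", "complete_case"]


@dataclass
class FitResult:
    coef: dict           # name -> estimate
    se: dict             # name -> standard error
    n_used: int

    def aligned(self, names):
        return (np.array([self.coef[n] for n in names]),
                np.array([self.se[n] for n in names]))


@dataclass
class PooledFit:
    coef: dict
    within_var: dict
    between_var: dict
    total_var: dict
    df: dict
    ci_low: dict
    ci_high: dict
    m: int

    @property
    def se(self) -> dict:
        return {k: float(np.sqrt(v)) for k, v in self.total_var.items()}

    def to_frame(self) -> pd.DataFrame:
        names = list(self.coef)
        return pd.DataFrame({
            "coefficient": names,
            "estimate": [self.coef[n] for n in names],
            "se": [self.se[n] for n in names],
            "ci_low": [self.ci_low[n] for n in names],
            "ci_high": [self.ci_high[n] for n in names],
            "df": [self.df[n] for n in names],
        })


def _coef_names(space_labels, z_cols, outcome_kind) -> list:
    names = [f"x_{l}" for l in space_labels[1:]] + list(z_cols)
    if outcome_kind == "continuous":
        names = ["intercept"] + names
    return names


def fit_completed_frame(df: pd.DataFrame, space_labels, outcome_kind) -> FitResult:
    """Fit the substantive model to a completed (no-missing) data frame.

    Expects columns ``x``, the covariates, and ``y`` or ``time``/``status``.
    """
    z_cols = [c for c in df.columns
              if c not in {"x", "x_true", "y", "time", "status", "r"}]
    x = df["x"].to_numpy()
    dummies = np.column_stack([(x == l).astype(float) for l in space_labels[1:]])
    if (dummies.sum(axis=0) == 0).any() or (x == space_labels[0]).sum() == 0:
        raise ValueError("a category is absent: coefficients unidentified")
    zmat = df[z_cols].to_numpy(float)
    names = _coef_names(space_labels, z_cols, outcome_kind)
    if outcome_kind == "continuous":
        X = np.c_[np.ones(len(df)), dummies, zmat]
        if len(df) <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular or under-identified design")
        res = sm.OLS(df["y"].to_numpy(float), X).fit()
        coef, se = res.params, res.bse
    else:
        X = np.c_[dummies, zmat]
        fit = fit_cox(X, df["time"].to_numpy(float), df["status"].to_numpy(int))
        coef, se = fit.coef, np.sqrt(np.diag(fit.cov))
    return FitResult(coef=dict(zip(names, coef)), se=dict(zip(names, se)),
                     n_used=len(df))


def fit_substantive(dataset_completed: AnalysisDataset | pd.DataFrame,
                    outcome_kind: str | None = None,
                    space_labels=None) -> FitResult:
    """Fit the substantive model to a completed dataset.

    Accepts either an :class:`AnalysisDataset` whose observations are all
    singletons, or a completed data frame together with the label order.
    """
    if isinstance(dataset_completed, AnalysisDataset):
        ds = dataset_completed
        if any(not s.is_observed for s in ds.x):
            raise ValueError("dataset contains non-singleton observations")
        return fit_completed_frame(ds.to_frame(), ds.space.labels, ds.outcome_kind)
    if outcome_kind is None or space_labels is None:
        raise ValueError("frame input requires outcome_kind and space_labels")
    return fit_completed_frame(dataset_completed, space_labels, outcome_kind)


def complete_case(dataset: AnalysisDataset) -> FitResult:
    """Discard every row without a directly observed X and fit the model.

    Rows whose value is only known through the coarsening column (singleton
    subsets with indicator R != 1) are discarded too: complete-case analysis
    uses the X record alone.
    """
    df = dataset.to_frame().loc[dataset.directly_observed]
    return fit_completed_frame(df, dataset.space.labels, dataset.outcome_kind)


def rubin_pool(fits: list, alpha: float = 0.05) -> PooledFit:
    """Pool per-imputation fits with Rubin's rules.

    With a single fit the between-imputation variance is undefined; the
    pooled variance then equals the within variance with infinite degrees of
    freedom (flagged by df = inf).
    """
    if not fits:
        raise ValueError("no fits to pool")
    names = list(fits[0].coef)
    for f in fits[1:]:
        if list(f.coef) != names:
            raise ValueError("mismatched coefficient sets across imputations")
    m = len(fits)
    est = np.array([[f.coef[n] for n in names] for f in fits])   # (m, p)
    ses = np.array([[f.se[n] for n in names] for f in fits])
    qbar = est.mean(axis=0)
    W = (ses ** 2).mean(axis=0)
    if m > 1:
        B = est.var(axis=0, ddof=1)
    else:
        B = np.zeros(len(names))
    T = W + (1 + 1 / m) * B
    with np.errstate(divide="ignore"):
        df = np.where((B > 0) & (m > 1),
                      (m - 1) * (1 + W / ((1 + 1 / m) * np.where(B > 0, B, 1))) ** 2,
                      np.inf)
    tq = np.where(np.isinf(df), stats.norm.ppf(1 - alpha / 2),
                  stats.t.ppf(1 - alpha / 2, np.where(np.isinf(df), 1, df)))
    half = tq * np.sqrt(T)
    return PooledFit(
        coef=dict(zip(names, qbar)),
        within_var=dict(zip(names, W)),
        between_var=dict(zip(names, B)),
        total_var=dict(zip(names, T)),
        df=dict(zip(names, df)),
        ci_low=dict(zip(names, qbar - half)),
        ci_high=dict(zip(names, qbar + half)),
        m=m,
    )
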