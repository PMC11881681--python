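"""MICE-style chained-equations imputation variants for the coarsened
categorical covariate, plus the two-step subset method.

Four variants are provided, differing only in how the coarsening column C is
used:

* ``mice_naive`` — C is ignored; every non-singleton observation of X is
  treated as completely missing and imputed by polytomous (multinomial
  logistic) regression on Z and the outcome.
* ``mice_c_na`` — C enters the imputation model for X as a categorical
  predictor; rows with X completely missing also have C missing (NA dialect)
  and C is itself imputed each cycle.
* ``mice_c_cat`` — as above, but missing C is recoded as the extra factor
  level "{a,b,c}" so C is complete and never imputed.
* ``mice_2step`` — coarsened rows are imputed within the subset of rows known
  to be b or c (binary logistic), guaranteeing compatibility; completely
  missing rows are then imputed once per completed dataset with a
  three-category model.

For survival outcomes the imputation models use the Nelson-Aalen estimate of
the marginal cumulative hazard at each subject's time together with the event
indicator, never the raw time.

Following the conventions of the reference chained-equations implementation,
the polytomous (3+ category) imputation step draws each missing entry from
the fitted category probabilities without a parameter draw, while binary
steps (the coarsened b-vs-c choice of the two-step method, and the
imputation of C itself) perturb the logistic coefficients with a
multivariate-normal draw from the inverse observed information.  A
nonparametric-bootstrap refit is available as an alternative uncertainty
scheme for the polytomous step.  Fits involving categorical predictors are
stabilized with the augmentation of White et al.: small-weight
pseudo-observations covering every (target category x
categorical-predictor level) cell, used in fitting only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .coarse import AnalysisDataset, encode_observed
from .smcfcs import ImputationResult

__all__ = [
    "FcsVariant",
    "AugmentationSpec",
    "VARIANTS",
    "nelson_aalen",
    "polyreg_impute_step",
    "logreg_impute_step",
    "MiceImputer",
    "TwoStepImputer",
    "mice_run",
    "two_step_impute",
]


@dataclass(frozen=True)
class FcsVariant:
    name: str
    uses_c: bool
    c_dialect: str  # "na" | "full_set" | "none"


VARIANTS = {
    "mice_naive": FcsVariant("mice_naive", uses_c=False, c_dialect="none"),
    "mice_c_na": FcsVariant("mice_c_na", uses_c=True, c_dialect="na"),
    "mice_c_cat": FcsVariant("mice_c_cat", uses_c=True, c_dialect="full_set"),
    "mice_2step": FcsVariant("mice_2step", uses_c=False, c_dialect="none"),
}


@dataclass(frozen=True)
class AugmentationSpec:
    """White-et-al pseudo-observation weights for separation-prone fits."""

    enabled: bool = True
    weight: float = 0.01  # per-cell weight is weight * n / n_cells

    def __post_init__(self):
        if self.enabled and not 0 < self.weight < 1:
            raise ValueError("augmentation weight must be in (0, 1)")


def nelson_aalen(time, status) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each subject's own time.

    H(t) = sum over event times t_i <= t of d_i / n_i, with n_i the at-risk
    count just before t_i.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    if len(time) == 0:
        raise ValueError("empty input")
    order = np.argsort(time, kind="stable")
    to, so = time[order], status[order]
    n = len(to)
    uniq, first = np.unique(to, return_index=True)
    # at-risk just before each unique time; events per unique time
    at_risk = n - first
    d = np.bincount(np.searchsorted(uniq, to[so == 1]), minlength=len(uniq))
    H = np.cumsum(d / at_risk)
    idx = np.searchsorted(uniq, time, side="right") - 1
    return np.where(idx >= 0, H[np.clip(idx, 0, None)], 0.0)


def _fit_logistic(X, y, weights=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(C=np.inf, max_iter=1000)
        clf.fit(X, y, sample_weight=weights)
    return clf


def _augment_rows(n_target_cats: int, design: np.ndarray,
                  cat_cols: list, weight_total: float):
    """Pseudo-rows covering every (target category x categorical cell).

    ``cat_cols`` lists column indices of the design that are 0/1 indicators
    coding one categorical predictor (plus the implicit reference cell);
    continuous columns are set to their observed means.  Returns
    (X_aug, y_aug, w_aug).
    """
    means = design.mean(axis=0)
    n_levels = len(cat_cols) + 1
    cells = []
    for lev in range(n_levels):
        row = means.copy()
        for j, col in enumerate(cat_cols):
            row[col] = 1.0 if j == lev - 1 else 0.0
        cells.append(row)
    X_aug, y_aug = [], []
    for k in range(n_target_cats):
        for row in cells:
            X_aug.append(row)
            y_aug.append(k)
    w = np.full(len(X_aug), weight_total / len(X_aug))
    return np.array(X_aug), np.array(y_aug), w


def polyreg_impute_step(target: np.ndarray, design: np.ndarray,
                        rng: np.random.Generator,
                        augmentation: AugmentationSpec = AugmentationSpec(enabled=False),
                        cat_cols: list | None = None,
                        n_categories: int | None = None,
                        param_draw: str = "none") -> np.ndarray:
    """One polytomous-regression imputation step.

    ``target`` holds category codes with -1 for missing.  A multinomial
    logistic model is fitted on the complete rows (augmented with
    small-weight pseudo-rows when requested) and each missing entry is drawn
    from its fitted category probabilities.  ``param_draw`` controls
    parameter uncertainty: ``"none"`` (the polytomous default of the
    reference chained-equations implementation) uses the point fit,
    ``"bootstrap"`` refits on a nonparametric resample of the complete rows.
    Returns the drawn codes for the missing entries (empty when nothing is
    missing).
    """
    target = np.asarray(target)
    obs = np.flatnonzero(target >= 0)
    mis = np.flatnonzero(target < 0)
    if len(mis) == 0:
        return np.empty(0, dtype=int)
    if param_draw not in {"none", "bootstrap"}:
        raise ValueError(f"unknown param_draw {param_draw!r}")
    K = n_categories or int(target[obs].max()) + 1
    for attempt in range(10):
        if param_draw == "bootstrap":
            boot = rng.integers(len(obs), size=len(obs))
            Xb, yb = design[obs][boot], target[obs][boot]
        else:
            Xb, yb = design[obs], target[obs]
        wb = np.ones(len(yb))
        if augmentation.enabled:
            Xa, ya, wa = _augment_rows(K, design[obs], cat_cols or [],
                                       augmentation.weight * len(obs))
            Xb, yb, wb = np.vstack([Xb, Xa]), np.r_[yb, ya], np.r_[wb, wa]
        if len(np.unique(yb)) == K:
            break
    else:
        raise RuntimeError("bootstrap sample degenerate: a category vanished")
    try:
        clf = _fit_logistic(Xb, yb, wb)
    except Exception as e:
        raise RuntimeError(f"polytomous imputation model failed: {e}") from e
    probs = clf.predict_proba(design[mis])
    # map class order back to code order
    full = np.zeros((len(mis), K))
    for j, cls in enumerate(clf.classes_):
        full[:, int(cls)] = probs[:, j]
    u = rng.uniform(size=len(mis))
    return (full.cumsum(axis=1) < u[:, None]).sum(axis=1)


def logreg_impute_step(target: np.ndarray, design: np.ndarray,
                       rng: np.random.Generator,
                       augmentation: AugmentationSpec = AugmentationSpec(enabled=False),
                       cat_cols: list | None = None) -> np.ndarray:
    """One binary logistic imputation step with a proper parameter draw.

    Mirrors the binary convention of the reference implementation: fit by
    maximum likelihood (with augmentation pseudo-rows where requested), draw
    the coefficients from a multivariate normal with the inverse observed
    information, and draw each missing entry from the implied probability.
    ``target`` holds codes 0/1 with -1 for missing.
    """
    import statsmodels.api as sm

    target = np.asarray(target)
    obs = np.flatnonzero(target >= 0)
    mis = np.flatnonzero(target < 0)
    if len(mis) == 0:
        return np.empty(0, dtype=int)
    X = np.c_[np.ones(len(obs)), design[obs]]
    y = target[obs].astype(float)
    w = np.ones(len(obs))
    if augmentation.enabled:
        Xa, ya, wa = _augment_rows(2, design[obs], cat_cols or [],
                                   augmentation.weight * len(obs))
        X = np.vstack([X, np.c_[np.ones(len(Xa)), Xa]])
        y = np.r_[y, ya.astype(float)]
        w = np.r_[w, wa]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(),
                         freq_weights=w).fit()
            beta = rng.multivariate_normal(res.params,
                                           res.cov_params(),
                                           method="cholesky")
        except Exception as e:
            raise RuntimeError(f"binary imputation model failed: {e}") from e
    lp = np.c_[np.ones(len(mis)), design[mis]] @ beta
    p1 = 1.0 / (1.0 + np.exp(-lp))
    return (rng.uniform(size=len(mis)) < p1).astype(int)


def _outcome_columns(dataset: AnalysisDataset) -> np.ndarray:
    if dataset.outcome_kind == "continuous":
        return dataset.y[:, None]
    H = nelson_aalen(dataset.time, dataset.status)
    return np.c_[H, dataset.status.astype(float)]


def _completed_frame(dataset: AnalysisDataset, codes: np.ndarray) -> pd.DataFrame:
    labels = np.array(dataset.space.labels, dtype=object)[codes]
    df = pd.DataFrame({"x": labels})
    for c in dataset.z.columns:
        df[c] = np.asarray(dataset.z[c])
    if dataset.outcome_kind == "continuous":
        df["y"] = dataset.y
    else:
        df["time"] = dataset.time
        df["status"] = dataset.status
    return df


class MiceImputer(BaseEstimator):
    """Chained-equations imputer for the coarsened covariate.

    ``variant`` selects how the coarsening column C is handled (see module
    docstring).  Each of the m imputations runs an independent chain of
    ``n_cycles`` cycles with visit order X then (where applicable) C; the
    final cycle's values form the completed dataset.
    """

    def __init__(self, variant: str = "mice_naive", m: int = 5,
                 n_cycles: int = 10, augment_weight: float = 0.01,
                 param_draw: str = "none", random_state=None):
        self.variant = variant
        self.m = m
        self.n_cycles = n_cycles
        self.augment_weight = augment_weight
        self.param_draw = param_draw
        self.random_state = random_state

    def fit(self, X: AnalysisDataset, y=None) -> "MiceImputer":
        dataset = X
        var = VARIANTS.get(self.variant)
        if var is None or var.name == "mice_2step":
            raise ValueError(f"unknown MICE variant {self.variant!r}")
        rng = np.random.default_rng(self.random_state)
        space = dataset.space
        K = len(space)
        mask = dataset.subset_mask()
        base_codes = dataset.singleton_codes()
        # variants that ignore C treat every row whose direct X record is
        # missing (R != 1) as completely missing; the C-aware variants keep
        # singleton subsets fixed, including values identified via C alone
        obs_mask = (base_codes >= 0) if var.uses_c else dataset.directly_observed
        x_mis = np.flatnonzero(~obs_mask)
        coarsened = np.array([s.is_coarsened for s in dataset.x])
        n_coarsened = int(coarsened.sum())

        zmat = dataset.z.to_numpy(float)
        ycols = _outcome_columns(dataset)
        base_design = np.c_[zmat, ycols]

        # C column via the two-column X/C encoding; -1 marks NA-dialect
        # missing rows
        if var.uses_c:
            enc = encode_observed(dataset.x, c_dialect=var.c_dialect)
            c_levels = sorted({t for t in enc.c_col if t is not None})
            level_idx = {t: i for i, t in enumerate(c_levels)}
            c_codes = np.array([-1 if t is None else level_idx[t]
                                for t in enc.c_col])
            n_c_levels = len(c_levels)
        else:
            c_codes = np.zeros(dataset.n, dtype=int)
            n_c_levels = 1

        completed, incompat = [], []
        aug = AugmentationSpec(enabled=var.uses_c, weight=self.augment_weight)
        for _ in range(self.m):
            chain = np.random.default_rng(rng.integers(2 ** 63))
            codes = np.where(obs_mask, base_codes, -1)
            # initial fill from observed marginals
            obs_pool = base_codes[obs_mask]
            codes[x_mis] = obs_pool[chain.integers(len(obs_pool), size=len(x_mis))]
            c_cur = c_codes.copy()
            c_mis = np.flatnonzero(c_cur < 0)
            if len(c_mis):
                c_pool = c_cur[c_cur >= 0]
                c_cur[c_mis] = c_pool[chain.integers(len(c_pool), size=len(c_mis))]

            # without C there is no chained feedback: the imputation model is
            # fit on the fixed complete rows, so a single cycle draws from
            # the identical distribution
            cycles = self.n_cycles if var.uses_c else 1
            for _cycle in range(cycles):
                if var.uses_c:
                    c_dum = np.eye(n_c_levels)[c_cur][:, 1:]
                    design_x = np.c_[base_design, c_dum]
                    cat_cols = list(range(base_design.shape[1], design_x.shape[1]))
                else:
                    design_x, cat_cols = base_design, []
                tgt = codes.copy()
                tgt[x_mis] = -1
                codes[x_mis] = polyreg_impute_step(
                    tgt, design_x, chain, aug, cat_cols, n_categories=K,
                    param_draw=self.param_draw)
                if var.uses_c and var.c_dialect == "na" and len(c_mis):
                    x_dum = np.eye(K)[codes][:, 1:]
                    design_c = np.c_[base_design, x_dum]
                    ccat = list(range(base_design.shape[1], design_c.shape[1]))
                    tgt_c = c_cur.copy()
                    tgt_c[c_mis] = -1
                    if n_c_levels == 2:
                        c_cur[c_mis] = logreg_impute_step(
                            tgt_c, design_c, chain, aug, ccat)
                    else:
                        c_cur[c_mis] = polyreg_impute_step(
                            tgt_c, design_c, chain, aug, ccat,
                            n_categories=n_c_levels,
                            param_draw=self.param_draw)
            completed.append(_completed_frame(dataset, codes))
            bad = (~mask[np.arange(dataset.n), codes]) & coarsened
            incompat.append(int(bad.sum()))

        self.result_ = ImputationResult(completed=completed,
                                        incompatible_counts=incompat,
                                        n_coarsened=n_coarsened,
                                        n_imputed=len(x_mis))
        return self

    def transform(self, X=None) -> list:
        if not hasattr(self, "result_"):
            raise RuntimeError("imputer is not fitted")
        return self.result_.completed

    def fit_transform(self, X: AnalysisDataset, y=None) -> list:
        return self.fit(X).transform()


class TwoStepImputer(BaseEstimator):
    """Two-step subset imputation for the single coarse pattern {b, c}.

    Step 1 restricts to rows known to be b or c (observed singletons and the
    coarsened rows) and imputes the coarsened rows by binary logistic
    regression fitted on the observed b/c rows only — imputations are
    compatible by construction.  Step 2, when completely missing rows exist,
    imputes them once per step-1 dataset with a three-category model fitted
    on the then-complete remainder.
    """

    def __init__(self, m: int = 5, random_state=None):
        self.m = m
        self.random_state = random_state

    def fit(self, X: AnalysisDataset, y=None) -> "TwoStepImputer":
        dataset = X
        rng = np.random.default_rng(self.random_state)
        space = dataset.space
        K = len(space)
        base_codes = dataset.singleton_codes()
        coarsened = np.array([s.is_coarsened for s in dataset.x])
        fully_missing = np.array([s.is_missing for s in dataset.x])
        for s in np.asarray(dataset.x, dtype=object)[coarsened]:
            if s.sorted_labels() != ("b", "c"):
                raise ValueError("two-step imputation supports only the {b,c} pattern")
        n_coarsened = int(coarsened.sum())

        ycols = _outcome_columns(dataset)
        design = np.c_[dataset.z.to_numpy(float), ycols]
        bc_obs = np.flatnonzero(base_codes >= 1)         # observed b or c
        coarse_rows = np.flatnonzero(coarsened)
        mis_rows = np.flatnonzero(fully_missing)
        if coarse_rows.size and bc_obs.size < 2:
            raise ValueError("step-1 subset too small to fit")

        completed, incompat = [], []
        for _ in range(self.m):
            chain = np.random.default_rng(rng.integers(2 ** 63))
            codes = base_codes.copy()
            if coarse_rows.size:
                # binary target within the subset: 0 = b, 1 = c
                sub_rows = np.r_[bc_obs, coarse_rows]
                tgt = np.r_[base_codes[bc_obs] - 1, np.full(len(coarse_rows), -1)]
                drawn = logreg_impute_step(tgt, design[sub_rows], chain)
                codes[coarse_rows] = drawn + 1
            if mis_rows.size:
                tgt = codes.copy()
                tgt[mis_rows] = -1
                codes[mis_rows] = polyreg_impute_step(tgt, design, chain,
                                                      n_categories=K)
            completed.append(_completed_frame(dataset, codes))
            incompat.append(int((codes[coarse_rows] == 0).sum()))

        self.result_ = ImputationResult(completed=completed,
                                        incompatible_counts=incompat,
                                        n_coarsened=n_coarsened,
                                        n_imputed=len(coarse_rows) + len(mis_rows))
        return self

    def transform(self, X=None) -> list:
        if not hasattr(self, "result_"):
            raise RuntimeError("imputer is not fitted")
        return self.result_.completed

    def fit_transform(self, X: AnalysisDataset, y=None) -> list:
        return self.fit(X).transform()


def mice_run(dataset: AnalysisDataset, variant: str = "mice_naive", m: int = 5,
             n_cycles: int = 10, random_state=None) -> ImputationResult:
    """Functional wrapper over :class:`MiceImputer` / :class:`TwoStepImputer`."""
    if variant == "mice_2step":
        return two_step_impute(dataset, m=m, random_state=random_state)
    imp = MiceImputer(variant=variant, m=m, n_cycles=n_cycles,
                      random_state=random_state)
    return imp.fit(dataset).result_


def two_step_impute(dataset: AnalysisDataset, m: int = 5,
                    random_state=None) -> ImputationResult:
    imp = TwoStepImputer(m=m, random_state=random_state)
    return imp.fit(dataset).result_
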