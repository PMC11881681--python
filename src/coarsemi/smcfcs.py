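"""Substantive-model-compatible FCS imputation for a categorical covariate.

The imputation density for the covariate X given everything else is

    f(X | Z, Y)  proportional to  f(Y | X, Z; psi) * f(X | Z; phi)

so a candidate label's weight is the product of its covariate-model
probability (multinomial logistic on Z) and the substantive-model likelihood
of the observed outcome under that label.  Because X is discrete the draw is
a direct multinomial draw over the normalized weights.

The coarsening-compatible variant (restrict=True) zeroes the weight of every
label outside the observation's coarse subset before normalizing, and starts
each chain from observed values compatible with the subset — imputations can
then never contradict the coarsening information.  With restrict=False the
subset is ignored (every non-singleton row is treated as completely missing),
which is the standard algorithm and serves as the naive comparator.

Parameter uncertainty is propagated by approximate posterior draws:
maximum likelihood plus a multivariate-normal perturbation with the inverse
observed information (and a scaled inverse-chi-square draw for the residual
variance of the linear substantive model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .coarse import AnalysisDataset, CoarseValue, SampleSpace, encode_observed
from .cox import CoxError, breslow_cumhaz, fit_cox

__all__ = [
    "SeparationError",
    "CovariateModelParams",
    "SubstantiveParams",
    "ImputationResult",
    "SmcfcsImputer",
    "candidate_weights",
    "draw_covariate_params",
    "draw_substantive_params",
    "smcfcs_impute",
]


class SeparationError(RuntimeError):
    """A model fit failed (separation, degeneracy or non-convergence)."""


@dataclass
class CovariateModelParams:
    """Multinomial-logistic coefficients of f(X | Z).

    One row per non-reference category (reference = first sample-space
    label), one column per conditioning covariate including the intercept.
    """

    phi: np.ndarray  # (K-1, 1+q)
    labels: tuple

    def category_probs(self, z_design: np.ndarray) -> np.ndarray:
        """(n, K) probabilities from the logit rows (reference logit 0)."""
        logits = np.c_[np.zeros(len(z_design)), z_design @ self.phi.T]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class SubstantiveParams:
    """A draw of the outcome-model parameters.

    Continuous: intercept + category effects + covariate effects and the
    residual variance.  Survival: log hazard ratios plus the Breslow baseline
    cumulative hazard evaluated (at the drawn coefficients) at every
    subject's own time.
    """

    kind: str
    beta: np.ndarray                     # continuous: (1+K-1+q,), survival: (K-1+q,)
    sigma2: float | None = None
    cumhaz: np.ndarray | None = None     # (n,) H0(T_i), survival only


@dataclass
class ImputationResult:
    """m completed datasets plus per-draw compatibility diagnostics."""

    completed: list                      # list of pandas DataFrames
    incompatible_counts: list            # per dataset: imputed labels outside subset
    n_coarsened: int
    n_imputed: int = 0                   # rows the method had to impute
    trace: pd.DataFrame | None = None    # per (chain, iteration) parameter summary
    failures: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.completed)


def candidate_weights(prior, likelihood, compatible=None) -> np.ndarray:
    """Normalized imputation probabilities over the sample space.

    ``prior`` are covariate-model probabilities P(X = k | Z), ``likelihood``
    the substantive-model factors f(Y | X = k, Z) (any common factor cancels),
    and ``compatible`` an optional boolean mask; weights of incompatible
    labels are set to zero before normalization.  Raises if every weight is
    zero after restriction.
    """
    w = np.asarray(prior, dtype=float) * np.asarray(likelihood, dtype=float)
    if compatible is not None:
        w = np.where(np.asarray(compatible, dtype=bool), w, 0.0)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all candidate weights vanish (underflow or impossible subset)")
    return w / total


def _check_mnlogit(res, max_coef: float = 30.0):
    params = np.asarray(res.params)
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("multinomial fit did not converge")
    if not np.all(np.isfinite(params)) or np.abs(params).max() > max_coef:
        raise SeparationError("multinomial fit diverged (separation)")
    cov = np.asarray(res.cov_params())
    if not np.all(np.isfinite(cov)):
        raise SeparationError("singular information in multinomial fit")
    return params, cov


def draw_covariate_params(x_codes: np.ndarray, z_design: np.ndarray,
                          rng: np.random.Generator, labels: tuple
                          ) -> CovariateModelParams:
    """Approximate posterior draw of the multinomial-logistic coefficients.

    Fits by maximum likelihood and perturbs with a multivariate normal using
    the inverse observed information.  ``x_codes`` must be fully imputed
    (current completed values); ``z_design`` includes the intercept column.
    """
    K = len(labels)
    counts = np.bincount(x_codes, minlength=K)
    if (counts == 0).any():
        raise SeparationError(f"degenerate multinomial: category counts {counts}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(x_codes, z_design).fit(disp=0, maxiter=100)
        except Exception as e:  # LinAlgError, PerfectSeparationError, ...
            raise SeparationError(f"multinomial fit failed: {e}") from e
    params, cov = _check_mnlogit(res)
    flat = params.ravel(order="F")  # (K-1)*(1+q), category-major
    draw = rng.multivariate_normal(flat, cov, method="cholesky")
    phi = draw.reshape(K - 1, z_design.shape[1])
    return CovariateModelParams(phi=phi, labels=labels)


def draw_substantive_params(x_codes: np.ndarray, dataset: AnalysisDataset,
                            rng: np.random.Generator) -> SubstantiveParams:
    """Approximate posterior draw of the substantive-model parameters.

    Continuous outcome: sigma^2 from its scaled inverse-chi-square
    conditional, then beta | sigma^2 ~ N(OLS estimate, sigma^2 (X'X)^-1).
    Survival outcome: beta ~ N(Cox MLE, inverse information), with the
    Breslow baseline cumulative hazard re-evaluated at the drawn beta.
    """
    K = len(dataset.space)
    dummies = np.eye(K)[x_codes][:, 1:]  # reference = first label
    zmat = dataset.z.to_numpy(float)
    if dataset.outcome_kind == "continuous":
        X = np.c_[np.ones(dataset.n), dummies, zmat]
        y = dataset.y
        beta_hat, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise SeparationError("singular design in substantive model")
        resid = y - X @ beta_hat
        df = dataset.n - X.shape[1]
        sse = resid @ resid
        sigma2 = sse / rng.chisquare(df)
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = rng.multivariate_normal(beta_hat, sigma2 * XtX_inv, method="cholesky")
        return SubstantiveParams(kind="continuous", beta=beta, sigma2=sigma2)
    X = np.c_[dummies, zmat]
    try:
        fit = fit_cox(X, dataset.time, dataset.status)
    except CoxError as e:
        raise SeparationError(f"Cox fit failed: {e}") from e
    beta = rng.multivariate_normal(fit.coef, fit.cov, method="cholesky")
    cumhaz = breslow_cumhaz(fit, dataset.time, beta=beta)
    return SubstantiveParams(kind="survival", beta=beta, cumhaz=cumhaz)


def _outcome_loglik(dataset: AnalysisDataset, psi: SubstantiveParams,
                    rows: np.ndarray) -> np.ndarray:
    """(len(rows), K) log f(Y_i | X = k, Z_i) up to row-constant terms."""
    K = len(dataset.space)
    zmat = dataset.z.to_numpy(float)[rows]
    if psi.kind == "continuous":
        b0 = psi.beta[0]
        bx = np.r_[0.0, psi.beta[1:K]]          # effect per label
        bz = psi.beta[K:]
        mu = b0 + zmat @ bz
        resid = dataset.y[rows, None] - (mu[:, None] + bx[None, :])
        return -0.5 * resid ** 2 / psi.sigma2
    bx = np.r_[0.0, psi.beta[:K - 1]]
    bz = psi.beta[K - 1:]
    lp = (zmat @ bz)[:, None] + bx[None, :]
    d = dataset.status[rows, None]
    H = psi.cumhaz[rows, None]
    return d * lp - H * np.exp(lp)


class SmcfcsImputer(BaseEstimator):
    """Substantive-model-compatible FCS imputer for one coarsened categorical
    covariate.

    Parameters
    ----------
    m : number of imputed datasets (independent chains).
    n_iter : iterations per chain; all but the last are burn-in.
    restrict : when True (the coarsening-compatible variant) candidate labels
        outside an observation's coarse subset get probability zero and the
        chain is initialized from compatible observed values only.  When
        False the standard algorithm runs, ignoring the subsets.
    c_predictor : None, "na" or "full_set".  When set, the coarsening column
        C (in the given dialect) is added as a categorical predictor to the
        covariate model.  With coarsened data this induces complete
        separation between X and C; fits then fail and the failure is
        recorded per chain rather than raised.
    random_state : seed or Generator.

    Attributes
    ----------
    result_ : ImputationResult with the completed datasets, per-dataset
        incompatible-imputation counts, a per-iteration trace and any
        recorded chain failures.
    """

    def __init__(self, m: int = 5, n_iter: int = 20, restrict: bool = True,
                 c_predictor: str | None = None, random_state=None):
        self.m = m
        self.n_iter = n_iter
        self.restrict = restrict
        self.c_predictor = c_predictor
        self.random_state = random_state

    # -- internals -----------------------------------------------------------

    def _z_design(self, dataset: AnalysisDataset) -> np.ndarray:
        cols = [np.ones(dataset.n), dataset.z.to_numpy(float)]
        if self.c_predictor is not None:
            enc = encode_observed(dataset.x, c_dialect=self.c_predictor)
            c = pd.Series(enc.c_col, dtype=object)
            dummies = pd.get_dummies(c, drop_first=True, dummy_na=(self.c_predictor == "na"))
            cols.append(dummies.to_numpy(float))
        return np.column_stack(cols)

    def _initial_codes(self, dataset: AnalysisDataset, impute_rows: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
        codes = dataset.singleton_codes().copy()
        pool = codes[dataset.directly_observed]
        if len(pool) == 0:
            raise ValueError("no directly observed values to initialize from")
        mask = dataset.subset_mask()
        for i in impute_rows:
            p = pool[mask[i, pool]] if self.restrict else pool
            if len(p) == 0:
                raise ValueError(f"no observed value compatible with row {i}")
            codes[i] = p[rng.integers(len(p))]
        return codes

    def _completed_frame(self, dataset: AnalysisDataset, codes: np.ndarray
                         ) -> pd.DataFrame:
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

    # -- API -----------------------------------------------------------------

    def fit(self, X: AnalysisDataset, y=None) -> "SmcfcsImputer":
        dataset = X
        if self.m < 1 or self.n_iter < 1:
            raise ValueError("m and n_iter must be >= 1")
        rng = np.random.default_rng(self.random_state)
        space = dataset.space
        K = len(space)
        z_design = self._z_design(dataset)
        mask = dataset.subset_mask()
        base_codes = dataset.singleton_codes()
        if self.restrict:
            # impute every non-singleton subset; singleton rows (directly
            # observed or identified through the coarse group) are fixed
            to_impute = np.flatnonzero(base_codes < 0)
        else:
            # the coarsening information is ignored: every row whose direct X
            # record is missing is treated as completely missing
            to_impute = np.flatnonzero(~dataset.directly_observed)
        coarsened = np.array([s.is_coarsened for s in dataset.x])
        n_coarsened = int(coarsened.sum())

        completed, incompat, trace_rows, failures = [], [], [], []
        weight_mask = mask if self.restrict else np.ones_like(mask)
        for chain in range(self.m):
            chain_rng = np.random.default_rng(rng.integers(2 ** 63))
            codes = self._initial_codes(dataset, to_impute, chain_rng)
            if len(to_impute) == 0:
                completed.append(self._completed_frame(dataset, codes))
                incompat.append(0)
                continue
            try:
                for it in range(self.n_iter):
                    psi = draw_substantive_params(codes, dataset, chain_rng)
                    phi = draw_covariate_params(codes, z_design, chain_rng,
                                                space.labels)
                    prior = phi.category_probs(z_design[to_impute])
                    loglik = _outcome_loglik(dataset, psi, to_impute)
                    logw = np.log(np.clip(prior, 1e-300, None)) + loglik
                    logw -= logw.max(axis=1, keepdims=True)
                    w = np.exp(logw) * weight_mask[to_impute]
                    totals = w.sum(axis=1)
                    if (totals <= 0).any() or not np.all(np.isfinite(totals)):
                        raise SeparationError("all candidate weights vanish for a row")
                    w /= totals[:, None]
                    u = chain_rng.uniform(size=len(to_impute))
                    codes[to_impute] = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
                    trace_rows.append({
                        "chain": chain, "iteration": it,
                        **{f"beta_{j}": b for j, b in enumerate(psi.beta)},
                    })
            except SeparationError as e:
                failures.append({"chain": chain, "error": str(e)})
                continue
            completed.append(self._completed_frame(dataset, codes))
            bad = (~mask[np.arange(dataset.n), codes]) & coarsened
            incompat.append(int(bad.sum()))

        self.result_ = ImputationResult(
            completed=completed, incompatible_counts=incompat,
            n_coarsened=n_coarsened, n_imputed=len(to_impute),
            trace=pd.DataFrame(trace_rows) if trace_rows else None,
            failures=failures,
        )
        return self

    def transform(self, X=None) -> list:
        """Return the m completed datasets from the preceding :meth:`fit`."""
        if not hasattr(self, "result_"):
            raise RuntimeError("imputer is not fitted")
        return self.result_.completed

    def fit_transform(self, X: AnalysisDataset, y=None) -> list:
        return self.fit(X).transform()


def smcfcs_impute(dataset: AnalysisDataset, m: int = 5, n_iter: int = 20,
                  restrict: bool = True, random_state=None) -> ImputationResult:
    """Functional wrapper over :class:`SmcfcsImputer`."""
    imp = SmcfcsImputer(m=m, n_iter=n_iter, restrict=restrict,
                        random_state=random_state)
    imp.fit(dataset)
    return imp.result_
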