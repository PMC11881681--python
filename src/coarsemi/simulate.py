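"""Synthetic data generation for the coarsened-covariate simulation study.

One replicate consists of a three-level categorical covariate X (obtained by
thresholding a latent standard normal), two continuous covariates Z1, Z2
(jointly trivariate normal with X's latent variable), an outcome that is
either linear-Gaussian or exponential-survival with uniform censoring, and a
multinomial-logistic coarsening/missingness mechanism acting on X: each row
draws an indicator R with

    P(R=0 | Z) = 1 / (1 + e^{g1'Z} + e^{g2'Z})        (completely missing)
    P(R=r | Z) = e^{gr'Z} / (1 + e^{g1'Z} + e^{g2'Z}),  r = 1 (observed),
                                                         r = 2 (coarsened)

with Z = (1, Z1, Z2).  Coarsening collapses b and c into the subset {b, c};
rows with X = a are exempt from coarsening (an R = 2 draw leaves them fully
observed), and R = 0 makes the row completely missing regardless of X.  The
intercepts g10, g20 are calibrated so that the marginal pattern probabilities
match requested targets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .coarse import AnalysisDataset, CoarseValue, SampleSpace

__all__ = [
    "LABELS",
    "ScenarioConfig",
    "TrueCoefficients",
    "GammaParams",
    "SimulatedReplicate",
    "gen_covariates",
    "discretize_x",
    "linear_predictor",
    "gen_outcome_continuous",
    "gen_outcome_survival",
    "calibrate_gamma_intercepts",
    "apply_coarsening",
    "simulate_replicate",
    "scenario_grid",
]

LABELS = ("a", "b", "c")
SPACE = SampleSpace(LABELS)


@dataclass(frozen=True)
class TrueCoefficients:
    """Coefficients of the data-generating substantive model.

    beta1, beta2 are the effects of X=b and X=c relative to a; beta3, beta4
    the effects of Z1 and Z2.  The intercept is 0 for the continuous outcome
    and log(0.1) for the survival outcome (baseline hazard rate 0.1).
    """

    beta0: float = 0.0
    beta1: float = 0.5
    beta2: float = 1.0
    beta3: float = 0.5
    beta4: float = 0.5

    @classmethod
    def defaults(cls, outcome_kind: str, effect_multiplier: float = 1.0
                 ) -> "TrueCoefficients":
        beta0 = math.log(0.1) if outcome_kind == "survival" else 0.0
        return cls(beta0=beta0, beta1=0.5 * effect_multiplier,
                   beta2=1.0 * effect_multiplier, beta3=0.5, beta4=0.5)

    def as_dict(self, outcome_kind: str) -> dict:
        d = {"x_b": self.beta1, "x_c": self.beta2, "z1": self.beta3, "z2": self.beta4}
        if outcome_kind == "continuous":
            d = {"intercept": self.beta0, **d}
        return d


@dataclass(frozen=True)
class GammaParams:
    """Coarsening-mechanism parameters: two logit rows over Z = (1, Z1, Z2).

    ``drop_missing`` marks the degenerate mechanism with P(R=0) identically
    zero, in which the missing category is removed and the choice between
    observed and coarsened is binary logistic (no finite intercept can set a
    softmax category to exactly zero).
    """

    g1: tuple  # (g10, g11, g12)
    g2: tuple  # (g20, g21, g22)
    drop_missing: bool = False

    def pattern_probs(self, z1, z2) -> np.ndarray:
        """(n, 3) matrix of P(R = 0, 1, 2 | Z)."""
        z1 = np.asarray(z1, dtype=float)
        z2 = np.asarray(z2, dtype=float)
        lp1 = self.g1[0] + self.g1[1] * z1 + self.g1[2] * z2
        lp2 = self.g2[0] + self.g2[1] * z1 + self.g2[2] * z2
        if self.drop_missing:
            logits = np.c_[np.full_like(lp1, -np.inf), lp1, lp2]
        else:
            logits = np.c_[np.zeros_like(lp1), lp1, lp2]
        shift = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - shift)
        return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial simulation design."""

    n_obs: int = 2000
    rho_xz1: float = 0.0
    rho_xz2: float = 0.0
    rho_z1z2: float = 0.0
    category_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    outcome_kind: str = "continuous"
    effect_multiplier: float = 1.0
    coarsen_probs: tuple = (0.2, 0.4, 0.4)  # (P(R=0), P(R=1), P(R=2))
    gamma_slopes: tuple = (1.0, 0.0, 0.0, 1.0)  # (g11, g12, g21, g22)
    n_sim: int = 165
    m: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if abs(sum(self.category_probs) - 1) > 1e-9 or min(self.category_probs) <= 0:
            raise ValueError("category_probs must be positive and sum to 1")
        if abs(sum(self.coarsen_probs) - 1) > 1e-9 or min(self.coarsen_probs) < 0:
            raise ValueError("coarsen_probs must be non-negative and sum to 1")

    @property
    def correlation_matrix(self) -> np.ndarray:
        return np.array([
            [1.0, self.rho_xz1, self.rho_xz2],
            [self.rho_xz1, 1.0, self.rho_z1z2],
            [self.rho_xz2, self.rho_z1z2, 1.0],
        ])

    @property
    def true_coefficients(self) -> TrueCoefficients:
        return TrueCoefficients.defaults(self.outcome_kind, self.effect_multiplier)


@dataclass
class SimulatedReplicate:
    """One simulated dataset, keeping the true labels for scoring."""

    dataset: AnalysisDataset
    x_true: np.ndarray      # true labels ('a'/'b'/'c')
    r: np.ndarray           # coarsening indicator codes (0 missing, 1 observed, 2 coarsened)
    config: ScenarioConfig


# -- covariates ---------------------------------------------------------------

def gen_covariates(config: ScenarioConfig, rng: np.random.Generator):
    """Draw (x_latent, z1, z2) from the trivariate normal with unit marginals."""
    C = config.correlation_matrix
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"correlation matrix not positive definite: {C}") from e
    draws = rng.standard_normal((config.n_obs, 3)) @ L.T
    return draws[:, 0], draws[:, 1], draws[:, 2]


def discretize_x(x_latent, category_probs) -> np.ndarray:
    """Threshold the latent normal into labels a/b/c.

    a iff x <= Phi^-1(pa); b iff Phi^-1(pa) < x <= Phi^-1(pa+pb); c otherwise
    (upper thresholds inclusive).
    """
    pa, pb, pc = category_probs
    t1 = stats.norm.ppf(pa)
    t2 = stats.norm.ppf(pa + pb)
    x_latent = np.asarray(x_latent, dtype=float)
    out = np.where(x_latent <= t1, "a", np.where(x_latent <= t2, "b", "c"))
    return out.astype(object)


# -- outcomes -----------------------------------------------------------------

def linear_predictor(labels, z1, z2, betas: TrueCoefficients) -> np.ndarray:
    """beta0 + beta1 1{X=b} + beta2 1{X=c} + beta3 Z1 + beta4 Z2."""
    labels = np.asarray(labels)
    return (betas.beta0
            + betas.beta1 * (labels == "b")
            + betas.beta2 * (labels == "c")
            + betas.beta3 * np.asarray(z1, dtype=float)
            + betas.beta4 * np.asarray(z2, dtype=float))


def gen_outcome_continuous(labels, z1, z2, betas: TrueCoefficients,
                           rng: np.random.Generator) -> np.ndarray:
    """Y = linear predictor + standard normal noise."""
    lp = linear_predictor(labels, z1, z2, betas)
    return lp + rng.standard_normal(len(lp))


def gen_outcome_survival(labels, z1, z2, betas: TrueCoefficients,
                         rng: np.random.Generator):
    """Exponential event time with rate exp(linear predictor), Unif(5, 10) censoring.

    Returns (time, status) with time = min(event, censoring) and status the
    event indicator.
    """
    lp = linear_predictor(labels, z1, z2, betas)
    t_event = rng.exponential(scale=1.0, size=len(lp)) / np.exp(lp)
    t_cens = rng.uniform(5.0, 10.0, size=len(lp))
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)
    return time, status


# -- coarsening mechanism -----------------------------------------------------

_CALIB_N = 1_000_000
_CALIB_SEED = 176_543  # fixed stream for intercept calibration draws


@lru_cache(maxsize=64)
def _calibrate_cached(targets: tuple, slopes: tuple, rho_z1z2: float,
                      tol: float) -> GammaParams:
    rng = np.random.default_rng(_CALIB_SEED)
    z = rng.standard_normal((_CALIB_N, 2))
    z2 = rho_z1z2 * z[:, 0] + math.sqrt(1 - rho_z1z2 ** 2) * z[:, 1]
    z1 = z[:, 0]
    g11, g12, g21, g22 = slopes
    s1 = g11 * z1 + g12 * z2
    s2 = g21 * z1 + g22 * z2
    t0, t1, t2 = targets

    if t0 == 0.0:
        # degenerate: drop the missing category, one binary intercept
        if slopes == (0.0, 0.0, 0.0, 0.0):
            d0 = math.log(t2 / t1)
        else:
            def resid(d):
                return np.mean(1.0 / (1.0 + np.exp(-(d + s2 - s1)))) - t2
            d0 = optimize.brentq(resid, -20, 20, xtol=1e-10)
        g = GammaParams(g1=(0.0, g11, g12), g2=(d0, g21, g22), drop_missing=True)
    else:
        # damped Newton on the Monte-Carlo expectations of (P1, P2)
        x = np.array([math.log(t1 / t0), math.log(t2 / t0)])  # slope-free closed form
        for _ in range(100):
            e1 = np.exp(x[0] + s1)
            e2 = np.exp(x[1] + s2)
            denom = 1.0 + e1 + e2
            p1 = e1 / denom
            p2 = e2 / denom
            r = np.array([p1.mean() - t1, p2.mean() - t2])
            if np.max(np.abs(r)) < 1e-10:
                break
            J = np.array([
                [np.mean(p1 * (1 - p1)), -np.mean(p1 * p2)],
                [-np.mean(p1 * p2), np.mean(p2 * (1 - p2))],
            ])
            step = np.linalg.solve(J, r)
            # damping: cap the step to keep the iteration stable
            x = x - np.clip(step, -2.0, 2.0)
        else:
            raise RuntimeError(f"intercept calibration did not converge for {targets}")
        g = GammaParams(g1=(x[0], g11, g12), g2=(x[1], g21, g22), drop_missing=False)

    achieved = g.pattern_probs(z1, z2).mean(axis=0)
    if np.max(np.abs(achieved - np.array(targets))) > tol:
        raise RuntimeError(
            f"calibration tolerance not met: achieved {achieved} for targets {targets}")
    return g


def calibrate_gamma_intercepts(target_probs, gamma_slopes=(1.0, 0.0, 0.0, 1.0),
                               rho_z1z2: float = 0.0, tol: float = 0.002) -> GammaParams:
    """Choose intercepts so the marginal pattern probabilities match targets.

    The expectation over (Z1, Z2) is evaluated on a fixed large Monte-Carlo
    sample (10^6 draws, dedicated seed) and the two intercepts are found by a
    damped Newton iteration; with a zero missing-probability target the
    mechanism degenerates to a binary logistic choice and a 1-d root find.
    """
    t = tuple(float(p) for p in target_probs)
    if abs(sum(t) - 1) > 1e-9 or min(t) < 0:
        raise ValueError("target probabilities must be non-negative and sum to 1")
    if t[1] == 0.0 or t[2] == 0.0:
        raise ValueError("observed and coarsened probabilities must be positive")
    return _calibrate_cached(t, tuple(float(s) for s in gamma_slopes),
                             float(rho_z1z2), float(tol))


def apply_coarsening(labels, z1, z2, gamma: GammaParams,
                     rng: np.random.Generator):
    """Draw the coarsening indicator and build the observed coarse values.

    Rows with R=0 become completely missing and R=2 coarsens b/c rows to the
    subset {b, c}.  Coarsening never applies to a: an a-row drawing R=2
    remains fully observed (its group-level value, "absent", identifies it
    exactly) and is recorded with indicator 1.  The observation process is
    therefore coarsening-at-random with respect to the subsets — the
    probability of each pattern is the same for every value inside the
    subset — but the *direct* X record is informatively missing for methods
    that discard the subsets: b/c rows lose their X record under R=2 while
    a rows never do.  Returns (x_obs, r) with r the realized indicator.
    """
    labels = np.asarray(labels)
    probs = gamma.pattern_probs(z1, z2)
    u = rng.uniform(size=len(labels))
    r = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    r = np.where((r == 2) & (labels == "a"), 1, r)
    bc = CoarseValue(("b", "c"), SPACE)
    full = CoarseValue(SPACE.labels, SPACE)
    x_obs = [full if ri == 0 else (bc if ri == 2 else CoarseValue((l,), SPACE))
             for l, ri in zip(labels, r)]
    return x_obs, r


def simulate_replicate(config: ScenarioConfig,
                       rng: np.random.Generator | int) -> SimulatedReplicate:
    """Generate one full replicate: covariates, outcome, coarsening."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x_latent, z1, z2 = gen_covariates(config, rng)
    labels = discretize_x(x_latent, config.category_probs)
    betas = config.true_coefficients
    gamma = calibrate_gamma_intercepts(config.coarsen_probs, config.gamma_slopes,
                                       config.rho_z1z2)
    if config.outcome_kind == "continuous":
        y = gen_outcome_continuous(labels, z1, z2, betas, rng)
        outcome = {"y": y}
    else:
        time, status = gen_outcome_survival(labels, z1, z2, betas, rng)
        outcome = {"time": time, "status": status}
    x_obs, r = apply_coarsening(labels, z1, z2, gamma, rng)
    import pandas as pd
    dataset = AnalysisDataset(x=x_obs, z=pd.DataFrame({"z1": z1, "z2": z2}),
                              outcome_kind=config.outcome_kind, r=r, **outcome)
    return SimulatedReplicate(dataset=dataset, x_true=labels, r=r, config=config)


# -- factorial design ---------------------------------------------------------

CORRELATION_SETS = tuple(
    (rx1, rx2, rz)
    for rx1 in (0.0, 0.7)
    for rx2 in (0.0, 0.3)
    for rz in (0.0, 0.7)
    if not (rx1 == 0.0 and rx2 == 0.3)  # excluded cells of the design
)

CATEGORY_PROB_SETS = {
    "uniform": (1 / 3, 1 / 3, 1 / 3),
    "bc_uniform": (1 / 2, 1 / 4, 1 / 4),
    "skewed": (1 / 2, 1 / 3, 1 / 6),
}

COARSEN_PROB_SETS = ((0.0, 0.4, 0.6), (0.2, 0.4, 0.4))


def scenario_grid(base_seed: int = 0, **overrides) -> list:
    """The full factorial design: 6 correlation sets x 3 category-frequency
    sets x 2 outcomes x 3 effect sizes x 2 coarsening strengths = 216 cells.
    """
    grid = []
    for i, (corr, (_, probs), outcome, mult, cprobs) in enumerate(
        itertools.product(
            CORRELATION_SETS,
            CATEGORY_PROB_SETS.items(),
            ("continuous", "survival"),
            (0.5, 1.0, 2.0),
            COARSEN_PROB_SETS,
        )
    ):
        grid.append(ScenarioConfig(
            rho_xz1=corr[0], rho_xz2=corr[1], rho_z1z2=corr[2],
            category_probs=probs, outcome_kind=outcome,
            effect_multiplier=mult, coarsen_probs=cprobs,
            seed=base_seed + i, **overrides,
        ))
    return grid
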