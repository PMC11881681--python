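"""SMC-FCS core: candidate weights, posterior draws, the sampler, and the
coarsening-compatibility guarantee."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from coarsemi.coarse import AnalysisDataset, CoarseValue, SampleSpace
from coarsemi.simulate import ScenarioConfig, simulate_replicate
from coarsemi.smcfcs import (SeparationError, SmcfcsImputer, candidate_weights,
                             draw_covariate_params, draw_substantive_params,
                             smcfcs_impute)

SPACE = SampleSpace(("a", "b", "c"))


def cv(*labels):
    return CoarseValue(labels, SPACE)


class TestCandidateWeights:
    def test_hand_normalization_full_space(self):
        w = candidate_weights([0.2, 0.3, 0.5], [1.0, 2.0, 1.0])
        np.testing.assert_allclose(w, [0.2 / 1.3, 0.6 / 1.3, 0.5 / 1.3],
                                   atol=1e-4)
        np.testing.assert_allclose(w, [0.1538, 0.4615, 0.3846], atol=1e-4)

    def test_hand_restriction_to_bc(self):
        w = candidate_weights([0.2, 0.3, 0.5], [1.0, 2.0, 1.0],
                              [False, True, True])
        np.testing.assert_allclose(w, [0.0, 0.5455, 0.4545], atol=1e-4)

    def test_singleton_forces_value(self):
        w = candidate_weights([0.2, 0.3, 0.5], [1.0, 2.0, 1.0],
                              [False, False, True])
        np.testing.assert_allclose(w, [0.0, 0.0, 1.0])

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            candidate_weights([0.5, 0.5, 0.0], [1.0, 1.0, 1.0],
                              [False, False, True])

    @given(prior=st.lists(st.floats(0.01, 10), min_size=3, max_size=3),
           lik=st.lists(st.floats(0.01, 10), min_size=3, max_size=3),
           mask=st.lists(st.booleans(), min_size=3, max_size=3))
    def test_normalized_and_supported_on_compatible_labels(self, prior, lik,
                                                           mask):
        if not any(mask):
            mask = [True, True, True]
        w = candidate_weights(prior, lik, mask)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w[~np.array(mask)] == 0)
        assert np.all(w >= 0)

    @given(prior=st.lists(st.floats(0.01, 10), min_size=3, max_size=3),
           lik=st.lists(st.floats(0.01, 10), min_size=3, max_size=3),
           mask=st.lists(st.booleans(), min_size=3, max_size=3))
    def test_restriction_equals_conditioning(self, prior, lik, mask):
        """Zero-then-renormalize equals the Bayes conditional of the
        unrestricted vector given membership of the subset."""
        if not any(mask):
            mask = [True, True, True]
        mask = np.array(mask)
        unres = candidate_weights(prior, lik)
        if unres[mask].sum() == 0:
            return
        conditional = np.where(mask, unres, 0) / unres[mask].sum()
        restricted = candidate_weights(prior, lik, mask)
        np.testing.assert_allclose(restricted, conditional, atol=1e-12)

    def test_rejection_sampling_equivalence(self, rng):
        """Drawing unrestricted and rejecting outside S reproduces the
        restricted distribution (chi-square goodness of fit, 1e5 draws)."""
        prior = np.array([0.25, 0.35, 0.40])
        lik = np.array([1.3, 0.7, 2.1])
        mask = np.array([False, True, True])
        restricted = candidate_weights(prior, lik, mask)
        unres = candidate_weights(prior, lik)
        n = 100_000
        draws = rng.choice(3, size=3 * n, p=unres)
        accepted = draws[mask[draws]][:n]
        counts = np.bincount(accepted, minlength=3)
        expected = restricted * len(accepted)
        chi2 = ((counts[1:] - expected[1:]) ** 2 / expected[1:]).sum()
        assert counts[0] == 0
        assert chi2 < stats.chi2.ppf(0.999, df=1)


class TestParameterDraws:
    def test_covariate_draw_matches_closed_form_log_odds(self, rng):
        # X independent of Z: drawn intercepts ~ log(p_k / p_ref)
        n = 40_000
        p = np.array([0.5, 0.3, 0.2])
        x = rng.choice(3, size=n, p=p)
        z = np.c_[np.ones(n), rng.normal(size=n)]
        phi = draw_covariate_params(x, z, rng, SPACE.labels)
        np.testing.assert_allclose(phi.phi[:, 0],
                                   np.log(p[1:] / p[0]), atol=0.1)
        np.testing.assert_allclose(phi.phi[:, 1], 0.0, atol=0.1)

    def test_degenerate_single_category_raises(self, rng):
        z = np.ones((50, 1))
        with pytest.raises(SeparationError):
            draw_covariate_params(np.zeros(50, dtype=int), z, rng,
                                  SPACE.labels)

    def test_draws_reproducible_under_fixed_seed(self, small_dataset):
        codes = np.array([0, 1, 2, 1, 2, 0, 0, 1, 2, 1])
        z = np.c_[np.ones(10), small_dataset.z.to_numpy()]
        a = draw_covariate_params(codes, z, np.random.default_rng(3),
                                  SPACE.labels)
        b = draw_covariate_params(codes, z, np.random.default_rng(3),
                                  SPACE.labels)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_substantive_draw_recovers_truth_large_n(self, rng):
        n = 30_000
        x = rng.choice(3, size=n)
        z = pd.DataFrame({"z1": rng.normal(size=n), "z2": rng.normal(size=n)})
        labels = np.array(["a", "b", "c"], dtype=object)[x]
        y = (0.5 * (x == 1) + 1.0 * (x == 2) + 0.5 * z["z1"] + 0.5 * z["z2"]
             + rng.standard_normal(n))
        ds = AnalysisDataset(x=[cv(l) for l in labels], z=z,
                             outcome_kind="continuous", y=y.to_numpy())
        psi = draw_substantive_params(x, ds, rng)
        np.testing.assert_allclose(psi.beta, [0.0, 0.5, 1.0, 0.5, 0.5],
                                   atol=0.05)
        assert psi.sigma2 == pytest.approx(1.0, abs=0.05)

    def test_all_censored_survival_raises(self, rng):
        n = 30
        z = pd.DataFrame({"z1": rng.normal(size=n)})
        x = rng.choice(3, size=n)
        labels = np.array(["a", "b", "c"], dtype=object)[x]
        ds = AnalysisDataset(x=[cv(l) for l in labels], z=z,
                             outcome_kind="survival",
                             time=np.ones(n), status=np.zeros(n, dtype=int))
        with pytest.raises(SeparationError):
            draw_substantive_params(x, ds, rng)


def _coarse_replicate(outcome_kind="continuous", seed=11, n=400):
    cfg = ScenarioConfig(n_obs=n, rho_xz1=0.7, rho_xz2=0.3,
                         coarsen_probs=(0.2, 0.4, 0.4),
                         outcome_kind=outcome_kind)
    return simulate_replicate(cfg, seed).dataset


class TestSmcfcsImputer:
    def test_restricted_never_imputes_outside_subset(self):
        ds = _coarse_replicate()
        res = smcfcs_impute(ds, m=3, n_iter=5, restrict=True, random_state=0)
        assert res.incompatible_counts == [0, 0, 0]
        mask = ds.subset_mask()
        labels = list(ds.space.labels)
        for df in res.completed:
            codes = np.array([labels.index(v) for v in df["x"]])
            assert mask[np.arange(ds.n), codes].all()

    def test_unrestricted_produces_incompatible_imputations(self):
        ds = _coarse_replicate()
        res = smcfcs_impute(ds, m=3, n_iter=5, restrict=False, random_state=0)
        assert sum(res.incompatible_counts) > 0

    def test_nothing_to_impute_returns_input(self, rng):
        n = 60
        x = rng.choice(3, size=n)
        labels = np.array(["a", "b", "c"], dtype=object)[x]
        ds = AnalysisDataset(
            x=[cv(l) for l in labels],
            z=pd.DataFrame({"z1": rng.normal(size=n)}),
            outcome_kind="continuous", y=rng.normal(size=n))
        res = smcfcs_impute(ds, m=2, n_iter=3, random_state=0)
        for df in res.completed:
            assert list(df["x"]) == list(labels)

    def test_determinism(self):
        ds = _coarse_replicate(n=200)
        a = smcfcs_impute(ds, m=2, n_iter=3, random_state=42)
        b = smcfcs_impute(ds, m=2, n_iter=3, random_state=42)
        for da, db in zip(a.completed, b.completed):
            pd.testing.assert_frame_equal(da, db)

    def test_survival_outcome_runs_and_respects_subsets(self):
        ds = _coarse_replicate("survival", seed=13)
        res = smcfcs_impute(ds, m=2, n_iter=5, restrict=True, random_state=1)
        assert res.incompatible_counts == [0, 0]

    def test_trace_exposes_chain_iterations(self):
        ds = _coarse_replicate(n=200)
        imp = SmcfcsImputer(m=2, n_iter=4, random_state=0).fit(ds)
        t = imp.result_.trace
        assert set(t["chain"]) == {0, 1}
        assert t.groupby("chain")["iteration"].max().eq(3).all()

    def test_sklearn_param_interface(self):
        imp = SmcfcsImputer(m=7, restrict=False)
        assert imp.get_params()["m"] == 7
        imp.set_params(restrict=True)
        assert imp.restrict

    def test_c_as_predictor_records_separation_failures(self):
        """Putting the coarsening column into the covariate model induces
        complete separation with X; fits fail and failures are recorded
        per chain instead of raised."""
        ds = _coarse_replicate(n=1000)
        imp = SmcfcsImputer(m=4, n_iter=10, restrict=False, c_predictor="na",
                            random_state=0).fit(ds)
        assert len(imp.result_.failures) > 0
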