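import numpy as np
import pytest

from mbfd import EffectParameters, VarianceComponents, build_standard_design, randomize, simulate_trial
from mbfd.lmm import ModelSpec, RandomInterceptLMM, design_matrix, fit_reml

from conftest import ADDITIVE, INTERACTION, make_trial
import oracles


class TestModelSpec:
    def test_column_counts(self):
        assert ModelSpec(1).n_params == 4
        assert ModelSpec(2).n_params == 5
        assert ModelSpec(3).n_params == 5

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model_id"):
            ModelSpec(4)


class TestDesignMatrix:
    def test_row_coding(self, small_trial):
        for mid, cols in [(1, 4), (2, 5), (3, 5)]:
            X, y, g = design_matrix(small_trial, ModelSpec(mid))
            assert X.shape == (150, cols)
        data = small_trial.sort_values(["participant", "period"])
        X1, _, _ = design_matrix(small_trial, ModelSpec(1))
        X2, _, _ = design_matrix(small_trial, ModelSpec(2))
        X3, _, _ = design_matrix(small_trial, ModelSpec(3))
        ab = (data["condition"] == "AB").to_numpy()
        ctrl = (data["condition"] == "C").to_numpy()
        # additive model: combined phase sets both exposure indicators
        assert np.all(X1[ab][:, 2:] == 1.0)
        assert np.all(X1[ctrl][:, 2:] == 0.0)
        # interaction column is the product of the exposures
        assert np.allclose(X2[:, 4], X2[:, 2] * X2[:, 3])
        # multi-arm: AB rows activate only the combined indicator
        assert np.all(X3[ab][:, 2:] == [0.0, 0.0, 1.0])
        # intercept and period columns
        assert np.all(X1[:, 0] == 1.0)
        assert set(np.unique(X1[:, 1])) == {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_rows_grouped_by_participant(self, small_trial):
        shuffled = small_trial.sample(frac=1, random_state=0)
        _, _, g = design_matrix(shuffled, ModelSpec(1))
        changes = np.sum(g[1:] != g[:-1])
        assert changes == len(np.unique(g)) - 1


class TestRemlFit:
    def test_noise_free_interpolation(self, standard_design):
        alloc = randomize(standard_design, 30, seed=2)
        eff = EffectParameters(u=0.3, beta_t=1.0, beta_a=0.8, beta_b=0.6, beta_c=1.6)
        data = simulate_trial(
            standard_design, alloc, eff, VarianceComponents(tau=0.0, sigma=1e-10), 3
        )
        fit = fit_reml(data, ModelSpec(3))
        expected = [0.3, 1.0, 0.8, 0.6, 1.6]
        assert np.allclose(fit.coef, expected, atol=1e-7)
        assert fit.sigma2 < 1e-12

    @pytest.mark.parametrize("model_id,sl", [(1, slice(0, 7)), (2, slice(7, 14)),
                                             (3, slice(14, 20))])
    def test_matches_brute_force_oracle(self, trial_batch, model_id, sl):
        """Profiled REML agrees with generic restricted-likelihood maximization.

        Twenty fixed-seed datasets spanning ICC 0 to 0.30 and all effect
        patterns, split across the three mean models; log-likelihood to 1e-6
        and coefficients to 1e-6.
        """
        spec = ModelSpec(model_id)
        for data in trial_batch[sl]:
            X, y, g = design_matrix(data, spec)
            est = RandomInterceptLMM().fit(X, y, g)
            ref = oracles.brute_force_reml(X, y, g)
            assert abs(est.loglik_ - ref["loglik"]) < 1e-6
            assert np.max(np.abs(est.coef_ - ref["beta"])) < 1e-6

    @pytest.mark.parametrize("seed", [200, 204, 209])
    def test_boundary_equals_ols(self, standard_design, seed):
        """ICC-0 draws whose REML solution hits the tau2 = 0 boundary: the
        GLS fit must collapse to ordinary least squares exactly."""
        data = make_trial(seed, n=30, icc=0.0)
        X, y, g = design_matrix(data, ModelSpec(1))
        est = RandomInterceptLMM().fit(X, y, g)
        assert est.tau2_ == 0.0  # these draws sit on the boundary
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(est.coef_ - ols)) < 1e-6

    def test_statsmodels_cross_check(self):
        """Secondary oracle: statsmodels MixedLM (REML) on a high-ICC trial
        (agreement limited by that optimizer's own tolerance)."""
        MixedLM = pytest.importorskip(
            "statsmodels.regression.mixed_linear_model"
        ).MixedLM
        data = make_trial(99, n=60, icc=0.30)
        X, y, g = design_matrix(data, ModelSpec(3))
        est = RandomInterceptLMM().fit(X, y, g)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = MixedLM(y, X, groups=g).fit(reml=True)
        assert np.max(np.abs(est.coef_ - sm_fit.fe_params)) < 1e-4
        assert est.sigma2_ == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_participant_permutation_invariance(self, small_trial):
        fit1 = fit_reml(small_trial, ModelSpec(2))
        shuffled = small_trial.sample(frac=1, random_state=1)
        # relabel participants in shuffled order to change block order
        fit2 = fit_reml(shuffled, ModelSpec(2))
        assert np.allclose(fit1.coef, fit2.coef, atol=1e-10)
        assert np.allclose(fit1.vcov, fit2.vcov, atol=1e-10)
        assert np.allclose(fit1.df, fit2.df, atol=1e-6)

    def test_rank_deficiency_reported(self, small_trial):
        data = small_trial.copy()
        data["x_b"] = data["x_a"]  # collinear exposures
        with pytest.raises(ValueError, match="rank deficient"):
            fit_reml(data, ModelSpec(1))

    def test_estimates_unbiased_over_replicates(self):
        """Mean multi-arm estimates track the generating coefficients."""
        ests = []
        for k in range(60):
            data = make_trial(3000 + k, n=60, icc=0.10, effects=INTERACTION)
            ests.append(fit_reml(data, ModelSpec(3)).coef)
        mean = np.mean(ests, axis=0)
        se = np.std(ests, axis=0, ddof=1) / np.sqrt(len(ests))
        truth = np.array([0.0, 1.0, 0.8, 0.8, 2.0])
        assert np.all(np.abs(mean - truth) < 3 * se + 1e-8)


class TestSatterthwaite:
    def test_matches_richardson_oracle(self, trial_batch):
        """Satterthwaite df within 2% of the dense-matrix numerical oracle."""
        spec = ModelSpec(1)
        checked = 0
        for data in trial_batch[:8]:
            X, y, g = design_matrix(data, spec)
            est = RandomInterceptLMM().fit(X, y, g)
            if est.tau2_ < 1e-6:  # boundary handled by its own test
                continue
            for k in (2, 3):
                c = np.eye(4)[k]
                df = est.satterthwaite_df(c)
                ref = oracles.satterthwaite_oracle(
                    X, y, g, est.tau2_, est.sigma2_, c
                )
                assert df == pytest.approx(min(ref, est.n_obs_ - 4), rel=0.02)
                checked += 1
        assert checked >= 6

    def test_boundary_df_is_residual_df(self, standard_design):
        alloc = randomize(standard_design, 20, seed=4)
        rng = np.random.default_rng(8)
        data = simulate_trial(
            standard_design, alloc, EffectParameters(beta_t=1.0),
            VarianceComponents(tau=0.0, sigma=1.0), rng,
        )
        X, y, g = design_matrix(data, ModelSpec(1))
        est = RandomInterceptLMM().fit(X, y, g)
        if est.tau2_ < 1e-10:
            assert est.satterthwaite_df(np.eye(4)[2]) == pytest.approx(100 - 4)

    def test_df_grows_with_sample_size(self):
        dfs = []
        for n in (30, 120):
            data = make_trial(55, n=n, icc=0.10)
            X, y, g = design_matrix(data, ModelSpec(1))
            est = RandomInterceptLMM().fit(X, y, g)
            dfs.append(est.satterthwaite_df(np.eye(4)[2]))
        assert dfs[1] > dfs[0]
        assert 1 <= dfs[0] <= 30 * 5 - 4


class TestFitResult:
    def test_summary_and_json(self, small_trial):
        fit = fit_reml(small_trial, ModelSpec(1))
        frame = fit.summary_frame()
        assert list(frame.index) == ["intercept", "period", "beta_a", "beta_b"]
        assert (frame["p"].between(0, 1)).all()
        import json

        payload = json.loads(fit.to_json())
        assert payload["estimator"] == "LMM"
        assert payload["converged"] is True
        assert len(payload["coef"]) == 4

    def test_vcov_symmetric_psd(self, small_trial):
        fit = fit_reml(small_trial, ModelSpec(3))
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert np.all(np.linalg.eigvalsh(fit.vcov) > 0)
        assert np.all(fit.df > 0)
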