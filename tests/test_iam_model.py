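"""Unit and oracle tests for the independent-annotator conditionals."""

import numpy as np
import pytest
from scipy import stats

from conftest import grid_normalize
from vitalfuse.errors import ConfigurationError, DimensionError
from vitalfuse.iam_model import (
    AnnotationSet,
    FeatureMatrix,
    IAMHyperparams,
    IAMState,
    alpha_phi_conditional,
    b_conditional,
    lambda_conditional,
    phi_conditional,
    sample_alpha_phi,
    sample_b,
    sample_lambda,
    sample_phi,
    sample_z,
    update_w,
    z_conditional,
)


def make_state(z, phi, lam, b=1.0, alpha_phi=1.0, w=(0.0,)):
    return IAMState(
        z=np.asarray(z, float), phi=np.asarray(phi, float),
        lam=np.asarray(lam, float), b=b, alpha_phi=alpha_phi,
        w=np.asarray(w, float),
    )


class TestAnnotationSet:
    def test_derived_counts_are_consistent(self):
        labels = np.array([[1.0, np.nan, 3.0], [np.nan, 2.0, 4.0]])
        mask = ~np.isnan(labels)
        data = AnnotationSet(labels=labels, mask=mask)
        assert data.labels_per_annotator.tolist() == [1, 1, 2]
        assert data.labels_per_sample.tolist() == [2, 2]
        assert data.labels_per_annotator.sum() == mask.sum()

    def test_nonfinite_observed_label_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSet(labels=np.array([[np.inf]]), mask=np.array([[True]]))

    def test_masked_sentinels_are_ignored(self):
        data = AnnotationSet(
            labels=np.array([[1.0, np.nan]]), mask=np.array([[True, False]])
        )
        assert data.observed_or(0.0).tolist() == [[1.0, 0.0]]


class TestZConditional:
    def test_no_observations_reverts_to_prior(self):
        # V_i empty, b=1, x'w=10 -> N(10, 1)
        data = AnnotationSet(labels=np.array([[np.nan]]), mask=np.array([[False]]))
        state = make_state([0.0], [0.0], [1.0], b=1.0, w=[10.0])
        X = FeatureMatrix.from_features(None, 1)
        mean, prec = z_conditional(state, data, X)
        assert mean[0] == pytest.approx(10.0)
        assert prec[0] == pytest.approx(1.0)

    def test_hand_worked_posterior_parameters(self):
        # b=1, x'w=10, one label y=14 from annotator phi=0, lam=4:
        # precision 5, mean (10 + 4*14)/5 = 13.2
        data = AnnotationSet(labels=np.array([[14.0]]), mask=np.array([[True]]))
        state = make_state([0.0], [0.0], [4.0], b=1.0, w=[10.0])
        X = FeatureMatrix.from_features(None, 1)
        mean, prec = z_conditional(state, data, X)
        assert prec[0] == pytest.approx(5.0)
        assert mean[0] == pytest.approx(13.2)

    def test_dominating_annotator_precision_pins_mean_to_label(self):
        data = AnnotationSet(labels=np.array([[14.0]]), mask=np.array([[True]]))
        state = make_state([0.0], [0.0], [1e8], b=1.0, w=[10.0])
        X = FeatureMatrix.from_features(None, 1)
        mean, _ = z_conditional(state, data, X)
        assert abs(mean[0] - 14.0) < 1e-3

    def test_precision_bookkeeping_exact(self, tiny_instance):
        data, X, state, _ = tiny_instance
        _, prec = z_conditional(state, data, X)
        expected = state.b + data.mask @ state.lam
        assert np.array_equal(prec, expected)

    def test_dimension_mismatch_raises(self, tiny_instance):
        data, X, state, _ = tiny_instance
        bad = make_state([1.0, 2.0], state.phi, state.lam, w=[0.0])
        with pytest.raises(DimensionError):
            z_conditional(bad, data, X)


class TestPhiConditional:
    def test_unused_annotator_reverts_to_prior(self):
        data = AnnotationSet(
            labels=np.array([[5.0, np.nan]]), mask=np.array([[True, False]])
        )
        state = make_state([5.0], [0.0, 0.0], [1.0, 1.0], alpha_phi=2.0)
        hyp = IAMHyperparams(mu_phi=0.5)
        mean, prec = phi_conditional(state, data, hyp)
        assert mean[1] == pytest.approx(0.5)
        assert prec[1] == pytest.approx(2.0)

    def test_hand_worked_update(self):
        # mu=0, alpha=1, lam=1, residuals {2, 4}: alpha*=3, mu*=6/3=2
        data = AnnotationSet(
            labels=np.array([[2.0], [4.0]]), mask=np.array([[True], [True]])
        )
        state = make_state([0.0, 0.0], [0.0], [1.0], alpha_phi=1.0)
        hyp = IAMHyperparams(mu_phi=0.0)
        mean, prec = phi_conditional(state, data, hyp)
        assert prec[0] == pytest.approx(3.0)
        assert mean[0] == pytest.approx(2.0)

    def test_label_shift_moves_mean_linearly(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        c = 1.7
        mean0, _ = phi_conditional(state, data, hyp)
        shifted = AnnotationSet(
            labels=np.where(data.mask, data.labels + c, np.nan), mask=data.mask
        )
        mean1, _ = phi_conditional(state, shifted, hyp)
        n_j = data.labels_per_annotator
        gain = n_j * state.lam * c / (state.alpha_phi + n_j * state.lam)
        np.testing.assert_allclose(mean1 - mean0, gain, rtol=1e-12)


class TestGammaConditionals:
    def test_lambda_prior_reversion_and_hand_update(self):
        # annotator 2 has no labels; annotator 1 residuals {1, -1} with
        # k=2, theta=1 -> shape 3, rate 2
        data = AnnotationSet(
            labels=np.array([[1.0, np.nan], [-1.0, np.nan]]),
            mask=np.array([[True, False], [True, False]]),
        )
        state = make_state([0.0, 0.0], [0.0, 0.0], [1.0, 1.0])
        hyp = IAMHyperparams(k_lambda=2.0, theta_lambda=1.0)
        shape, rate = lambda_conditional(state, data, hyp)
        assert shape.tolist() == [3.0, 2.0]
        assert rate[0] == pytest.approx(2.0)       # scale 0.5
        assert rate[1] == pytest.approx(1.0)       # prior scale exactly

    def test_lambda_zero_residuals_keep_prior_scale(self):
        z = np.arange(10.0)
        data = AnnotationSet(labels=z[:, None], mask=np.ones((10, 1), bool))
        state = make_state(z, [0.0], [1.0])
        hyp = IAMHyperparams(k_lambda=2.0, theta_lambda=0.25)
        shape, rate = lambda_conditional(state, data, hyp)
        assert shape[0] == pytest.approx(2.0 + 5.0)
        assert rate[0] == pytest.approx(1.0 / 0.25)

    def test_alpha_phi_hand_update(self):
        # phi = {1, -1}, k=1, theta=1 -> shape 2, rate 2
        state = make_state([0.0], [1.0, -1.0], [1.0, 1.0])
        hyp = IAMHyperparams(k_alpha=1.0, theta_alpha=1.0)
        shape, rate = alpha_phi_conditional(state, hyp)
        assert shape == pytest.approx(2.0)
        assert rate == pytest.approx(2.0)

    def test_alpha_phi_equal_biases_keep_prior_scale(self):
        state = make_state([0.0], [0.7, 0.7, 0.7], [1.0, 1.0, 1.0])
        hyp = IAMHyperparams(k_alpha=1.5, theta_alpha=2.0)
        shape, rate = alpha_phi_conditional(state, hyp)
        assert shape == pytest.approx(1.5 + 1.5)
        assert rate == pytest.approx(0.5)

    def test_b_hand_update_and_mode_agreement(self):
        # z = {0, 2}, k_b=1, theta_b=2: zbar=1, SS=2, shape 2, rate 1.5
        X = FeatureMatrix.from_features(None, 2)
        state = make_state([0.0, 2.0], [0.0], [1.0], w=[1.0])
        hyp = IAMHyperparams(k_b=1.0, theta_b=2.0)
        shape, rate = b_conditional(state, X, hyp, "as_printed")
        assert shape == pytest.approx(2.0)
        assert rate == pytest.approx(1.5)
        # intercept-only X with w = [zbar]: modes coincide
        shape2, rate2 = b_conditional(state, X, hyp, "regression_residual")
        assert (shape2, rate2) == (shape, rate)

    def test_b_invalid_mode_rejected(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        with pytest.raises(ConfigurationError):
            b_conditional(state, X, hyp, "bogus")

    def test_draws_strictly_positive(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert np.all(sample_lambda(state, data, hyp, rng) > 0)
            assert sample_alpha_phi(state, hyp, rng) > 0
            assert sample_b(state, X, hyp, "as_printed", rng) > 0


class TestUpdateW:
    def test_intercept_only_returns_mean(self):
        X = FeatureMatrix.from_features(None, 3)
        w = update_w(np.array([1.0, 2.0, 6.0]), X)
        assert w == pytest.approx([3.0])

    def test_hand_solved_two_parameter_fit(self):
        X = FeatureMatrix.from_features(np.array([[0.0], [1.0], [2.0]]), 3)
        w = update_w(np.array([1.0, 3.0, 5.0]), X)
        np.testing.assert_allclose(w, [1.0, 2.0], atol=1e-12)

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(1)
        X = FeatureMatrix.from_features(rng.standard_normal((20, 3)), 20)
        w0 = np.array([0.5, -1.0, 2.0, 0.25])
        np.testing.assert_allclose(update_w(X.X @ w0, X), w0, atol=1e-10)

    def test_rank_deficient_design_warns_not_raises(self):
        feats = np.ones((5, 2))  # duplicated intercept
        X = FeatureMatrix.from_features(feats, 5)
        with pytest.warns(RuntimeWarning):
            w = update_w(np.arange(5.0), X)
        assert np.all(np.isfinite(w))


class TestGridOracles:
    """Analytic conditionals vs brute-force grid normalization of
    prior x likelihood on the fixed tiny instance."""

    GRID_N = 2001

    def test_z_conditional_density(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        mean, prec = z_conditional(state, data, X)
        i = 0
        grid = np.linspace(mean[i] - 6, mean[i] + 6, self.GRID_N)
        logd = stats.norm.logpdf(grid, X.X[i] @ state.w, 1 / np.sqrt(state.b))
        for j in np.flatnonzero(data.mask[i]):
            logd += stats.norm.logpdf(
                data.labels[i, j], grid + state.phi[j], 1 / np.sqrt(state.lam[j])
            )
        oracle = grid_normalize(logd, grid)
        analytic = stats.norm.pdf(grid, mean[i], 1 / np.sqrt(prec[i]))
        assert np.max(np.abs(oracle - analytic)) < 1e-3

    def test_phi_conditional_density(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        mean, prec = phi_conditional(state, data, hyp)
        j = 1
        grid = np.linspace(mean[j] - 6, mean[j] + 6, self.GRID_N)
        logd = stats.norm.logpdf(grid, hyp.mu_phi, 1 / np.sqrt(state.alpha_phi))
        for i in np.flatnonzero(data.mask[:, j]):
            logd += stats.norm.logpdf(
                data.labels[i, j], state.z[i] + grid, 1 / np.sqrt(state.lam[j])
            )
        oracle = grid_normalize(logd, grid)
        analytic = stats.norm.pdf(grid, mean[j], 1 / np.sqrt(prec[j]))
        assert np.max(np.abs(oracle - analytic)) < 1e-3

    def test_lambda_conditional_density(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        shape, rate = lambda_conditional(state, data, hyp)
        j = 0
        grid = np.linspace(1e-6, shape[j] / rate[j] * 8, self.GRID_N)
        logd = stats.gamma.logpdf(grid, hyp.k_lambda, scale=hyp.theta_lambda)
        for i in np.flatnonzero(data.mask[:, j]):
            logd += stats.norm.logpdf(
                data.labels[i, j],
                state.z[i] + state.phi[j],
                1 / np.sqrt(grid),
            )
        oracle = grid_normalize(logd, grid)
        analytic = stats.gamma.pdf(grid, shape[j], scale=1 / rate[j])
        assert np.max(np.abs(oracle - analytic)) < 1e-3

    def test_alpha_phi_conditional_density(self, tiny_instance):
        """Gridded against the phi-dispersion likelihood the update assumes
        (biases centred at their current mean)."""
        data, X, state, hyp = tiny_instance
        shape, rate = alpha_phi_conditional(state, hyp)
        grid = np.linspace(1e-6, shape / rate * 8, self.GRID_N)
        logd = stats.gamma.logpdf(grid, hyp.k_alpha, scale=hyp.theta_alpha)
        for ph in state.phi:
            logd += stats.norm.logpdf(ph, state.phi_bar, 1 / np.sqrt(grid))
        oracle = grid_normalize(logd, grid)
        analytic = stats.gamma.pdf(grid, shape, scale=1 / rate)
        assert np.max(np.abs(oracle - analytic)) < 1e-3

    def test_b_conditional_density(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        shape, rate = b_conditional(state, X, hyp, "as_printed")
        grid = np.linspace(1e-6, shape / rate * 8, self.GRID_N)
        logd = stats.gamma.logpdf(grid, hyp.k_b, scale=hyp.theta_b)
        for z_i in state.z:
            logd += stats.norm.logpdf(z_i, state.z_bar, 1 / np.sqrt(grid))
        oracle = grid_normalize(logd, grid)
        analytic = stats.gamma.pdf(grid, shape, scale=1 / rate)
        assert np.max(np.abs(oracle - analytic)) < 1e-3


class TestStructuralProperties:
    def test_annotator_permutation_equivariance(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        perm = np.array([1, 0])
        pdata = AnnotationSet(
            labels=data.labels[:, perm], mask=data.mask[:, perm]
        )
        pstate = make_state(
            state.z, state.phi[perm], state.lam[perm],
            b=state.b, alpha_phi=state.alpha_phi, w=state.w,
        )
        m0, p0 = phi_conditional(state, data, hyp)
        m1, p1 = phi_conditional(pstate, pdata, hyp)
        np.testing.assert_allclose(m1, m0[perm], rtol=1e-12)
        np.testing.assert_allclose(p1, p0[perm], rtol=1e-12)
        s0, r0 = lambda_conditional(state, data, hyp)
        s1, r1 = lambda_conditional(pstate, pdata, hyp)
        np.testing.assert_allclose(s1, s0[perm], rtol=1e-12)
        np.testing.assert_allclose(r1, r0[perm], rtol=1e-12)

    def test_missing_column_reverts_to_prior_every_sweep(self):
        labels = np.column_stack([np.arange(4.0), np.full(4, np.nan)])
        data = AnnotationSet(labels=labels, mask=~np.isnan(labels))
        X = FeatureMatrix.from_features(None, 4)
        hyp = IAMHyperparams(mu_phi=0.3, k_lambda=2.0, theta_lambda=0.5)
        state = make_state(np.arange(4.0), [0.0, 0.0], [1.0, 1.0], alpha_phi=2.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            mean, prec = phi_conditional(state, data, hyp)
            assert mean[1] == pytest.approx(hyp.mu_phi)
            assert prec[1] == pytest.approx(state.alpha_phi)
            shape, rate = lambda_conditional(state, data, hyp)
            assert shape[1] == pytest.approx(hyp.k_lambda)
            assert rate[1] == pytest.approx(1 / hyp.theta_lambda)
            state.z = sample_z(state, data, X, rng)
            state.phi = sample_phi(state, data, hyp, rng)
            state.lam = sample_lambda(state, data, hyp, rng)

    def test_positivity_over_many_sweeps(self, tiny_instance):
        data, X, state, hyp = tiny_instance
        rng = np.random.default_rng(42)
        for _ in range(2000):
            state.z = sample_z(state, data, X, rng)
            state.phi = sample_phi(state, data, hyp, rng)
            state.lam = sample_lambda(state, data, hyp, rng)
            state.alpha_phi = sample_alpha_phi(state, hyp, rng)
            state.b = sample_b(state, X, hyp, "as_printed", rng)
            assert np.all(state.lam > 0) and state.b > 0 and state.alpha_phi > 0
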