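"""Kernels, GP posterior against a brute-force oracle, BMT updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gridbandits as gb
from gridbandits.grid import N_OPTIONS
from gridbandits.learners import (
    BMTConfig,
    KernelSpec,
    bmt_prior,
    bmt_update,
    gp_posterior,
    gp_posterior_weights,
    kernel_matrix,
    kernel_value,
    normalize_reward,
    denormalize_reward,
)


def brute_force_gp_posterior(history, spec):
    """Oracle: condition the explicit 64+t joint normal on noisy observations.

    Builds the full covariance of (f at all 64 options, noisy y at the
    observed options) and applies the partitioned-Gaussian conditioning
    formula with an explicit matrix inverse — no code shared with
    gp_posterior beyond the kernel matrix.
    """
    K = kernel_matrix(spec)
    idx = np.array([i for i, _ in history])
    y = np.array([v for _, v in history])
    cov_ff = K
    cov_fy = K[:, idx]
    cov_yy = K[np.ix_(idx, idx)] + spec.noise_var * np.eye(len(idx))
    inv = np.linalg.inv(cov_yy)
    mean = cov_fy @ inv @ y
    cov_post = cov_ff - cov_fy @ inv @ cov_fy.T
    return mean, np.diag(cov_post)


class TestKernels:
    def test_zero_distance_similarity_is_one(self):
        for lam in (0.5, 2.0, 10.0):
            assert kernel_value((3, 4), (3, 4), KernelSpec(lambda_=lam)) == pytest.approx(1.0)

    def test_rbf_analytic_value(self):
        # d^2 = 8 between (0,0) and (2,2); lambda = 2 gives exp(-8/8)
        k = kernel_value((0, 0), (2, 2), KernelSpec(lambda_=2.0))
        assert k == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_shepard_with_rho_2_equals_rbf(self):
        rng = np.random.default_rng(0)
        rbf = kernel_matrix(KernelSpec(kind="rbf", lambda_=1.3))
        shep = kernel_matrix(KernelSpec(kind="shepard", lambda_=1.3, rho=2.0))
        pairs = rng.integers(0, 64, size=(1000, 2))
        np.testing.assert_allclose(rbf[pairs[:, 0], pairs[:, 1]],
                                   shep[pairs[:, 0], pairs[:, 1]], atol=1e-12)

    def test_separable_rho_never_exceeds_rbf_similarity(self):
        # Minkowski distance with rho < 2 dominates the Euclidean distance,
        # so similarity can only shrink; axis-aligned displacements tie.
        rbf = kernel_matrix(KernelSpec(kind="rbf", lambda_=1.0))
        shep = kernel_matrix(KernelSpec(kind="shepard", lambda_=1.0, rho=1.0))
        assert (shep <= rbf + 1e-12).all()
        assert shep[0, 5] == pytest.approx(rbf[0, 5])  # same row: one axis only

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec(lambda_=0.0)
        with pytest.raises(ValueError):
            KernelSpec(kind="shepard", lambda_=1.0, rho=2.5)
        with pytest.raises(ValueError):
            KernelSpec(kind="matern", lambda_=1.0)


class TestGPPosterior:
    def test_empty_history_returns_prior(self):
        b = gp_posterior([], KernelSpec(lambda_=1.0))
        np.testing.assert_array_equal(b.post_mean, np.zeros(64))
        np.testing.assert_array_equal(b.post_var, np.ones(64))

    def test_single_observation_analytic(self):
        # one observation y=1 with unit noise: m = k/(1+1) at the observed
        # point, v = 1 - 1/2
        spec = KernelSpec(lambda_=2.0, noise_var=1.0)
        b = gp_posterior([((3, 3), 1.0)], spec)
        assert b.mean_at((3, 3)) == pytest.approx(0.5)
        assert b.var_at((3, 3)) == pytest.approx(0.5)
        k = kernel_value((3, 3), (0, 0), spec)
        assert b.mean_at((0, 0)) == pytest.approx(k / 2)

    @pytest.mark.parametrize("n_obs", [2, 5, 8, 12])
    def test_matches_brute_force_conditioning(self, n_obs):
        rng = np.random.default_rng(n_obs)
        spec = KernelSpec(lambda_=float(rng.uniform(0.5, 3.0)))
        history = [(int(rng.integers(64)), float(rng.normal(0, 0.3)))
                   for _ in range(n_obs)]
        b = gp_posterior(history, spec)
        mean, var = brute_force_gp_posterior(history, spec)
        np.testing.assert_allclose(b.post_mean, mean, atol=1e-8)
        np.testing.assert_allclose(b.post_var, np.maximum(var, 0), atol=1e-8)

    def test_variance_never_increases_with_observations(self):
        rng = np.random.default_rng(3)
        spec = KernelSpec(lambda_=1.5)
        history = []
        prev = np.ones(64)
        for _ in range(12):
            history.append((int(rng.integers(64)), float(rng.normal())))
            cur = gp_posterior(history, spec).post_var
            assert (cur <= prev + 1e-10).all()
            prev = cur


class TestWeights:
    def test_single_observation_scalar_inverse(self):
        w = gp_posterior_weights([((0, 0), 1.0)], KernelSpec(lambda_=1.0, noise_var=1.0))
        assert w == pytest.approx([0.5])

    def test_similarity_weighted_sum_equals_matrix_form(self):
        rng = np.random.default_rng(1)
        spec = KernelSpec(lambda_=1.2)
        history = [(int(rng.integers(64)), float(rng.normal())) for _ in range(9)]
        w = gp_posterior_weights(history, spec)
        K = kernel_matrix(spec)
        idx = [i for i, _ in history]
        means_from_weights = K[:, idx] @ w
        np.testing.assert_allclose(
            means_from_weights, gp_posterior(history, spec).post_mean, atol=1e-10)

    def test_zero_rewards_give_zero_weights(self):
        history = [(3, 0.0), (17, 0.0), (44, 0.0)]
        w = gp_posterior_weights(history, KernelSpec(lambda_=1.0))
        np.testing.assert_allclose(w, 0.0, atol=1e-14)
        with pytest.raises(ValueError):
            gp_posterior_weights([], KernelSpec(lambda_=1.0))


class TestBMT:
    def test_single_update_closed_form(self):
        cfg = BMTConfig(theta_eps2=1.0, m0=0.0, v0=1.0)
        state, trace = bmt_update(bmt_prior(cfg), cfg, (0, 0), 10.0)
        assert trace.kalman_gain == pytest.approx(0.5)
        assert state.mean_at((0, 0)) == pytest.approx(5.0)
        assert state.var_at((0, 0)) == pytest.approx(0.5)

    def test_unchosen_options_untouched(self):
        cfg = BMTConfig(theta_eps2=2.0)
        prior = bmt_prior(cfg)
        state, _ = bmt_update(prior, cfg, 10, 3.0)
        mask = np.arange(64) != 10
        np.testing.assert_array_equal(state.post_mean[mask], prior.post_mean[mask])
        np.testing.assert_array_equal(state.post_var[mask], prior.post_var[mask])

    def test_repeated_observation_converges_monotonically(self):
        cfg = BMTConfig(theta_eps2=1.0, v0=5.0)
        state = bmt_prior(cfg)
        gaps, variances = [], []
        for _ in range(50):
            state, trace = bmt_update(state, cfg, 7, 1.0)
            assert 0 < trace.kalman_gain < 1
            gaps.append(abs(1.0 - state.mean_at(7)))
            variances.append(state.var_at(7))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert all(a > b for a, b in zip(variances, variances[1:]))
        # the gain shrinks like 1/t once v << theta, so convergence is
        # harmonic, not geometric: after 50 updates v ~ 1/50
        assert gaps[-1] < 0.01 and variances[-1] < 0.05

    def test_error_variance_limits(self):
        huge = BMTConfig(theta_eps2=1e12)
        state, trace = bmt_update(bmt_prior(huge), huge, 0, 100.0)
        assert trace.kalman_gain < 1e-10  # no learning
        assert abs(state.mean_at(0)) < 1e-8
        tiny = BMTConfig(theta_eps2=1e-12, v0=5.0)
        state, trace = bmt_update(bmt_prior(tiny), tiny, 0, 7.0)
        assert state.mean_at(0) == pytest.approx(7.0)


def test_belief_frame_snapshot():
    from gridbandits.learners import belief_frame
    b = gp_posterior([(10, 0.2)], KernelSpec(lambda_=1.0))
    df = belief_frame(b)
    assert list(df.columns) == ["option", "d1", "d2", "mean", "variance"]
    assert len(df) == 64
    assert df.loc[10, "mean"] == pytest.approx(b.post_mean[10])


@given(st.floats(-40, 60))
@settings(max_examples=25, deadline=None)
def test_reward_normalization_round_trips(r):
    assert denormalize_reward(normalize_reward(r)) == pytest.approx(r, abs=1e-9)
    assert normalize_reward(50.0) == 0.0
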