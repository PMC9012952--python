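import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slctkd.solver import (
    HyperParams,
    fit_slctkd,
    initialize_state,
    soft_threshold,
    solve_R_sylvester,
    update_B,
    update_E_shrink,
    update_G_shrink,
    update_multipliers,
    update_penalties,
    update_S,
    update_Y_newton,
)
from slctkd.tensor_ops import tucker2_reconstruct


def make_state(rng, V=12, T=7, K=3, N=2, **hp):
    X = rng.normal(size=(V, T, K))
    params = HyperParams(n_components=N, **hp)
    state = initialize_state(X, params)
    return X, params, state


class TestSoftThreshold:
    def test_analytic_prox_values(self):
        assert soft_threshold(np.array(0.5), 0.2) == pytest.approx(0.3)
        assert soft_threshold(np.array(-0.1), 0.2) == 0.0
        assert soft_threshold(np.array(-0.7), 0.2) == pytest.approx(-0.5)

    def test_zero_threshold_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array(1.0), -0.1)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.floats(-1e6, 1e6, allow_nan=False),
        t=st.floats(0, 1e6, allow_nan=False),
    )
    def test_nonexpansive_and_sign_preserving(self, x, t):
        y = float(soft_threshold(np.array(x), t))
        assert abs(y) <= abs(x) + 1e-12
        assert y * x >= 0


class TestFactorUpdates:
    def test_update_B_zero_numerator(self, rng):
        X, params, state = make_state(rng)
        state.E = X.copy()
        state.U = np.zeros_like(X)
        assert np.allclose(update_B(state, X, params), 0)

    def test_update_B_closed_form_orthonormal_identity_core(self, rng):
        X, params, state = make_state(rng, V=10, T=6, K=3, N=3)
        S, _ = np.linalg.qr(rng.normal(size=(10, 3)))
        state.factors.S = S
        state.R = np.stack([np.eye(3)] * 3, axis=2)
        state.U = np.zeros_like(X)
        state.E = rng.normal(size=X.shape)
        a, K = state.alpha, 3
        expected = a * sum((X[:, :, k] - state.E[:, :, k]).T @ S for k in range(K)) @ np.linalg.inv(
            (1 + a * K) * np.eye(3)
        )
        np.testing.assert_allclose(update_B(state, X, params), expected, atol=1e-10)

    def test_update_S_zero_numerator(self, rng):
        X, params, state = make_state(rng)
        state.E = X.copy()
        state.U = np.zeros_like(X)
        state.Y = np.zeros_like(state.Y)
        state.Q = np.zeros_like(state.Q)
        assert np.allclose(update_S(state, X, params), 0)

    def test_update_S_pure_hqs_pull_at_zero_alpha(self, rng):
        X, params, state = make_state(rng)
        state.alpha = 0.0
        state.Q = np.zeros_like(state.Q)
        state.Y = rng.normal(size=state.Y.shape)
        expected = params.delta * state.Y / (params.delta + params.mu_s)
        np.testing.assert_allclose(update_S(state, X, params), expected, atol=1e-12)

    def _lagrangian(self, X, params, state, S, B):
        rec = tucker2_reconstruct(state.R, S, B)
        resid = X - rec - state.E
        L = params.mu_s * np.sum(S**2) + params.mu_b * np.sum(B**2)
        L += params.delta * np.sum((S - state.Y) ** 2)
        L += state.alpha * np.sum(resid**2) + np.sum(resid * state.U)
        return L

    def test_update_B_minimizes_quadratic_lagrangian(self, rng):
        X, params, state = make_state(rng)
        state.E = rng.normal(size=X.shape)
        state.U = rng.normal(size=X.shape)
        Bnew = update_B(state, X, params)
        base = self._lagrangian(X, params, state, state.factors.S, Bnew)
        for _ in range(100):
            P = np.zeros_like(Bnew)
            P[rng.integers(0, P.shape[0]), rng.integers(0, P.shape[1])] = rng.choice([-1e-4, 1e-4])
            assert self._lagrangian(X, params, state, state.factors.S, Bnew + P) >= base - 1e-12

    def test_update_S_minimizes_quadratic_lagrangian(self, rng):
        # Q = 0 isolates the quadratic part from the multiplier convention
        X, params, state = make_state(rng)
        state.E = rng.normal(size=X.shape)
        state.U = rng.normal(size=X.shape)
        state.Y = rng.normal(size=state.Y.shape)
        state.Q = np.zeros_like(state.Q)
        Snew = update_S(state, X, params)
        base = self._lagrangian(X, params, state, Snew, state.factors.B)
        for _ in range(100):
            P = np.zeros_like(Snew)
            P[rng.integers(0, P.shape[0]), rng.integers(0, P.shape[1])] = rng.choice([-1e-4, 1e-4])
            assert self._lagrangian(X, params, state, Snew + P, state.factors.B) >= base - 1e-12


class TestNewtonY:
    def test_zero_xi_single_step_exact(self, rng):
        # Newton on a pure quadratic lands at the minimiser in one step
        V, N = 8, 3
        S = rng.normal(size=(V, N))
        Q = rng.normal(size=(V, N))
        Y0 = rng.normal(size=(V, N))
        for strict in (True, False):
            params = HyperParams(n_components=N, xi=0.0, strict_paper=strict)
            Y1 = update_Y_newton(Y0, S, Q, params, n_steps=1)
            np.testing.assert_allclose(Y1, S - Q / params.delta, atol=1e-12)

    def test_printed_step_hand_computed_at_p_one(self, rng):
        V, N = 5, 2
        S = rng.normal(size=(V, N))
        Q = rng.normal(size=(V, N))
        Y0 = rng.normal(size=(V, N)) + np.sign(rng.normal(size=(V, N))) * 2.0  # |Y| >> 0
        params = HyperParams(n_components=N, p=1.0, strict_paper=True)
        yd = params.xi * 1.0 * np.sign(Y0) + params.delta * (S - Y0) - Q
        ydd = -params.delta * np.ones_like(Y0)
        expected = Y0 - yd / ydd
        np.testing.assert_allclose(update_Y_newton(Y0, S, Q, params, n_steps=1), expected, atol=1e-12)

    def test_stationary_point_unchanged(self, rng):
        V, N = 6, 2
        params = HyperParams(n_components=N, xi=0.0, strict_paper=True)
        S = rng.normal(size=(V, N))
        Q = rng.normal(size=(V, N))
        Ystar = S - Q / params.delta  # yd(Ystar) = 0 when xi = 0
        np.testing.assert_allclose(
            update_Y_newton(Ystar, S, Q, params, n_steps=5), Ystar, atol=1e-12
        )

    def test_invalid_p_rejected(self, rng):
        with pytest.raises(ValueError):
            HyperParams(n_components=2, p=1.5)

    def test_output_finite_near_zero_entries(self, rng):
        V, N = 6, 2
        params = HyperParams(n_components=N)
        Y0 = np.zeros((V, N))
        out = update_Y_newton(Y0, rng.normal(size=(V, N)), np.zeros((V, N)), params)
        assert np.all(np.isfinite(out))


class TestCoreAndResidualShrinkage:
    def test_no_shrinkage_returns_split_core(self, rng):
        R = rng.normal(size=(3, 3, 2))
        np.testing.assert_array_equal(update_G_shrink(R, np.zeros_like(R), 1.0, 0.0), R)

    def test_constant_shrink_amount(self):
        R = np.ones((2, 2, 2))
        out = update_G_shrink(R, np.zeros_like(R), beta=0.5, lam=0.4)  # lam/2beta = 0.4
        np.testing.assert_allclose(out, 0.6)

    def test_total_shrinkage_zeroes_core(self, rng):
        R = rng.uniform(-1, 1, size=(3, 3, 2))
        out = update_G_shrink(R, np.zeros_like(R), beta=0.5, lam=10.0)
        assert np.all(out == 0)

    def test_nonpositive_beta_rejected(self, rng):
        with pytest.raises(ValueError):
            update_G_shrink(rng.normal(size=(2, 2, 1)), np.zeros((2, 2, 1)), 0.0, 0.1)

    def test_E_zero_when_model_exact(self, rng):
        X, params, state = make_state(rng)
        X = tucker2_reconstruct(state.R, state.factors.S, state.factors.B)
        state.U = np.zeros_like(X)
        assert np.allclose(update_E_shrink(state, X, params), 0)

    def test_E_exact_residual_when_gamma_zero(self, rng):
        X, params, state = make_state(rng, gamma=0.0)
        state.U = np.zeros_like(X)
        expected = X - tucker2_reconstruct(state.R, state.factors.S, state.factors.B)
        np.testing.assert_allclose(update_E_shrink(state, X, params), expected, atol=1e-12)

    def test_E_total_shrinkage(self, rng):
        X, params, state = make_state(rng)
        state.alpha = 1e-12  # gamma/2alpha huge
        assert np.all(update_E_shrink(state, X, params) == 0)

    def test_shrinkage_nonexpansive(self, rng):
        x = rng.normal(size=(50, 40, 3))
        out = soft_threshold(x, 0.3)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-15)


class TestSylvesterSolve:
    def test_orthonormal_factors_closed_form(self, rng):
        X, params, state = make_state(rng, V=10, T=8, K=2, N=3)
        S, _ = np.linalg.qr(rng.normal(size=(10, 3)))
        B, _ = np.linalg.qr(rng.normal(size=(8, 3)))
        state.factors.S, state.factors.B = S, B
        state.W = rng.normal(size=state.W.shape)
        a, b = state.alpha, state.beta
        R = solve_R_sylvester(state, X, params)
        for k in range(2):
            Rt = S.T @ (a * (X[:, :, k] - state.E[:, :, k]) + state.U[:, :, k] / 2) @ B
            rhs = Rt + state.beta * state.factors.G[:, :, k] + state.W[:, :, k] / 2
            np.testing.assert_allclose(R[:, :, k], rhs / (a + b), atol=1e-10)

    @pytest.mark.parametrize("strict", [True, False])
    def test_matches_kronecker_vectorized_oracle(self, rng, strict):
        for trial in range(10):
            V, T, K, N = 15, 9, 3, 4
            X = rng.normal(size=(V, T, K))
            params = HyperParams(n_components=N, strict_paper=strict)
            state = initialize_state(X, params)
            state.W = rng.normal(size=state.W.shape)
            state.E = rng.normal(size=X.shape)
            state.U = rng.normal(size=X.shape)
            state.alpha, state.beta = rng.uniform(0.1, 3), rng.uniform(0.1, 3)
            R = solve_R_sylvester(state, X, params)
            S, B, G = state.factors.S, state.factors.B, state.factors.G
            sgn = -1.0 if strict else 1.0
            A = state.alpha * np.kron(np.eye(N), S.T @ S) @ np.kron((B.T @ B).T, np.eye(N)) + state.beta * np.eye(N * N)
            for k in range(K):
                Rt = S.T @ (state.alpha * (X[:, :, k] - state.E[:, :, k]) + state.U[:, :, k] / 2) @ B
                rhs = Rt + sgn * (state.beta * G[:, :, k] + state.W[:, :, k] / 2)
                vec = np.linalg.solve(A, rhs.flatten(order="F"))
                np.testing.assert_allclose(R[:, :, k].flatten(order="F"), vec, atol=1e-8)

    def test_small_alpha_limit(self, rng):
        X, params, state = make_state(rng, N=3)
        state.alpha = 1e-12
        R = solve_R_sylvester(state, X, params)
        for k in range(X.shape[2]):
            rhs = state.beta * state.factors.G[:, :, k] + state.W[:, :, k] / 2
            np.testing.assert_allclose(R[:, :, k], rhs / state.beta, atol=1e-6)


class TestMultipliersAndPenalties:
    def test_exact_feasibility_leaves_multipliers_unchanged(self, rng):
        X, params, state = make_state(rng)
        X = tucker2_reconstruct(state.R, state.factors.S, state.factors.B) + state.E
        state.factors.G = state.R.copy()
        state.Y = state.factors.S.copy()
        U0, W0, Q0 = state.U.copy(), state.W.copy(), state.Q.copy()
        state = update_multipliers(state, X, params)
        np.testing.assert_allclose(state.U, U0, atol=1e-12)
        np.testing.assert_allclose(state.W, W0, atol=1e-12)
        np.testing.assert_allclose(state.Q, Q0, atol=1e-12)

    def test_first_step_equals_scaled_primal_residual(self, rng):
        X, params, state = make_state(rng)
        state.E = rng.normal(size=X.shape)
        state = update_multipliers(state, X, params)
        expected_U = state.alpha * (
            X - tucker2_reconstruct(state.R, state.factors.S, state.factors.B) - state.E
        )
        np.testing.assert_allclose(state.U, expected_U, atol=1e-12)

    def test_penalty_growth_values(self):
        assert update_penalties(1.0, 2.0, 1.3) == (pytest.approx(1.3), pytest.approx(2.6))

    def test_penalty_growth_is_geometric(self):
        a, b = 0.7, 0.9
        for _ in range(10):
            a, b = update_penalties(a, b, 1.3)
        assert a == pytest.approx(0.7 * 1.3**10)
        assert b == pytest.approx(0.9 * 1.3**10)

    def test_eta_must_exceed_one(self):
        with pytest.raises(ValueError):
            update_penalties(1.0, 1.0, 1.0)


class TestFitLoop:
    def test_single_iteration_bookkeeping(self, rng):
        X = rng.normal(size=(20, 10, 3))
        params = HyperParams(n_components=3, iter_max=1)
        fit = fit_slctkd(X, params)
        assert fit.n_iterations == 1
        assert fit.converged_reason == "max_iter"

    def test_deterministic_eps_trace(self, rng):
        X = rng.normal(size=(20, 10, 3))
        params = HyperParams(n_components=3, iter_max=15)
        f1 = fit_slctkd(X, params)
        f2 = fit_slctkd(X.copy(), params)
        np.testing.assert_array_equal(f1.eps_trace, f2.eps_trace)

    def test_penalties_grow_geometrically_across_iterations(self, rng):
        X = rng.normal(size=(20, 10, 3))
        params = HyperParams(n_components=3, iter_max=8, deps_min=1e-15, eps_min=1e-15)
        fit = fit_slctkd(X, params)
        a0 = X.shape[2] / np.linalg.norm(X)
        np.testing.assert_allclose(fit.alpha_trace, a0 * params.eta ** np.arange(len(fit.alpha_trace)))

    def test_descent_on_noiseless_low_rank_data(self, small_tucker2):
        X, G, S, B = small_tucker2
        params = HyperParams(n_components=G.shape[0], iter_max=60)
        fit = fit_slctkd(X, params)
        assert fit.eps_trace[-1] < fit.eps_trace[0] / 10

    def test_stop_reason_recorded(self, small_tucker2):
        X, G, S, B = small_tucker2
        params = HyperParams(n_components=G.shape[0], iter_max=300)
        fit = fit_slctkd(X, params)
        assert fit.converged_reason in {"eps_min", "deps_min", "max_iter"}
        assert len(fit.eps_trace) == fit.n_iterations

    def test_zero_tensor_rejected(self):
        with pytest.raises(ValueError, match="zero tensor"):
            fit_slctkd(np.zeros((10, 5, 2)), HyperParams(n_components=2))

    def test_order_exceeding_dims_rejected(self, rng):
        with pytest.raises(ValueError, match="model order"):
            fit_slctkd(rng.normal(size=(10, 4, 2)), HyperParams(n_components=6))


class TestConstraintLimits:
    """delta, lambda, gamma -> 0 must reduce to the unconstrained updates."""

    def test_gamma_zero_E_update_unconstrained(self, rng):
        X, params, state = make_state(rng, gamma=0.0)
        state.U = np.zeros_like(X)
        expected = X - tucker2_reconstruct(state.R, state.factors.S, state.factors.B)
        np.testing.assert_allclose(update_E_shrink(state, X, params), expected)

    def test_lambda_zero_G_update_unconstrained(self, rng):
        R = rng.normal(size=(3, 3, 2))
        W = rng.normal(size=(3, 3, 2))
        np.testing.assert_allclose(update_G_shrink(R, W, 0.8, 0.0), R - W / 1.6)

    def test_delta_zero_S_update_drops_y_coupling(self, rng):
        X, params0, state = make_state(rng)
        state.E = rng.normal(size=X.shape)
        state.U = rng.normal(size=X.shape)
        state.Q = np.zeros_like(state.Q)
        params = HyperParams(n_components=2, delta=0.0)
        S_free = update_S(state, X, params)
        # same computation with Y zeroed must agree: Y no longer enters
        state.Y = np.zeros_like(state.Y)
        np.testing.assert_allclose(update_S(state, X, params), S_free, atol=1e-12)


class TestHyperParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p": 0.0},
            {"p": 1.2},
            {"eta": 0.9},
            {"delta": -1.0},
            {"eps_min": 0.0},
            {"iter_y": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HyperParams(n_components=2, **kwargs)

    def test_documented_defaults(self):
        hp = HyperParams()
        assert (hp.p, hp.gamma, hp.lam, hp.eta, hp.xi) == (0.3, 0.6, 0.4, 1.3, 0.4)
        assert (hp.iter_y, hp.iter_max) == (10, 300)
        assert hp.eps_min == 1e-7 and hp.deps_min == 1e-4
        assert hp.delta == 2.5  # sparse/simulated regime; 0.4 suits experimental data
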