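import numpy as np
import pytest

from nmftrack.abundance_io import AbundanceTable
from nmftrack.nmf_core import (
    FactorState,
    SolverConfig,
    TrackingProblem,
    build_problem,
    has_converged,
    initialize_state,
    lagrangian,
    rescale,
    solve,
    update_H,
    update_W,
    update_duals,
)

from _oracles import lagrangian_reference, simplex_grid


def _random_problem(rng, n_taxa=6, n_sources=3):
    Y = rng.dirichlet(np.ones(n_taxa), size=n_sources + 1).T
    A = np.ones_like(Y)
    A[:, -1] = 0.0
    X = rng.dirichlet(np.ones(n_taxa))
    return TrackingProblem(
        X=X, Y=Y, A=A, source_ids=tuple(f"s{j}" for j in range(n_sources))
    )


class TestBuildProblem:
    def test_mask_structure(self, tiny_sources):
        prob = build_problem(tiny_sources, np.array([0.5, 0.5]))
        np.testing.assert_array_equal(prob.A, [[1, 1, 0], [1, 1, 0]])

    def test_sink_normalized(self, tiny_sources):
        prob = build_problem(tiny_sources, np.array([2.0, 2.0]))
        np.testing.assert_allclose(prob.X, [0.5, 0.5])

    def test_reference_columns_normalized(self):
        src = AbundanceTable(
            ("a", "b"), ("s1", "s2"), np.array([[4.0, 1.0], [4.0, 3.0]])
        )
        prob = build_problem(src, np.array([1.0, 1.0]))
        np.testing.assert_allclose(prob.Y[:, :2].sum(axis=0), 1.0, atol=1e-12)

    def test_zero_sink_rejected(self, tiny_sources):
        with pytest.raises(ValueError, match="sink"):
            build_problem(tiny_sources, np.zeros(2))

    def test_zero_source_rejected(self):
        src = AbundanceTable(("a", "b"), ("ok", "bad"), np.array([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="bad"):
            build_problem(src, np.array([1.0, 0.0]))

    def test_nnls_seed_on_feasible_mixture(self, tiny_sources):
        prob = build_problem(tiny_sources, np.array([0.3, 0.7]))
        np.testing.assert_allclose(prob.h_init, [0.3, 0.7, 0.0], atol=1e-9)


class TestInitializeState:
    def test_uniform_mode(self, rng):
        prob = _random_problem(rng, n_sources=4)
        state = initialize_state(prob, SolverConfig(init="uniform"))
        np.testing.assert_allclose(state.H_plus, 0.2)
        np.testing.assert_allclose(state.H, 0.2)
        assert not state.alpha_W.any() and not state.alpha_H.any()

    def test_nnls_mode_uses_seed(self, tiny_sources):
        prob = build_problem(tiny_sources, np.array([0.3, 0.7]))
        state = initialize_state(prob, SolverConfig())
        np.testing.assert_allclose(state.H, prob.h_init)

    def test_W_plus_columns_on_simplex(self, rng):
        prob = _random_problem(rng)
        state = initialize_state(prob, SolverConfig())
        np.testing.assert_allclose(state.W_plus.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(state.W_plus >= 0)


class TestPrimalUpdates:
    def test_update_H_hand_case(self):
        # W = I2, X = (0.6, 0.4), rho = 1, H+ = (0.5, 0.5), duals 0
        prob = TrackingProblem(
            X=np.array([0.6, 0.4]),
            Y=np.column_stack([np.eye(2)[:, :1], np.array([[0.5], [0.5]])]),
            A=np.array([[1.0, 0.0], [1.0, 0.0]]),
            source_ids=("s1",),
        )
        state = FactorState(
            W=np.eye(2), H=np.zeros(2), W_plus=np.eye(2),
            H_plus=np.array([0.5, 0.5]), alpha_W=np.zeros((2, 2)),
            alpha_H=np.zeros(2),
        )
        np.testing.assert_allclose(update_H(state, prob, 1.0), [0.55, 0.45], atol=1e-12)

    def test_update_H_defining_equation(self, rng):
        prob = _random_problem(rng)
        state = initialize_state(prob, SolverConfig(init="uniform"))
        state.alpha_H = rng.normal(size=4)
        rho = 1.3
        H = update_H(state, prob, rho)
        lhs = (state.W.T @ state.W + rho * np.eye(4)) @ H
        rhs = state.W.T @ prob.X + rho * state.H_plus - state.alpha_H
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_update_H_large_rho_limit(self, rng):
        prob = _random_problem(rng)
        state = initialize_state(prob, SolverConfig(init="uniform"))
        H = update_H(state, prob, 1e8)
        np.testing.assert_allclose(H, state.H_plus, atol=1e-7)

    def test_update_W_defining_equation(self, rng):
        prob = _random_problem(rng)
        state = initialize_state(prob, SolverConfig(init="uniform"))
        state.H = rng.dirichlet(np.ones(4))
        state.alpha_W = rng.normal(scale=0.1, size=prob.Y.shape)
        rho = 0.7
        W = update_W(state, prob, rho)
        lhs = W @ (np.outer(state.H, state.H) + rho * np.eye(4))
        rhs = rho * state.W_plus - state.alpha_W + np.outer(prob.X, state.H)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_update_W_large_rho_limit(self, rng):
        prob = _random_problem(rng)
        state = initialize_state(prob, SolverConfig(init="uniform"))
        W = update_W(state, prob, 1e8)
        np.testing.assert_allclose(W, state.W_plus, atol=1e-7)

    def test_update_W_scalar_case(self):
        # N=1, K+1=1: W = (rho*w_plus - alpha + x*h) / (h^2 + rho)
        rho, w_plus, alpha, x, h = 0.9, 0.4, -0.2, 1.0, 0.7
        prob = TrackingProblem(
            X=np.array([1.0]), Y=np.array([[0.3]]), A=np.array([[0.0]]),
            source_ids=(),
        )
        state = FactorState(
            W=np.array([[0.0]]), H=np.array([h]), W_plus=np.array([[w_plus]]),
            H_plus=np.array([1.0]), alpha_W=np.array([[alpha]]),
            alpha_H=np.zeros(1),
        )
        expected = (rho * w_plus - alpha + x * h) / (h**2 + rho)
        assert update_W(state, prob, rho)[0, 0] == pytest.approx(expected, abs=1e-12)


class TestRescale:
    def test_direct(self):
        W = np.array([[2.0], [2.0]])
        H = np.array([0.5])
        W2, H2 = rescale(W, H)
        np.testing.assert_allclose(W2.ravel(), [0.5, 0.5])
        np.testing.assert_allclose(H2, [2.0])

    def test_product_invariant(self, rng):
        W = rng.normal(size=(5, 3)) + 1.0
        H = rng.uniform(0.1, 1.0, size=3)
        W2, H2 = rescale(W, H)
        np.testing.assert_allclose(W2 @ H2, W @ H, atol=1e-12)
        np.testing.assert_allclose(W2.sum(axis=0), 1.0, atol=1e-12)

    def test_idempotent_on_normalized(self, rng):
        W = rng.dirichlet(np.ones(5), size=3).T
        H = rng.uniform(size=3)
        W2, H2 = rescale(W, H)
        np.testing.assert_allclose(W2, W, atol=1e-12)
        np.testing.assert_allclose(H2, H, atol=1e-12)

    def test_tiny_column_sum_clamped(self):
        W = np.array([[1e-15], [-1e-15]])
        H = np.array([1.0])
        W2, H2 = rescale(W, H)
        assert np.all(np.isfinite(W2)) and np.all(np.isfinite(H2))


class TestLagrangian:
    def test_zero_at_consistent_state(self, rng):
        prob = _random_problem(rng)
        H = rng.dirichlet(np.ones(4))
        X = prob.Y @ H
        prob2 = TrackingProblem(
            X=X / X.sum(), Y=prob.Y, A=prob.A, source_ids=prob.source_ids
        )
        # rebuild H for the renormalized X so that X = W H exactly
        H = H / X.sum()
        state = FactorState(
            W=prob2.Y.copy(), H=H, W_plus=prob2.Y.copy(), H_plus=H,
            alpha_W=np.zeros_like(prob2.Y), alpha_H=np.zeros(4),
        )
        assert lagrangian(state, prob2, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_term_isolation(self, rng):
        prob = _random_problem(rng)
        W = rng.dirichlet(np.ones(6), size=4).T
        H = rng.dirichlet(np.ones(4))
        state = FactorState(
            W=W, H=H, W_plus=W.copy(), H_plus=H.copy(),
            alpha_W=np.zeros_like(W), alpha_H=np.zeros(4),
        )
        expected = 0.5 * np.sum((prob.X - W @ H) ** 2) + 0.5 * np.sum(
            (prob.A * (W - prob.Y)) ** 2
        )
        assert lagrangian(state, prob, 2.0) == pytest.approx(expected, abs=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        prob = _random_problem(rng)
        state = FactorState(
            W=rng.normal(size=prob.Y.shape),
            H=rng.normal(size=4),
            W_plus=rng.dirichlet(np.ones(6), size=4).T,
            H_plus=rng.dirichlet(np.ones(4)),
            alpha_W=rng.normal(scale=0.3, size=prob.Y.shape),
            alpha_H=rng.normal(scale=0.3, size=4),
        )
        rho = 1.7
        ref = lagrangian_reference(
            prob.X, prob.Y, prob.A, state.W, state.H, state.W_plus,
            state.H_plus, state.alpha_W, state.alpha_H, rho,
        )
        assert lagrangian(state, prob, rho) == pytest.approx(ref, abs=1e-10)


class TestDualsAndConvergence:
    def test_zero_residual_leaves_duals(self, rng):
        prob = _random_problem(rng)
        state = initialize_state(prob, SolverConfig(init="uniform"))
        aW, aH = update_duals(state, 1.0)
        np.testing.assert_array_equal(aW, state.alpha_W)
        np.testing.assert_array_equal(aH, state.alpha_H)

    def test_direct_dual_step(self):
        state = FactorState(
            W=np.zeros((1, 2)), H=np.array([0.6, 0.4]), W_plus=np.zeros((1, 2)),
            H_plus=np.array([0.5, 0.5]), alpha_W=np.zeros((1, 2)),
            alpha_H=np.zeros(2),
        )
        _, aH = update_duals(state, 1.0)
        np.testing.assert_allclose(aH, [0.1, -0.1], atol=1e-15)

    @pytest.mark.parametrize(
        "L_prev, L_curr, tol, expected",
        [
            (1.0, 1.0000005, 1e-6, True),
            (1.0, 0.9, 1e-6, False),
            (0.0, 5e-7, 1e-6, True),  # absolute fallback at L_prev = 0
            (0.0, 0.1, 1e-6, False),
        ],
    )
    def test_has_converged(self, L_prev, L_curr, tol, expected):
        assert has_converged(L_prev, L_curr, tol) is expected


class TestSolve:
    def test_orthogonal_mixture_recovery(self, tiny_sources):
        result = solve(build_problem(tiny_sources, np.array([0.3, 0.7])))
        np.testing.assert_allclose(result.proportions, [0.3, 0.7, 0.0], atol=1e-3)

    def test_orthogonal_solution_attains_grid_optimum(self, tiny_sources):
        """The returned proportions reach the minimal fit loss found by an
        exhaustive simplex grid search with profiles fixed at the anchors."""
        prob = build_problem(tiny_sources, np.array([0.3, 0.7]))
        result = solve(prob)
        grid = simplex_grid(3, 0.01)
        losses = 0.5 * np.sum((prob.X[:, None] - prob.Y @ grid.T) ** 2, axis=0)
        fit = 0.5 * np.sum((prob.X - prob.Y @ result.proportions) ** 2)
        assert fit <= losses.min() + 1e-6
        assert result.unknown_proportion <= 1e-3

    def test_sink_equal_to_one_source(self, tiny_sources):
        result = solve(build_problem(tiny_sources, np.array([1.0, 0.0])))
        np.testing.assert_allclose(result.proportions, [1.0, 0.0, 0.0], atol=1e-3)

    def test_defaults_match_protocol(self):
        config = SolverConfig()
        assert config.rho == 1.0
        assert config.tol == 1e-6
        assert config.max_iter == 2000

    def test_taxon_permutation_invariance(self, rng):
        prob = _random_problem(rng, n_taxa=8)
        perm = rng.permutation(8)
        prob_p = TrackingProblem(
            X=prob.X[perm], Y=prob.Y[perm], A=prob.A[perm],
            source_ids=prob.source_ids,
        )
        r1 = solve(prob, SolverConfig(max_iter=200))
        r2 = solve(prob_p, SolverConfig(max_iter=200))
        np.testing.assert_allclose(r1.proportions, r2.proportions, atol=1e-9)

    def test_source_permutation_equivariance(self, rng):
        prob = _random_problem(rng, n_taxa=8, n_sources=3)
        perm = np.array([2, 0, 1])
        cols = np.append(perm, 3)  # unknown column stays last
        prob_p = TrackingProblem(
            X=prob.X, Y=prob.Y[:, cols], A=prob.A,
            source_ids=tuple(prob.source_ids[j] for j in perm),
        )
        r1 = solve(prob, SolverConfig(max_iter=200))
        r2 = solve(prob_p, SolverConfig(max_iter=200))
        np.testing.assert_allclose(r1.proportions[perm], r2.proportions[:3], atol=1e-9)

    def test_convergence_criterion_holds_when_converged(self, tiny_sources):
        config = SolverConfig()
        result = solve(build_problem(tiny_sources, np.array([0.4, 0.6])), config)
        assert result.converged
        trace = result.lagrangian_trace
        if trace.size >= 2:
            assert has_converged(trace[-2], trace[-1], config.tol)

    def test_deterministic(self, rng):
        prob = _random_problem(rng)
        r1 = solve(prob, SolverConfig(max_iter=100))
        r2 = solve(prob, SolverConfig(max_iter=100))
        np.testing.assert_array_equal(r1.proportions, r2.proportions)
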