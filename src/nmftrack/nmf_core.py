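"""Reference-anchored NMF for source tracking, solved by ADMM.

A sink sample's taxon profile ``X`` (length N, on the simplex) is modeled
as a mixture ``X = W @ H`` of K reference sources plus one aggregate
unknown source.  ``W`` (N x (K+1)) holds the actual per-source taxon
profiles and ``H`` (length K+1) the mixing proportions; both are unknown.
The observed reference profiles ``Y`` anchor the first K columns of ``W``:

    minimize   1/2 ||X - W H||_F^2  +  1/2 ||A o (W - Y)||_F^2
    subject to W >= 0, H >= 0, sum(H) = 1, each column of W sums to 1,

where ``A`` is a binary mask whose first K columns are ones and whose last
(unknown) column is zeros, so the unknown source is unconstrained by Y.
The problem is split with auxiliary variables W+, H+ carrying the simplex
constraints and solved with scaled-penalty ADMM: closed-form ridge updates
for W and H, a column rescaling keeping W H invariant, water-filling
projections for W+ and H+, then dual ascent.  H+ at termination is the
estimated proportion vector, its last entry the unknown-source total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .abundance_io import AbundanceTable
from .simplex_projection import project_H_plus, project_W_plus

__all__ = [
    "TrackingProblem",
    "SolverConfig",
    "FactorState",
    "TrackingResult",
    "build_problem",
    "initialize_state",
    "update_H",
    "update_W",
    "rescale",
    "lagrangian",
    "update_duals",
    "has_converged",
    "solve",
]

_COLSUM_FLOOR = 1e-12


@dataclass(frozen=True)
class SolverConfig:
    """ADMM settings.

    rho
        Augmented-Lagrangian penalty (default 1).
    tol
        Relative change in the Lagrangian that counts as converged
        (default 1e-6).
    max_iter
        Iteration cap (default 2000).
    seed
        Reserved for randomized initialization; the default initializer is
        deterministic, so this only matters for user extensions.
    init
        Proportion-vector start: ``"nnls"`` (default) seeds H with a
        non-negative least-squares fit of the sink on the references plus
        the residual mass for the unknown; ``"uniform"`` starts at
        1/(K+1).  The objective admits degenerate optima in which the
        free unknown column duplicates reference mass; the NNLS seed
        starts inside the basin where references explain what they can
        and the unknown absorbs only the remainder.
    """

    rho: float = 1.0
    tol: float = 1e-6
    max_iter: int = 2000
    seed: int = 0
    init: str = "nnls"

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("nnls", "uniform"):
            raise ValueError("init must be 'nnls' or 'uniform'")


@dataclass(frozen=True)
class TrackingProblem:
    """Aligned, normalized inputs of one sink-vs-sources factorization."""

    X: np.ndarray  # (N,) sink profile, sums to 1
    Y: np.ndarray  # (N, K+1); first K columns observed sources, last unknown seed
    A: np.ndarray  # (N, K+1) binary mask; ones over references, zeros over unknown
    source_ids: tuple[str, ...]  # K reference ids (unknown column excluded)
    h_init: np.ndarray | None = None  # optional simplex start for H (K+1,)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "A", A)
        N, K1 = Y.shape
        if X.shape != (N,):
            raise ValueError("X length must match Y row count")
        if A.shape != (N, K1):
            raise ValueError("A shape must match Y")
        if len(self.source_ids) != K1 - 1:
            raise ValueError("need one source id per reference column")
        if abs(X.sum() - 1.0) > 1e-9:
            raise ValueError("X must sum to 1")
        colsums = Y[:, :-1].sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("reference columns of Y must sum to 1")
        if not (np.all(A[:, :-1] == 1.0) and np.all(A[:, -1] == 0.0)):
            raise ValueError("A must be ones over references, zeros over unknown")
        if self.h_init is not None:
            h = np.asarray(self.h_init, dtype=float)
            object.__setattr__(self, "h_init", h)
            if h.shape != (K1,) or np.any(h < 0) or abs(h.sum() - 1.0) > 1e-9:
                raise ValueError("h_init must be a simplex vector of length K+1")

    @property
    def n_taxa(self) -> int:
        return self.X.size

    @property
    def n_sources(self) -> int:
        return self.Y.shape[1] - 1


@dataclass
class FactorState:
    """ADMM variables: primals W, H, their simplex copies, and duals."""

    W: np.ndarray
    H: np.ndarray
    W_plus: np.ndarray
    H_plus: np.ndarray
    alpha_W: np.ndarray
    alpha_H: np.ndarray


@dataclass(frozen=True)
class TrackingResult:
    """Solver output: estimated proportions plus convergence diagnostics."""

    proportions: np.ndarray  # H+ at termination, length K+1, last = unknown
    source_ids: tuple[str, ...]  # K reference ids
    iterations: int
    converged: bool
    lagrangian_trace: np.ndarray = field(repr=False)
    primal_residual_W: float = float("nan")
    primal_residual_H: float = float("nan")

    @property
    def unknown_proportion(self) -> float:
        return float(self.proportions[-1])


def build_problem(
    sources: AbundanceTable,
    sink_column: np.ndarray,
    config: SolverConfig | None = None,
) -> TrackingProblem:
    """Assemble X, Y and the mask A from aligned source/sink abundances.

    Sources and the sink may be raw counts; they are column-normalized
    here.  Y gains a (K+1)-th unknown column used only to seed W: it is
    masked out of the loss by A.  A non-negative least-squares fit of X on
    the reference columns supplies both the unknown seed profile — the
    normalized positive residual, i.e. the sink mass the references cannot
    explain, falling back to uniform when that is zero — and a starting
    proportion vector (``h_init``) with the residual mass on the unknown.
    """
    S = np.asarray(sources.values, dtype=float)
    x = np.asarray(sink_column, dtype=float).ravel()
    if x.size != S.shape[0]:
        raise ValueError("sink vector length must match source taxon count")
    if x.sum() <= 0:
        raise ValueError("sink sample has zero total abundance")
    colsums = S.sum(axis=0)
    zero = np.nonzero(colsums <= 0)[0]
    if zero.size:
        raise ValueError(f"source {sources.sample_ids[zero[0]]!r} is all zero")
    X = x / x.sum()
    Yref = S / colsums
    coef, _ = nnls(Yref, X)
    residual = np.maximum(0.0, X - Yref @ coef)
    if residual.sum() > 0:
        unknown = residual / residual.sum()
    else:
        unknown = np.full(X.size, 1.0 / X.size)
    Y = np.column_stack([Yref, unknown])
    A = np.ones_like(Y)
    A[:, -1] = 0.0
    h0 = np.append(coef, min(1.0, residual.sum()))
    h0 = np.maximum(h0, 0.0)
    h0 = h0 / h0.sum() if h0.sum() > 0 else np.full(h0.size, 1.0 / h0.size)
    return TrackingProblem(
        X=X, Y=Y, A=A, source_ids=sources.sample_ids, h_init=h0
    )


def initialize_state(
    problem: TrackingProblem, config: SolverConfig | None = None
) -> FactorState:
    """Deterministic start: W = W+ = Y, duals zero.

    H = H+ starts at the problem's NNLS-derived seed (``problem.h_init``)
    under ``init="nnls"``, or at the uniform vector 1/(K+1) under
    ``init="uniform"``.
    """
    config = config or SolverConfig()
    K1 = problem.Y.shape[1]
    if config.init == "nnls" and problem.h_init is not None:
        H = problem.h_init.copy()
    else:
        H = np.full(K1, 1.0 / K1)
    return FactorState(
        W=problem.Y.copy(),
        H=H.copy(),
        W_plus=problem.Y.copy(),
        H_plus=H.copy(),
        alpha_W=np.zeros_like(problem.Y),
        alpha_H=np.zeros(K1),
    )


def update_H(state: FactorState, problem: TrackingProblem, rho: float) -> np.ndarray:
    """Ridge update: H <- (W'W + rho I)^-1 (W'X + rho H+ - alpha_H)."""
    W = state.W
    K1 = W.shape[1]
    lhs = W.T @ W + rho * np.eye(K1)
    rhs = W.T @ problem.X + rho * state.H_plus - state.alpha_H
    return np.linalg.solve(lhs, rhs)


def update_W(state: FactorState, problem: TrackingProblem, rho: float) -> np.ndarray:
    """Ridge update: W <- (rho W+ - alpha_W + X H') (H H' + rho I)^-1."""
    H = state.H
    K1 = H.size
    lhs = np.outer(H, H) + rho * np.eye(K1)
    rhs = rho * state.W_plus - state.alpha_W + np.outer(problem.X, H)
    return np.linalg.solve(lhs.T, rhs.T).T


def rescale(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Push column scale from W into H, keeping the product W @ H fixed.

    W's columns may carry negative entries before projection, so a column
    sum can be arbitrarily small; sums below 1e-12 are clamped to that
    floor rather than inverted directly.
    """
    d = W.sum(axis=0)
    d = np.where(np.abs(d) < _COLSUM_FLOOR, _COLSUM_FLOOR, d)
    return W / d, H * d


def lagrangian(state: FactorState, problem: TrackingProblem, rho: float) -> float:
    """Augmented Lagrangian of the split problem at the current state."""
    fit = problem.X - state.W @ state.H
    anchor = problem.A * (state.W_plus - problem.Y)
    rW = state.W - state.W_plus
    rH = state.H - state.H_plus
    return float(
        0.5 * fit @ fit
        + 0.5 * np.sum(anchor**2)
        + np.sum(state.alpha_W * rW)
        + 0.5 * rho * np.sum(rW**2)
        + state.alpha_H @ rH
        + 0.5 * rho * rH @ rH
    )


def update_duals(state: FactorState, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Dual ascent on the splitting constraints W = W+, H = H+."""
    return (
        state.alpha_W + rho * (state.W - state.W_plus),
        state.alpha_H + rho * (state.H - state.H_plus),
    )


def has_converged(L_prev: float, L_curr: float, tol: float) -> bool:
    """Relative Lagrangian change |L_t - L_{t+1}| / |L_t| <= tol.

    Near L_prev = 0 the ratio is undefined; fall back to the absolute
    difference there.
    """
    diff = abs(L_prev - L_curr)
    if abs(L_prev) < 1e-15:
        return diff <= tol
    return diff / abs(L_prev) <= tol


def solve(problem: TrackingProblem, config: SolverConfig | None = None) -> TrackingResult:
    """Run the ADMM iteration to estimate source proportions.

    Per iteration, in order: H update, W update, column rescaling, H+
    projection, W+ projection, dual updates.  The Lagrangian is evaluated
    after the full iteration and the run stops when its relative change
    drops below ``config.tol`` or at ``config.max_iter``.
    """
    config = config or SolverConfig()
    rho = config.rho
    state = initialize_state(problem, config)
    trace: list[float] = []
    L_prev = lagrangian(state, problem, rho)
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        state.H = update_H(state, problem, rho)
        state.W = update_W(state, problem, rho)
        state.W, state.H = rescale(state.W, state.H)
        state.H_plus = project_H_plus(state, rho)
        state.W_plus = project_W_plus(state, problem, rho)
        state.alpha_W, state.alpha_H = update_duals(state, rho)
        L_curr = lagrangian(state, problem, rho)
        if not np.isfinite(L_curr):
            raise FloatingPointError(
                f"non-finite Lagrangian at iteration {iterations}"
            )
        trace.append(L_curr)
        if has_converged(L_prev, L_curr, config.tol):
            converged = True
            break
        L_prev = L_curr
    return TrackingResult(
        proportions=state.H_plus.copy(),
        source_ids=problem.source_ids,
        iterations=iterations,
        converged=converged,
        lagrangian_trace=np.asarray(trace),
        primal_residual_W=float(np.linalg.norm(state.W - state.W_plus)),
        primal_residual_H=float(np.linalg.norm(state.H - state.H_plus)),
    )
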