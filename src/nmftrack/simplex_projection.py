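"""Closed-form projections onto the probability simplex (water-filling).

Both ADMM projection steps — the source-proportion vector H+ and each
column of the source-profile matrix W+ — reduce to the same separable
quadratic program over the simplex:

    minimize   1/2 * sum_i d_i x_i^2  -  sum_i n_i x_i
    subject to x >= 0,  sum_i x_i = 1,   with all d_i > 0.

The KKT conditions give x_i = max(0, (n_i - beta) / d_i) for a scalar
multiplier beta (the "water level") chosen so the entries sum to one.
Because sum_i max(0, (n_i - beta)/d_i) is continuous, strictly decreasing
where positive, and piecewise linear in beta with breakpoints at the n_i,
the exact beta is found by sorting the numerators and scanning support
sizes — no iterative root finding is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .nmf_core import FactorState, TrackingProblem

__all__ = [
    "WeightedProjectionInput",
    "project_weighted_simplex",
    "project_columns_weighted_simplex",
    "project_H_plus",
    "project_W_plus",
]


@dataclass(frozen=True)
class WeightedProjectionInput:
    """Numerators and (positive) denominators of one water-filling problem."""

    numerators: np.ndarray
    denominators: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.numerators, dtype=float)
        d = np.asarray(self.denominators, dtype=float)
        object.__setattr__(self, "numerators", n)
        object.__setattr__(self, "denominators", d)
        if n.shape != d.shape or n.ndim != 1:
            raise ValueError("numerators and denominators must be equal-length vectors")
        if np.any(d <= 0):
            raise ValueError("denominators must be strictly positive")


def project_weighted_simplex(
    inp: WeightedProjectionInput,
) -> tuple[np.ndarray, float]:
    """Solve the weighted simplex projection; return ``(x, beta)``.

    ``x_i = max(0, (n_i - beta) / d_i)`` with ``sum(x) == 1``.  The support
    consists of the entries with the largest numerators; scanning supports
    in descending-numerator order, the water level for support size k is

        beta_k = (sum_{i<=k} n_i/d_i - 1) / sum_{i<=k} 1/d_i

    and the correct k is the largest one keeping every included entry
    positive (``n_(k) > beta_k``).  Ties among equal numerators enter or
    leave the support together, so no tie-breaking rule is needed.
    """
    n = inp.numerators
    d = inp.denominators
    order = np.argsort(-n)
    n_sorted = n[order]
    d_sorted = d[order]
    cum_ratio = np.cumsum(n_sorted / d_sorted)
    cum_inv = np.cumsum(1.0 / d_sorted)
    betas = (cum_ratio - 1.0) / cum_inv
    # largest support size whose smallest included numerator stays above beta
    positive = n_sorted > betas
    k = int(np.nonzero(positive)[0].max()) if positive.any() else 0
    beta = float(betas[k])
    x = np.maximum(0.0, (n - beta) / d)
    # exact renormalization absorbs accumulated float error (sum is ~1 already)
    x /= x.sum()
    return x, beta


def project_H_plus(state: "FactorState", rho: float) -> np.ndarray:
    """Project the proportion vector: n_i = alpha_H_i + rho*H_i, d_i = rho."""
    n = state.alpha_H + rho * state.H
    d = np.full_like(n, rho)
    x, _ = project_weighted_simplex(WeightedProjectionInput(n, d))
    return x


def project_columns_weighted_simplex(N: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Columnwise water-filling: vectorized over the columns of N and D.

    Equivalent to :func:`project_weighted_simplex` applied per column;
    batched because the solver projects every column of W each iteration.
    """
    if np.any(D <= 0):
        raise ValueError("denominators must be strictly positive")
    # row-major layout: one projection problem per row of the transposed arrays
    Nt = np.ascontiguousarray(N.T)
    Dt = np.ascontiguousarray(D.T)
    order = np.argsort(-Nt, axis=1)
    n_sorted = np.take_along_axis(Nt, order, axis=1)
    d_sorted = np.take_along_axis(Dt, order, axis=1)
    betas = (np.cumsum(n_sorted / d_sorted, axis=1) - 1.0) / np.cumsum(
        1.0 / d_sorted, axis=1
    )
    positive = n_sorted > betas
    idx = np.arange(Nt.shape[1])
    k = np.max(np.where(positive, idx, 0), axis=1)
    beta = betas[np.arange(Nt.shape[0]), k]
    Xt = np.maximum(0.0, (Nt - beta[:, None]) / Dt)
    Xt /= Xt.sum(axis=1, keepdims=True)
    return Xt.T.copy()


def project_W_plus(
    state: "FactorState", problem: "TrackingProblem", rho: float
) -> np.ndarray:
    """Project every column of W onto the taxon simplex.

    Column j uses n_ij = A_ij^2*Y_ij + alpha_W_ij + rho*W_ij and
    d_ij = A_ij^2 + rho.  For the unknown column (A = 0) this reduces to
    the same form as the H+ projection.
    """
    A2 = problem.A**2
    N = A2 * problem.Y + state.alpha_W + rho * state.W
    D = A2 + rho
    return project_columns_weighted_simplex(N, D)
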