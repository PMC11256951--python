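"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the projection oracle
enumerates every support set instead of water-filling, and the Lagrangian
oracle accumulates scalar terms in loops instead of vectorized algebra.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def active_set_projection(n: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive KKT search for min 1/2*sum d x^2 - sum n x on the simplex.

    Tries every nonempty support S: solves for the multiplier beta from the
    equality constraint restricted to S, then accepts iff all included
    entries are non-negative and all excluded entries satisfy n_i <= beta.
    """
    m = n.size
    best: tuple[np.ndarray, float] | None = None
    for size in range(1, m + 1):
        for support in combinations(range(m), size):
            S = list(support)
            beta = (np.sum(n[S] / d[S]) - 1.0) / np.sum(1.0 / d[S])
            x = np.zeros(m)
            x[S] = (n[S] - beta) / d[S]
            if np.any(x[S] < -1e-12):
                continue
            out = [i for i in range(m) if i not in support]
            if out and np.any(n[out] - beta > 1e-12):
                continue
            best = (np.maximum(x, 0.0), float(beta))
    assert best is not None, "no KKT point found (should be impossible)"
    return best


def quadratic_objective(x: np.ndarray, n: np.ndarray, d: np.ndarray) -> float:
    return float(0.5 * np.sum(d * x**2) - np.sum(n * x))


def lagrangian_reference(
    X: np.ndarray,
    Y: np.ndarray,
    A: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    W_plus: np.ndarray,
    H_plus: np.ndarray,
    alpha_W: np.ndarray,
    alpha_H: np.ndarray,
    rho: float,
) -> float:
    """Term-by-term scalar-loop evaluation of the augmented Lagrangian."""
    N, K1 = W.shape
    total = 0.0
    for i in range(N):
        fit = X[i] - sum(W[i, j] * H[j] for j in range(K1))
        total += 0.5 * fit * fit
    for i in range(N):
        for j in range(K1):
            anchor = A[i, j] * (W_plus[i, j] - Y[i, j])
            total += 0.5 * anchor * anchor
            rw = W[i, j] - W_plus[i, j]
            total += alpha_W[i, j] * rw + 0.5 * rho * rw * rw
    for j in range(K1):
        rh = H[j] - H_plus[j]
        total += alpha_H[j] * rh + 0.5 * rho * rh * rh
    return total


def simplex_grid(dim: int, step: float) -> np.ndarray:
    """All points of the regular grid on the (dim-1)-simplex with spacing step."""
    ticks = int(round(1.0 / step))
    points = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            points.append(prefix + [remaining])
            return
        for v in range(remaining + 1):
            rec(prefix + [v], remaining - v, slots - 1)

    rec([], ticks, dim)
    return np.asarray(points, dtype=float) * step
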