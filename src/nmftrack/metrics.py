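"""Evaluation metrics: Jensen-Shannon divergence, Pearson correlation,
identified-source precision/recall, and alpha diversity.

JSD convention: by default :func:`jsd` returns the Jensen-Shannon
*distance* — the square root of ``(KL(p||m) + KL(q||m)) / 2`` in natural
logarithms, where ``m`` is the elementwise mean of the two distributions.
Under this convention the maximum (disjoint supports) is ``sqrt(ln 2)``,
about 0.8326.  ``sqrt=False`` and ``base=2`` give the plain divergence and
the bit-scaled variant (whose no-sqrt form ranges over [0, 1]).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_proportion_vector",
    "kl_divergence",
    "jsd",
    "pcc",
    "identified_source_metrics",
    "alpha_diversity",
]


def as_proportion_vector(values: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Validate and renormalize a vector expected to lie on the simplex.

    Accepts sums within ``atol`` of 1 (renormalizing exactly); anything
    else is an error.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty proportion vector")
    if np.any(v < 0):
        raise ValueError("proportion vector has negative entries")
    total = v.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"proportion vector sums to {total}, expected 1")
    return v / total


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence sum p_i ln(p_i / q_i), in nats.

    Terms with ``p_i = 0`` contribute zero; ``q_i = 0`` with ``p_i > 0``
    yields ``inf``.
    """
    p = as_proportion_vector(p)
    q = as_proportion_vector(q)
    if p.size != q.size:
        raise ValueError("distributions differ in length")
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def jsd(p: np.ndarray, q: np.ndarray, *, sqrt: bool = True, base: float | None = None) -> float:
    """Jensen-Shannon dissimilarity between two probability vectors.

    Default: square root of the natural-log divergence (the metric form).
    ``base`` rescales the logarithm (e.g. 2 for bits); ``sqrt=False``
    returns the divergence itself.
    """
    p = as_proportion_vector(p)
    q = as_proportion_vector(q)
    m = 0.5 * (p + q)
    div = 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)
    if base is not None:
        div /= np.log(base)
    div = max(div, 0.0)  # guard tiny negative round-off at p == q
    return float(np.sqrt(div)) if sqrt else float(div)


def pcc(p: np.ndarray, q: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length vectors."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.size != q.size or p.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(p) == 0 or np.std(q) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(p, q)[0, 1])


def identified_source_metrics(
    truth: np.ndarray,
    estimate: np.ndarray,
    threshold: float = 0.01,
) -> tuple[float, float]:
    """Precision and recall of identified reference sources.

    A source counts as identified when its estimated proportion exceeds
    ``threshold`` and as truly present when its true proportion is
    positive.  Only reference sources are scored — pass vectors without
    the unknown entry.  Empty denominators yield 1.0.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    t = np.asarray(truth, dtype=float).ravel()
    e = np.asarray(estimate, dtype=float).ravel()
    if t.size != e.size:
        raise ValueError("truth and estimate differ in length")
    identified = e > threshold
    present = t > 0
    tp = int(np.sum(identified & present))
    precision = tp / identified.sum() if identified.any() else 1.0
    recall = tp / present.sum() if present.any() else 1.0
    return float(precision), float(recall)


def alpha_diversity(profile: np.ndarray) -> tuple[float, int]:
    """Shannon entropy (nats) and observed-taxon count of one profile.

    Accepts counts or proportions; normalizes internally.
    """
    v = np.asarray(profile, dtype=float).ravel()
    if np.any(v < 0):
        raise ValueError("profile has negative entries")
    total = v.sum()
    if total <= 0:
        raise ValueError("profile has zero total abundance")
    p = v / total
    nz = p[p > 0]
    shannon = float(-np.sum(nz * np.log(nz)))
    return shannon, int(nz.size)
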