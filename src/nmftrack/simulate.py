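"""Synthetic benchmark generators for source tracking.

Two generation protocols are provided, mirroring the standard simulation
designs for evaluating source-tracking tools on community data:

* **noise-free**: K+U sparse source profiles are drawn from a synthetic
  pool; F of the K reference sources are designated irrelevant (true
  proportion zero) and the U extra sources are unknown (no observed
  reference profile).  Mixing proportions come from a Pareto distribution,
  the sink is the proportion-weighted mixture of the true profiles, and
  each observed reference profile is a finite-depth multinomial resample
  of its true profile.
* **noisy**: each of K true sources is the combined profile of G distinct
  pool samples, while its observed counterpart is resampled from only V of
  those G samples (V <= G).  Decreasing V widens the gap between the
  profiles actually mixed into the sink and the profiles the solver sees.
  Unknown and irrelevant sources are single pool samples.

The synthetic pool emulates environmental survey data (such as the Earth
Microbiome Project tables used for published benchmarks): each source
occupies a small random taxon support — a few percent of the taxon set —
with Dirichlet-distributed abundances, so distinct sources overlap little
and pairwise Jensen-Shannon distances are high unless supports are forced
to overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import identified_source_metrics, jsd, pcc
from .abundance_io import AbundanceTable
from .nmf_core import SolverConfig, build_problem, solve

__all__ = [
    "SourcePool",
    "MixtureDesign",
    "SimulationTruth",
    "SweepConfig",
    "synth_source_pool",
    "pairwise_jsd_matrix",
    "select_source_set",
    "generate_noise_free",
    "generate_noisy",
    "run_benchmark_sweep",
]


@dataclass(frozen=True)
class SourcePool:
    """A bank of column-normalized source profiles to draw benchmarks from."""

    profiles: np.ndarray  # (n_taxa, n_sources), columns on the simplex
    taxon_ids: tuple[str, ...]
    source_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        P = np.asarray(self.profiles, dtype=float)
        object.__setattr__(self, "profiles", P)
        if P.ndim != 2 or P.shape[1] < 2:
            raise ValueError("pool needs at least two source columns")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError("pool columns must be simplex vectors")

    @property
    def n_taxa(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_sources(self) -> int:
        return self.profiles.shape[1]

    def subset(self, source_ids: tuple[str, ...] | list[str]) -> "SourcePool":
        idx = [self.source_ids.index(s) for s in source_ids]
        return SourcePool(self.profiles[:, idx], self.taxon_ids, tuple(source_ids))


@dataclass(frozen=True)
class MixtureDesign:
    """Design of one simulated sink.

    K reference sources (F of them irrelevant, true proportion zero), U
    unknown sources whose proportions sum to ``unknown_total``, Pareto-
    distributed proportions with the given shape, and multinomial
    observation at ``depth`` counts per profile (``depth=None`` keeps
    exact profiles, for closed-loop checks).
    """

    K: int
    U: int = 0
    F: int = 0
    unknown_total: float = 0.5
    pareto_shape: float = 3.0
    depth: int | None = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.U < 0 or self.F < 0 or self.F > self.K:
            raise ValueError("need 0 <= F <= K and U >= 0")
        if not 0.0 <= self.unknown_total <= 1.0:
            raise ValueError("unknown_total must lie in [0, 1]")
        if self.U == 0 and self.unknown_total != 0.0:
            raise ValueError("unknown_total must be 0 when U = 0")
        if self.U > 0 and self.unknown_total == 0.0:
            raise ValueError("unknown sources need a positive unknown_total")
        if self.pareto_shape <= 0:
            raise ValueError("pareto_shape must be positive")
        if self.depth is not None and self.depth < 1:
            raise ValueError("depth must be a positive count or None")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated sink plus the solver-facing inputs."""

    taxon_ids: tuple[str, ...]
    source_ids: tuple[str, ...]  # K + U ids: references first, unknowns last
    true_profiles: np.ndarray  # (N, K+U) mixed profiles, columns normalized
    observed_profiles: np.ndarray  # (N, K) observed reference profiles
    sink: np.ndarray  # (N,) sink profile, sums to 1
    proportions: np.ndarray  # (K+U,) true proportions, sums to 1
    is_irrelevant: np.ndarray  # (K+U,) bool; zero-proportion references
    is_unknown: np.ndarray  # (K+U,) bool

    @property
    def n_references(self) -> int:
        return self.observed_profiles.shape[1]

    @property
    def unknown_total(self) -> float:
        return float(self.proportions[self.is_unknown].sum())

    def reference_table(self) -> AbundanceTable:
        ref_ids = tuple(np.asarray(self.source_ids)[~self.is_unknown])
        return AbundanceTable(self.taxon_ids, ref_ids, self.observed_profiles)

    def solver_truth(self) -> np.ndarray:
        """True proportions in solver layout: K references then unknown total."""
        return np.append(self.proportions[~self.is_unknown], self.unknown_total)


def synth_source_pool(
    n_taxa: int,
    n_sources: int,
    sparsity: float = 0.05,
    concentration: float = 1.0,
    seed: int = 0,
) -> SourcePool:
    """Draw a pool of sparse Dirichlet source profiles.

    Each source occupies ``round(sparsity * n_taxa)`` taxa on a uniformly
    random support; within-support abundances follow a symmetric Dirichlet
    with the given concentration.  Deterministic per seed.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    support_size = int(round(sparsity * n_taxa))
    if support_size < 1:
        raise ValueError("sparsity * n_taxa must be at least 1 taxon")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    P = np.zeros((n_taxa, n_sources))
    for j in range(n_sources):
        support = rng.choice(n_taxa, size=support_size, replace=False)
        P[support, j] = rng.dirichlet(np.full(support_size, concentration))
    taxon_ids = tuple(f"taxon_{i:05d}" for i in range(n_taxa))
    source_ids = tuple(f"pool_{j:04d}" for j in range(n_sources))
    return SourcePool(P, taxon_ids, source_ids)


def pairwise_jsd_matrix(profiles: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise Jensen-Shannon distances of columns."""
    m = profiles.shape[1]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = jsd(profiles[:, i], profiles[:, j])
    return D


_JSD_MAX = float(np.sqrt(np.log(2.0)))


def select_source_set(
    pool: SourcePool,
    target_jsd: float,
    jsd_window: float = 0.05,
    set_size: int = 20,
    relax_step: float = 0.05,
) -> list[str]:
    """Greedy selection of a source set with a prescribed inter-source JSD.

    Pairs whose JSD falls within ``target_jsd +/- jsd_window`` form the
    candidate graph.  The source participating in the most in-window pairs
    seeds the set; each following pick must be in-window with *every*
    already-selected source and, among those, has the highest pair count.
    Whenever no candidate qualifies, the window widens by ``relax_step``
    on each side, up to the full JSD range; if the set still cannot be
    completed, an error is raised.
    """
    if pool.n_sources < set_size:
        raise ValueError("pool smaller than requested set size")
    D = pairwise_jsd_matrix(pool.profiles)
    window = jsd_window
    while True:
        lo, hi = target_jsd - window, target_jsd + window
        in_window = (D >= lo) & (D <= hi)
        np.fill_diagonal(in_window, False)
        counts = in_window.sum(axis=1)
        if counts.max() > 0:
            selected = [int(np.argmax(counts))]
            while len(selected) < set_size:
                ok = np.all(in_window[:, selected], axis=1)
                ok[selected] = False
                if not ok.any():
                    break
                cand = np.nonzero(ok)[0]
                selected.append(int(cand[np.argmax(counts[cand])]))
            if len(selected) == set_size:
                return [pool.source_ids[i] for i in selected]
        if lo <= 0.0 and hi >= _JSD_MAX:
            raise ValueError(
                f"cannot assemble {set_size} sources near JSD {target_jsd} "
                "even with a fully relaxed window"
            )
        window += relax_step


def _pareto_proportions(rng: np.random.Generator, n: int, shape: float) -> np.ndarray:
    # classical Pareto with x_min = 1: 1 + Lomax draw
    draws = 1.0 + rng.pareto(shape, size=n)
    return draws / draws.sum()


def _observe(
    rng: np.random.Generator, profile: np.ndarray, depth: int | None
) -> np.ndarray:
    if depth is None:
        return profile.copy()
    counts = rng.multinomial(depth, profile / profile.sum())
    if counts.sum() == 0:  # unreachable for depth >= 1; defensive
        return profile.copy()
    return counts / counts.sum()


def generate_noise_free(
    pool_subset: SourcePool, design: MixtureDesign
) -> SimulationTruth:
    """Generate one sink from K+U exact pool profiles (Fig-2a-style design).

    ``pool_subset`` must hold exactly K+U columns: the first K become
    reference sources, the last U unknown.  F of the references are chosen
    uniformly at random as irrelevant (proportion zero); the remaining
    reference proportions are Pareto draws normalized to
    ``1 - unknown_total`` and the unknown proportions to ``unknown_total``.
    The sink mixes the *true* profiles; the observed reference profiles
    are multinomial resamples at ``design.depth``.
    """
    K, U, F = design.K, design.U, design.F
    if pool_subset.n_sources != K + U:
        raise ValueError(f"pool subset must have K+U = {K + U} columns")
    if K - F == 0 and design.unknown_total < 1.0:
        raise ValueError("no contributing reference source: K - F = 0 "
                         "requires unknown_total = 1")
    rng = np.random.default_rng(design.seed)
    S = pool_subset.profiles
    p = np.zeros(K + U)
    irrelevant = np.zeros(K + U, dtype=bool)
    if F:
        irrelevant[rng.choice(K, size=F, replace=False)] = True
    unknown = np.zeros(K + U, dtype=bool)
    unknown[K:] = True
    contributing = ~irrelevant & ~unknown
    if contributing.any():
        p[contributing] = (1.0 - design.unknown_total) * _pareto_proportions(
            rng, int(contributing.sum()), design.pareto_shape
        )
    if U:
        p[unknown] = design.unknown_total * _pareto_proportions(
            rng, U, design.pareto_shape
        )
    sink = S @ p
    sink = sink / sink.sum()
    observed = np.column_stack(
        [_observe(rng, S[:, j], design.depth) for j in range(K)]
    )
    return SimulationTruth(
        taxon_ids=pool_subset.taxon_ids,
        source_ids=pool_subset.source_ids,
        true_profiles=S.copy(),
        observed_profiles=observed,
        sink=sink,
        proportions=p,
        is_irrelevant=irrelevant,
        is_unknown=unknown,
    )


def generate_noisy(
    pool: SourcePool,
    G: int,
    V: int,
    design: MixtureDesign,
) -> SimulationTruth:
    """Generate one sink whose observed sources are degraded (Fig-2b-style).

    Each of the K mixture sources is the normalized sum of G distinct pool
    samples; its observed profile is a multinomial resample of only a
    random V-subset of those G samples.  The U unknown and F irrelevant
    sources are single pool samples (irrelevant ones observed directly).
    All groups and singletons are disjoint draws from the pool.
    """
    if not 1 <= V <= G:
        raise ValueError("need 1 <= V <= G")
    K, U, F = design.K, design.U, design.F
    need = K * G + U + F
    if pool.n_sources < need:
        raise ValueError(f"pool has {pool.n_sources} samples, need {need}")
    rng = np.random.default_rng(design.seed)
    chosen = rng.choice(pool.n_sources, size=need, replace=False)
    groups = chosen[: K * G].reshape(K, G)
    singles = chosen[K * G:]

    N = pool.n_taxa
    true_profiles = np.zeros((N, K + F + U))
    observed = np.zeros((N, K + F))
    for j in range(K):
        members = pool.profiles[:, groups[j]]
        mixed = members.sum(axis=1)
        true_profiles[:, j] = mixed / mixed.sum()
        sub = members[:, rng.choice(G, size=V, replace=False)].sum(axis=1)
        observed[:, j] = _observe(rng, sub / sub.sum(), design.depth)
    for i in range(F):
        col = pool.profiles[:, singles[i]]
        true_profiles[:, K + i] = col
        observed[:, K + i] = _observe(rng, col, design.depth)
    for i in range(U):
        true_profiles[:, K + F + i] = pool.profiles[:, singles[F + i]]

    p = np.zeros(K + F + U)
    irrelevant = np.zeros(K + F + U, dtype=bool)
    irrelevant[K: K + F] = True
    unknown = np.zeros(K + F + U, dtype=bool)
    unknown[K + F:] = True
    p[:K] = (1.0 - design.unknown_total) * _pareto_proportions(
        rng, K, design.pareto_shape
    )
    if U:
        p[unknown] = design.unknown_total * _pareto_proportions(
            rng, U, design.pareto_shape
        )
    sink = true_profiles @ p
    sink = sink / sink.sum()
    source_ids = tuple(
        [f"mixed_{j:02d}" for j in range(K)]
        + [f"irrelevant_{i:02d}" for i in range(F)]
        + [f"unknown_{i:02d}" for i in range(U)]
    )
    return SimulationTruth(
        taxon_ids=pool.taxon_ids,
        source_ids=source_ids,
        true_profiles=true_profiles,
        observed_profiles=observed,
        sink=sink,
        proportions=p,
        is_irrelevant=irrelevant,
        is_unknown=unknown,
    )


@dataclass(frozen=True)
class SweepConfig:
    """Settings for a benchmark sweep over unknown totals (and V, if noisy)."""

    mode: str = "noise-free"  # or "noisy"
    K: int = 10
    U: int = 5
    F: int = 5
    unknown_totals: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    pareto_shape: float = 3.0
    depth: int | None = 10_000
    replicates: int = 3
    seed: int = 0
    # noisy-mode parameters
    G: int = 10
    v_values: tuple[int, ...] = tuple(range(1, 11))
    # synthetic pool parameters
    n_taxa: int = 2000
    n_sources: int = 200
    sparsity: float = 0.05
    concentration: float = 1.0
    # optional divergence targeting for the noise-free source set
    target_jsd: float | None = None
    jsd_window: float = 0.05
    # metrics
    identification_threshold: float = 0.01
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("noise-free", "noisy"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")


def _evaluate_truth(
    truth: SimulationTruth, config: SweepConfig
) -> dict[str, float]:
    sources = truth.reference_table()
    problem = build_problem(sources, truth.sink, config.solver)
    result = solve(problem, config.solver)
    t = truth.solver_truth()
    e = result.proportions
    precision, recall = identified_source_metrics(
        t[:-1], e[:-1], config.identification_threshold
    )
    ref_mask = ~truth.is_unknown
    mix_obs = [
        jsd(truth.true_profiles[:, j], truth.observed_profiles[:, jj])
        for jj, j in enumerate(np.nonzero(ref_mask)[0])
    ]
    irrelevant_ref = truth.is_irrelevant[ref_mask]
    return {
        "proportion_jsd": jsd(t, e),
        "proportion_pcc": pcc(t, e),
        "precision": precision,
        "recall": recall,
        "unknown_true": truth.unknown_total,
        "unknown_est": result.unknown_proportion,
        "irrelevant_est_mean": (
            float(e[:-1][irrelevant_ref].mean()) if irrelevant_ref.any() else np.nan
        ),
        "irrelevant_estimates": ";".join(
            format(x, ".6g") for x in e[:-1][irrelevant_ref]
        ),
        "mixing_observed_jsd": float(np.mean(mix_obs)),
        "iterations": result.iterations,
        "converged": float(result.converged),
    }


def run_benchmark_sweep(config: SweepConfig) -> pd.DataFrame:
    """Generate-solve-score every design point; one row per point/replicate.

    Deterministic for a fixed config: sub-seeds for the pool and each
    design point derive from ``config.seed`` via a spawned seed sequence.
    """
    root = np.random.SeedSequence(config.seed)
    pool_seed, *_ = root.generate_state(1)
    pool = synth_source_pool(
        config.n_taxa,
        config.n_sources,
        config.sparsity,
        config.concentration,
        seed=int(pool_seed % (2**31)),
    )
    rows = []
    point_seeds = root.spawn(1)[0].generate_state(10_000)
    counter = 0
    v_grid: tuple[int | None, ...] = (
        config.v_values if config.mode == "noisy" else (None,)
    )
    for v in v_grid:
        for unknown_total in config.unknown_totals:
            for rep in range(config.replicates):
                seed = int(point_seeds[counter] % (2**31))
                counter += 1
                design = MixtureDesign(
                    K=config.K,
                    U=config.U,
                    F=config.F,
                    unknown_total=unknown_total,
                    pareto_shape=config.pareto_shape,
                    depth=config.depth,
                    seed=seed,
                )
                if config.mode == "noise-free":
                    if config.target_jsd is not None:
                        ids = select_source_set(
                            pool,
                            config.target_jsd,
                            config.jsd_window,
                            set_size=config.K + config.U,
                        )
                    else:
                        rng = np.random.default_rng(seed)
                        ids = [
                            pool.source_ids[i]
                            for i in rng.choice(
                                pool.n_sources, config.K + config.U, replace=False
                            )
                        ]
                    truth = generate_noise_free(pool.subset(ids), design)
                else:
                    truth = generate_noisy(pool, config.G, int(v), design)
                row = {
                    "mode": config.mode,
                    "v": np.nan if v is None else int(v),
                    "unknown_total": unknown_total,
                    "replicate": rep,
                    "seed": seed,
                }
                row.update(_evaluate_truth(truth, config))
                rows.append(row)
    return pd.DataFrame(rows)
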