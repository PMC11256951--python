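# Methods

## The source-tracking model

A sink (target) microbiome sample is modeled as a mixture of K candidate
source communities plus one aggregate unknown source. Let `X ∈ R^N` be the
sink's relative taxon abundances (N taxa, `Σ X_i = 1`), and let
`Y ∈ R^{N×K}` hold the observed reference profiles, column-normalized.
Because the community a source actually contributed to the sink can drift
from the profile observed for that source, the actual per-source profiles
`W ∈ R^{N×(K+1)}` are estimated jointly with the mixing proportions
`H ∈ R^{K+1}`:

    minimize   ½‖X − WH‖²_F  +  ½‖A ∘ (W − Y)‖²_F
    subject to W ≥ 0, H ≥ 0, Σ_j H_j = 1, Σ_i W_ij = 1 for every column j.

The binary mask `A` has ones over the K reference columns and zeros over
the appended unknown column, so the unknown profile is constrained only to
be a valid composition. `H` at the optimum is the estimate: its first K
entries are the reference-source proportions, the last entry the total
unknown contribution.

## ADMM solution

The simplex constraints are split onto copies `W⁺, H⁺` and the augmented
Lagrangian (penalty ρ, duals `α_W, α_H`) is minimized block-wise. One
iteration performs, in order:

1. `H ← (WᵀW + ρI)⁻¹ (WᵀX + ρH⁺ − α_H)` — ridge-regularized least squares;
2. `W ← (ρW⁺ − α_W + XHᵀ)(HHᵀ + ρI)⁻¹` — the matching row-wise solve;
3. column rescaling `W ← WD⁻¹`, `H ← DH` with `D_jj = Σ_i W_ij`, which
   restores unit column sums without changing the product `WH`;
4. projection of `H` onto the probability simplex and of every column of
   `W` onto the taxon simplex, giving `H⁺` and `W⁺`;
5. dual ascent `α ← α + ρ(primal − copy)`.

Both projections are weighted simplex projections
`min ½Σ d_i x_i² − Σ n_i x_i` s.t. `x ∈ Δ`, solved in closed form by
water-filling: `x_i = max(0, (n_i − β)/d_i)` with the level β chosen so
the entries sum to one. β is found exactly by sorting the numerators and
scanning support sizes (O(n log n)); no iterative root-finding is
involved, so results are deterministic to machine precision. Ties among
equal numerators enter or leave the support together; all-negative
numerators still yield a valid simplex point.

Iteration stops when the relative Lagrangian change
`|L_t − L_{t+1}|/|L_t|` drops to the threshold (default 1e−6) or at the
iteration cap (default 2000), with ρ = 1 by default. When `|L_t|` is
below 1e−15 the absolute difference is used instead, since the relative
criterion is undefined at zero. On sparse synthetic data both loss terms
can approach zero at the optimum, in which case the relative criterion
may never fire and the run legitimately ends at the iteration cap; the
returned proportions are accurate there, and `TrackingResult.converged`
records which rule ended the run.

### Initialization

The objective is not strictly convex and admits degenerate global optima:
because the unknown column of `W` is unanchored, it can replicate any
convex combination of reference profiles and absorb part of their mass
without changing the loss. Which optimum ADMM reaches is decided by the
starting point. The default initialization therefore seeds the solver
with a non-negative least-squares (NNLS) fit of the sink on the reference
profiles: `H` starts at the NNLS coefficients with the residual mass
assigned to the unknown entry, and the unknown column of `W` starts at
the normalized positive residual `max(0, X − Y c)` — the sink mass the
references cannot explain (uniform if that residual is zero). This starts
the iteration inside the basin where references explain what they can and
the unknown absorbs only the remainder; with exact reference profiles the
seed is already optimal and the solver confirms it in one iteration.
`W = W⁺ = Y` (with the seeded unknown column), duals start at zero.
`SolverConfig(init="uniform")` instead starts `H` at `1/(K+1)`, which
reaches the same fit quality but can leave substantially more mass on the
unknown source in the degenerate cases above; it is retained for
comparison. The solver is deterministic for fixed inputs either way.

Each sink is an independent problem; multiple sinks are solved
sequentially.

## Evaluation metrics

* **JSD** — reported as the Jensen-Shannon *distance*: the square root of
  `½KL(p‖m) + ½KL(q‖m)` with natural logarithms and `m = (p+q)/2`. Under
  this convention two disjoint compositions score `√ln2 ≈ 0.8326`, and
  the reference four-source example `{0.1,0.2,0.3,0.4}` vs
  `{0.01,0.05,0.1,0.84}` scores 0.334 with a Pearson correlation of
  0.830. `sqrt=False` and `base=2` select the plain divergence and the
  bit-scaled variant whose no-sqrt form ranges over [0, 1].
* **PCC** — plain Pearson correlation of true vs estimated proportion
  vectors; captures trend rather than magnitude.
* **Identified-source precision/recall** — a reference source counts as
  identified when its estimate exceeds a threshold (default 0.01, an
  order of magnitude below the "low-abundance" design regime of < 0.1)
  and as truly present when its true proportion is positive; the unknown
  entry is excluded. Empty denominators score 1.
* **Alpha diversity** — Shannon entropy (nats) and observed-taxon count,
  used to characterize generated source profiles.

## Synthetic benchmarks

The generator emulates environmental-survey source pools of the kind used
in published source-tracking benchmarks (sparse profiles in a large taxon
space): each pool source occupies a uniformly random taxon support of
`sparsity × n_taxa` taxa with symmetric-Dirichlet abundances. Defaults:
`n_taxa = 2000`, `n_sources = 200`, `sparsity = 0.05`, concentration 1 —
sized so a full generate-solve-score sweep runs in minutes on a laptop
while keeping the sparse, high-divergence character of real survey
tables (random source pairs score ≈ 0.8 JSD).

**Noise-free protocol.** K + U sources are drawn from the pool (optionally
via the greedy divergence-targeted selection below); F of the K references
are designated irrelevant and given true proportion zero. The remaining
proportions are Pareto draws (shape 3.0 by default; the shape is a free
parameter of the protocol) normalized so the U unknown sources sum to
`unknown_total` and the contributing references to the rest. The sink is
the proportion-weighted mixture of the *true* profiles; each observed
reference is a multinomial resample of its true profile at `depth` counts
(default 10 000). `depth=None` is an exact-profile mode used by
closed-loop tests.

**Noisy protocol.** Each of K true sources is the normalized sum of G
(default 10) distinct pool samples; its observed counterpart is a
multinomial resample of the normalized sum of a random V-subset of those
G samples (1 ≤ V ≤ G). V = G reproduces the noise-free observation model;
V = 1 maximizes the disparity between mixed and observed sources. The U
unknown and F irrelevant sources are single pool samples, so the
reference table holds K + F columns here (the irrelevant singletons are
observed directly).

**Divergence-targeted selection.** To build source sets with a prescribed
mean pairwise JSD, pairs within `target ± window` form a candidate graph;
the source in the most in-window pairs seeds the set and each addition
must be in-window with all previous picks, preferring high pair counts.
When stuck, the window widens by 0.05 per side up to the full range, and
selection fails only if the full range cannot complete the set.

**Sweep harness.** `run_benchmark_sweep` runs
generate → solve → score over an unknown-total grid (and a V grid in
noisy mode), emitting one row per design point and replicate with
proportion-JSD, PCC, precision/recall, unknown-total error, per-source
irrelevant estimates, and the mixing/observed disparity. All randomness
derives from one seed via spawned sub-sequences, so a sweep is exactly
reproducible.

### What the generator does not model

Real taxon tables carry compositional correlations between related
sources, lineage structure among taxa, and over-dispersed (non-
multinomial) count noise; pool supports here are independent and
uniform. Passing benchmarks therefore demonstrate the solver's behavior
under controlled divergence, missing-source and observation-noise
regimes — not performance on any particular environmental cohort.
Low-abundance taxa are never filtered before solving.

## Numerical choices

* Taxon alignment takes the sorted union of source and sink taxa,
  zero-filling absences: sink taxa absent from every reference carry the
  unknown-source signal and must be retained. Ordering is lexicographic
  for determinism.
* Raw counts are accepted anywhere; columns are normalized internally.
* Column sums in the rescaling step can be arbitrarily small (W may hold
  negative entries before projection); sums below 1e−12 are clamped to
  that floor rather than inverted.
* Simplex feasibility of `H⁺` and `W⁺` columns holds to 1e−9 at every
  iteration; projections renormalize exactly to absorb accumulated
  floating-point error.
* KL terms with `p_i = 0` contribute zero; the JSD mixture is strictly
  positive wherever either argument is, so JSD is always finite.

## Known limitations

* Proportions for *individual* unknown sources are not identifiable; only
  their total is estimated (one aggregate column).
* The unknown column of `W⁺` exists internally but is not a validated
  deliverable — with partially overlapping sources its composition is
  ambiguous (see the degeneracy discussion above), even when the total
  unknown proportion is well determined.
* When references are nearly collinear (inter-source JSD well below 0.5),
  proportions among them are weakly identified and accuracy degrades for
  any method of this family; the benchmarks quantify this regime rather
  than fix it.
* A command-line `sweep` accepts explicit grid flags rather than a
  configuration file; programmatic use goes through `SweepConfig`.
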