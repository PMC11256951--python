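# nmftrack

Microbial source tracking via reference-anchored non-negative matrix
factorization.

A sampled microbiome ("sink") is usually a blend of communities from
several habitats — skin flora on a keyboard, tube-associated microbes in
an infant gut, contamination in a clinical sample. Given taxa-abundance
profiles for K candidate sources, `nmftrack` estimates the proportion each
source contributes to the sink, plus the total contribution of sources
that were never observed. It is written for microbiome researchers who
need quantitative contribution estimates (contamination monitoring,
colonization tracking) rather than presence/absence calls.

## Model

With `X ∈ Δ^N` the sink's relative taxon abundances and `Y ∈ R^{N×K}` the
column-normalized observed reference profiles, the actual mixed profiles
`W` and mixing proportions `H` are estimated jointly:

```
min_{W,H}  ½‖X − WH‖²_F + ½‖A ∘ (W − Y)‖²_F
s.t.       W ≥ 0, H ≥ 0, Σ_j H_j = 1, Σ_i W_ij = 1 ∀j
```

`W` and `H` carry K+1 columns/entries: the extra, unanchored column (the
mask `A` zeroes it out of the second term) aggregates every unobserved
source. The problem is solved by ADMM with exact water-filling projections
onto the simplex constraints; `H` at termination is the estimate, its last
entry the unknown-source total. See `docs/methods.md` for the update
rules, initialization, and convergence policy.

The package also ships the simulation benchmarks used to validate this
model family — sparse synthetic source pools with controllable pairwise
Jensen–Shannon divergence, Pareto mixing proportions, designated unknown
and irrelevant sources, multinomial observation noise, and a noisy mode
that widens the gap between observed and actually-mixed sources — plus
the standard evaluation metrics (JSD, PCC, identified-source
precision/recall, alpha diversity).

## Worked example

```python
import numpy as np
from nmftrack import (
    MixtureDesign, SolverConfig, build_problem, generate_noise_free,
    jsd, pcc, solve, synth_source_pool,
)

# a 2000-taxon pool of 200 sparse sources; pick 20: 15 references
# (5 of them irrelevant) and 5 unknown contributors
pool = synth_source_pool(n_taxa=2000, n_sources=200, sparsity=0.05, seed=7)
rng = np.random.default_rng(7)
ids = [pool.source_ids[i] for i in rng.choice(200, 20, replace=False)]
design = MixtureDesign(K=15, U=5, F=5, unknown_total=0.3, depth=10_000, seed=7)
truth = generate_noise_free(pool.subset(ids), design)

problem = build_problem(truth.reference_table(), truth.sink)
result = solve(problem, SolverConfig())

estimate = result.proportions          # 15 references + 1 unknown entry
target = truth.solver_truth()
print(f"estimated unknown total: {result.unknown_proportion:.3f} (true {truth.unknown_total:.3f})")
print(f"proportion JSD vs truth: {jsd(target, estimate):.3f}")
print(f"proportion PCC vs truth: {pcc(target, estimate):.3f}")
irr = truth.is_irrelevant[~truth.is_unknown]
print(f"largest irrelevant-source estimate: {estimate[:-1][irr].max():.4f}")
```

Output:

```
estimated unknown total: 0.330 (true 0.300)
proportion JSD vs truth: 0.028
proportion PCC vs truth: 0.997
largest irrelevant-source estimate: 0.0002
```

The solver recovers the designed unknown total to 0.03 on this
high-divergence benchmark, tracks the full proportion vector closely
(JSD 0.028, PCC 0.997 — for scale, two identical vectors score 0 and 1),
and assigns essentially nothing to the five references that truly
contribute nothing.

## Command line

```
nmftrack track    --sources S.tsv --sinks X.tsv --out proportions.tsv
nmftrack simulate --mode noise-free --k 10 --u 5 --f 5 --unknown-total 0.5 --out sim/
nmftrack evaluate --truth sim/truth.tsv --estimate proportions.tsv --out metrics.tsv
nmftrack sweep    --k 10 --u 5 --f 5 --replicates 3 --seed 7 --out sweep.tsv
```

Tables are plain TSV in the FEAST/SourceTracker style: taxa in rows,
samples in columns, identifiers in the first row/column; counts or
relative abundances both work. `track` writes one row per sink whose
columns are the source proportions plus a final `Unknown` column.

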