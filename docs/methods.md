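# Methods

## Pattern model and quality measure

The target structure is the combined shifting-and-scaling pattern
`b_ij = pi_i * alpha_j + beta_j`: each condition column of a coherent
bicluster is an affine image of a common per-gene profile. The measure
used to quantify departure from this model is the transposed Virtual
Error. Given a bicluster B with gene set I and condition set J:

1. virtual condition `rho_i = (1/|J|) sum_j b_ij` (row means);
2. standardize each condition column and `rho` to zero mean and unit
   *population* standard deviation, using statistics computed over the
   bicluster's own genes;
3. `VE^t(B) = (1/(|I||J|)) sum_ij |b_hat_ij - rho_hat_i|`.

Three numerical conventions deserve note:

- **Absolute value.** The sum of *signed* differences is identically zero
  for every bicluster (both the standardized columns and the standardized
  virtual condition have zero mean over genes), so the measure is defined
  with `|·|`. This restores the intended properties: non-negativity, zero
  exactly on pattern-following biclusters, growth with noise.
- **Standardization scope.** Column means/deviations are taken over the
  bicluster's genes, not the full matrix column. Only this choice makes
  VE^t vanish on planted patterns regardless of the surrounding matrix.
- **Degenerate columns.** A zero-variance column (or constant virtual
  condition) standardizes to all zeros rather than raising: constant
  columns are pattern-compatible, and evolved individuals routinely pass
  through such states. Population (divide-by-n) deviation is used; with
  it, all perfect-pattern zero checks are exact to 1e-9 absolute, the
  tolerance used throughout for "perfect pattern" assertions.

Sign convention: the pattern class is implemented with `alpha_j > 0`. A
column anti-correlated with the virtual condition standardizes to
`-rho_hat` and scores positively (a 2x2 bicluster with one anti-oriented
column scores exactly 1). Negative scaling factors are representable in
the model equation but are not treated as matches; VE^t's zero set is
exactly the positive-affine-per-column class, which is what the zero-set
oracle test verifies by brute-force per-column least squares.

Invariances: VE^t is exactly invariant under a global affine rescaling
`x -> a*x + c` (a > 0) of the data, and its zero set is closed under
per-column positive affine maps (they compose with the pattern's own
alpha, beta). The *value* on non-pattern biclusters is not invariant
under per-column maps, because the virtual condition is a raw row mean.

MSR and SMSR are implemented as companion measures for contrast: MSR
vanishes on additive patterns only (the worked multiplicative 2x2
[[1,2],[2,4]] scores 0.0625), SMSR on multiplicative patterns only and
is undefined (raises) when a row or column mean is zero.

## Aggregate objective

`Phi(B) = VE^t(B)/VE^t(M) + w_s*Vol(B) + w_ov*Overlap(B)
+ w_var/(1 + GeneVar(B))`, minimised. Parameters, with defaults:

| weight | default | role |
|--------|---------|------|
| w_g    | 0.25    | shapes the gene-dimension volume addend; larger favours more genes |
| w_c    | 0.5     | same for conditions |
| w_s    | 5.0     | overall weight of the volume reward |
| w_ov   | 5.0     | weight of the overlap penalty |
| w_var  | 0.1     | weight of the inverse-gene-variance term |

All weights are dimensionless; zero disables an objective. The
normalisation by `VE^t(M)` (the whole matrix scored as one bicluster,
computed once and cached) makes the pattern term comparable across
matrices, so the remaining weights need no per-dataset retuning.

Edge cases fixed by continuity or convention: the volume addend at size 1
with weight 0 (a 0/0) is defined as 0; the overlap term of the first
bicluster (denominator `n_b - 1 = 0`) is defined as 0 — there are no
predecessors and the weight matrix is all-zero anyway. A matrix whose
`VE^t(M)` is 0 (e.g. an exact rank-style pattern over the whole matrix)
is rejected as degenerate at fitness construction.

## Genetic search

Individuals are binary strings of length M+N (gene bits then condition
bits). Defaults: population 200, up to 1500 generations, early stop when
the best fitness improves by less than 1e-6 over 150 consecutive
generations, tournament size 3, 80% of non-elite slots filled by
crossover (operator chosen uniformly among one-point, two-point,
uniform), the rest by replication; offspring are mutated with probability
0.1, choosing the simple operator (flip one bit) with probability 0.9 and
the uniform operator (per-bit flip probability 0.005) otherwise. Each
generation keeps the best individual unchanged plus a mutated copy of it,
so the best fitness trajectory is non-increasing by construction.

Values never stated for the original method — population size, mutation
probabilities, the stall tolerance — are exposed as `GAParams` fields
with the defaults above; they were chosen once as conventional GA
settings satisfying the stated qualitative constraints (uniform mutation
much rarer than simple) and recover planted patterns on the downscaled
benchmark without further adjustment.

Initialization draws random 3x3 seeds — 3x3 because any 2x2 already
follows a perfect pattern, making quality comparisons at that size
meaningless — oversampling `seed_oversampling * population_size` (default
10x) candidates and keeping the best. When a planted solution's size is
known (synthetic benchmarks), the seed count can instead be inflated to
`ceil(safety / p)` with `p = C(|I|,3)C(|J|,3) / (C(M,3)C(N,3))` (the
probability a random seed falls inside the solution; binomial-coefficient
reading of the seed-counting rule) and safety 3, so about three
in-solution seeds are expected. Seed evaluation is vectorised over the
whole batch.

Genotypes decoding to fewer than 2 genes or 2 conditions are repaired by
setting random bits: below 2x2 both the measure and the volume term
degenerate, so the search space is kept closed above that size.
Fitness values are memoised per genotype, so elites and converged
populations cost nothing to re-evaluate. All randomness flows from a
single `numpy` generator seeded by `GAParams.rng_seed`; two runs with the
same seed are bit-identical.

The outer sequential-covering loop runs the inner search n times,
incrementing the overlap weight matrix over each found bicluster's cells.
Inner run k uses seed `rng_seed + k`, so any single bicluster's search is
reproducible in isolation. Exact duplicate solutions are permitted (the
overlap penalty is the only deterrent); an optional flag filters them
from the returned list.

## Synthetic benchmark

The generator emulates in-silico recovery experiments: uniform(0, 50)
backgrounds of 2884 genes x 17 conditions; planted pattern sizes 20x10,
60x12, 100x13, 150x15, 200x16; five replicate backgrounds per size; each
clean case paired with a noisy twin (i.i.d. N(0, 0.25) added to every
cell) — 50 cases. Pattern parameters are drawn per case: `pi ~ U(0,10)`,
`alpha ~ U(0.5,3)` (positive, avoiding the negative-scaling ambiguity),
`beta ~ U(-5,5)`; row/column positions are uniform random subsets, not
necessarily contiguous. The background range does not matter for
VE^t-based recovery (global-affine invariance); uniform(0, 50) is a
positive, microarray-like scale. A downscaled profile (300x17 background,
sizes 20x10 and 60x12 only) is provided for fast runs; recovery tests use
it with 5 seeds per case, which keeps the full suite under a minute per
GA run on one core.

What the generator does *not* model: real expression data has correlated
noise, heavy-tailed intensities, missing values and biclusters that only
approximately follow any formula. Passing recovery tests therefore shows
the search machinery can find exact planted structure against an
unstructured background — not that biological biclusters of comparable
quality exist or would be ranked first on real data.

## Match-score evaluation

Gene and condition match scores are Jaccard indexes of the respective
index sets; the bicluster match score is their product. When a result
set is scored against multiple planted truths, each record is assigned
to the truth maximising the bicluster score (ties to the first truth in
order) — the assignment rule is a package choice, since scoring is only
defined pairwise. Summaries report mean ± sample (n−1) standard
deviation of |I|, |J|, VE^t and gene variance; the deviation of a single
record is reported as 0. Friedman-style rank testing across algorithms
is out of scope; the score CSV exported per case is the intended input
for external rank-test tools.

## Known limitations

- The search is single-objective (weighted aggregate); no Pareto front.
- Negative-scaling patterns are scored as non-matching by design.
- Loading rejects missing values rather than imputing them.
- The sequential loop is inherently serial (the overlap matrix creates
  an order dependence between runs).
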