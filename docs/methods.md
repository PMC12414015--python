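# Methods

This note documents the models, conventions and numerical choices behind
`haploselect`, in the order data flows through the package.

## Genotype model and coding conventions

The substrate is an N × 2 × M binary array: N individuals, two haplotype
copies, M mapped markers. At read time every locus is recoded so that
allele 1 is the **major** allele (frequency ≥ 0.5 across all 2N copies);
an exact 50/50 tie keeps the input's allele-1 coding (ALT for VCF, the
column coding for TSV). All downstream effects are therefore "effect of
the major allele". Base-pair positions are 1-based (VCF convention);
in-memory marker indices are 0-based.

Panels of selfing-crop lines are accepted as dosage matrices under
`assume_inbred=True`, which maps dosage 0/2 to identical copies and
rejects dosage 1 — for inbred lines phase is trivial and heterozygous
calls indicate residual outcrossing or genotyping error rather than
usable phase information. Phased VCF input carries explicit phase;
unphased heterozygotes are rejected because the block machinery needs
per-copy allele strings. Missing genotypes are rejected outright:
imputation belongs upstream.

## Trial analysis

**BLUEs.** Genotype means are estimated from `score ~ genotype +
replicate` (both fixed) by least squares; each genotype's BLUE is its
fitted value averaged over replicate levels, so balanced data with no
replicate effect reduce to arithmetic means. The design matrix is rank-
checked first; a genotype observed only in a replicate that contains only
that genotype raises a confounding error instead of returning a silent
pseudo-inverse solution.

**Heritability.** One-way random-effects REML; in the balanced case this
is the expected-mean-squares closed form σ²g = max(0, (MSG − MSE)/n₀)
with the standard n₀ coefficient for mild imbalance. H² is reported on
the **genotype-mean (entry-mean) basis**, σ²g / (σ²g + σ²e/r̄), because
the phenotypes entering downstream prediction are genotype means. The
synthetic generator's `h2` parameter uses the same basis (see below), so
estimator and generator are mutually consistent. A zero-variance trial
yields H² = 0 with a warning rather than an error.

**RR-BLUP.** Effects solve `(W'W + λI)u = W'(y − μ̂)` with W the
column-centred dosage matrix. λ = σ²ₑ/σ²ᵤ can be fixed; the default
estimates it by maximizing the restricted likelihood of the equivalent
single-variance-component model `y = 1μ + g + e`, `g ~ N(0, σ²ᵤ WW')`,
profiled over the scale via the eigenvalues of the intercept-projected
WW' and searched on a 121-point log grid over λ ∈ [1e-5, 1e7]. The grid
is deliberate: the profiled restricted likelihood in one ratio is cheap
to evaluate after one eigendecomposition, and a grid cannot silently
diverge. λ ≤ 0 is rejected (pass a small positive λ for near-OLS
behaviour).

**Trait direction.** All group-fitness functions maximize. For "lower is
better" traits (disease severity on a 1–9 scale) marker effects are
negated once by `desirability_transform` — an involution, with the
intercept untouched — so sign handling lives in exactly one place.

## Haplotype blocks and block values

LD is the squared Pearson correlation of dosage columns. For inbred
panels this equals haplotype r², and it needs no phasing. Monomorphic
loci have undefined r²; the block builder treats such pairs as below
threshold, while the standalone `pairwise_r2` raises.

Blocks are built per chromosome by a greedy left-to-right chain: marker
i+1 joins the open block when r²(i, i+1) ≥ t **or** r²(left boundary,
i+1) ≥ t, the second test being the "flanking marker" rescue. The rule
rechecks only the left boundary; this is a fixed, documented choice
among several defensible readings of boundary-marker rescue. The
comparison is ≥, the default threshold 0.5. Blocks never span
chromosomes, and the output always partitions the map (weak-LD markers
become singletons), which the value catalogue verifies. Raising the
threshold can only split, never merge, blocks.

Block values are plain sums of oriented marker effects over the block's
markers per copy; variant identity is the within-block allele string,
densely re-coded per block. Equal variant codes imply equal values by
construction, and the per-individual total over blocks and copies equals
GEBV minus intercept — an identity the tests check numerically.

## Group fitness

Given the B × N × 2 value tensor and subset size k:

* **OHS** sums, per block, the two largest values among *distinct
  variants* present in the subset's 2k copies. A block with a single
  distinct variant contributes its value twice (a homozygous ultimate
  genotype) rather than being penalized. Distinctness by variant is the
  default; `distinct_by="individual"` instead takes each selected
  individual's better copy and sums the top two across individuals, for
  users who read "two distinct haplotypes" as "two distinct donors".
* **OPV** doubles the per-block maximum over the subset. The max sits
  inside the block sum — the ideal gamete is assembled block-wise — so
  OPV ≥ OHS on every subset.
* **GEBV sum** adds the selected individuals' totals; top-k truncation
  is its exact argmax, which makes it the conventional-selection
  baseline and a free correctness oracle.

A brute-force enumerator (capped at C(N,k) ≤ 2×10⁶) returns the optimum
and *all* tied argmax subsets in lexicographic order; it is the test
oracle for every optimizer.

## Optimizers

All four share: exact cardinality at every evaluation (the problem
object raises on violation), a single `numpy` generator per run seeded
from the config (identical seed ⇒ bit-identical trace), lowest-index
tie-breaks, and a trace of best-so-far and mean fitness per iteration.
Defaults are the tuned values for the motivating wheat-panel problem.

* **GA** (pop 200, 250 generations, crossover 0.8, mutation 0.1,
  tournament 3, elitism 0.1): one-point crossover followed by
  priority-repair with uniform-random priorities; swap mutation flips a
  selected slot with a random unselected one (per-selected-slot
  Bernoulli), preserving k exactly; elites are copied unchanged, so the
  best series is non-decreasing. After 3 improvement-free generations
  the worst half is replaced by fresh random feasible solutions (elites
  are never replaced).
* **DE** (pop 200, 250 generations, F 0.4, CR 0.8): the subset mapping
  the underlying method leaves open is realized as random keys — real
  vectors in [0,1]^N decoded by top-k (stable, lowest index on ties) —
  keeping DE's vector arithmetic intact. Per individual per generation a
  strategy is drawn uniformly from {rand/1/bin, best/1/bin,
  current-to-best/1/bin}, F and CR get ±10% multiplicative uniform
  jitter, binomial crossover guarantees one mutant coordinate, and
  greedy replacement (ties keep the trial) makes the population best
  non-decreasing.
* **PSO** (swarm 100, 100 iterations, c1 1.5, c2 2.0, w 0.5→0.3
  linearly): binary positions with the standard velocity update,
  provisional positions sampled componentwise as Bernoulli(sigmoid(v)),
  then deterministic add/remove repair using sigmoid(v) as priority.
  Personal/global bests update only from repaired (feasible)
  evaluations. The explicit repair mechanism (rather than pure top-k
  decoding) is intentional: particles genuinely leave the feasible
  region and are corrected before evaluation. The 0.5→0.3 inertia
  schedule is the default; any schedule with w_start ≥ w_end is
  configurable.
* **SA** (T₀ 0.01, α 0.96, 10 iterations per temperature, 1000 total):
  single-solution Metropolis walk. The neighbour move is a swap of one
  selected with one unselected index — the minimal modification that
  preserves cardinality (a single bit flip would not). Acceptance is 1
  for non-worse moves, else exp(Δ/T); temperature follows T₀·αᵏ after
  each batch.

## Convergence scoring and comparison

Traces are min–max normalised within themselves on both axes; a
constant best-so-far series maps to y ≡ 1 by convention (the run is
always at its best — min–max is undefined on a zero range). Convergence
efficiency is the trapezoidal AUC of the normalised best-so-far curve
(not the population mean), in [0,1], invariant to affine rescaling of
raw fitness. Wall time is recorded in traces and grids but never
asserted — it is hardware-dependent. Overlap among selected sets is
reported as exclusive Venn-region sizes plus a pairwise intersection
matrix.

## Breeding simulation

Closed recurrent loop, default reference design: 50 parents, half-
diallel (1225 crosses), 50 DH per cross, best 10 DH per cross by genetic
value, next parents = best 15 new lines globally + best 35 retained
previous parents, 100 cycles, 10 replicates. "Best" always means lowest
true genetic value (resistance trait on the raw scale); both the
retained-parent rule and the global (not per-cross) choice of new
parents are fixed interpretations, chosen as best-by-value. Selection
uses true genetic values for every founder strategy — strategies differ
only in their founders — with no per-cycle re-estimation of effects.

Meiosis: per chromosome, crossover count ~ Poisson(length in Morgans),
crossover positions uniform on the genetic map, starting phase a fair
coin; no interference, so Haldane's mapping function holds and the
two-marker recombination fraction at 50 cM is (1 − e⁻¹)/2 ≈ 0.316
(verified by Monte Carlo within 3σ at 10⁵ gametes). Genetic positions
come from the map's cM column or from bp at a constant 1 cM/Mb. A
zero-length map warns and co-inherits whole chromosomes. DH lines
duplicate one gamete and are exactly homozygous.

Per-cycle metrics describe the parent set entering the cycle: mean
genetic value, sample variance of genetic values, and expected
heterozygosity (mean 2p(1−p) over loci, ≤ 0.5 for biallelic loci).

Tests and the acceptance script run a desk-scale configuration —
10 parents, 6 DH per cross, 2 selected per cross, 5+5 parent turnover,
15 cycles, 5–10 replicates — chosen as the smallest design that still
shows the phenomena of interest (directional gain, diversity decline,
and the founder-strategy contrast); the full-scale defaults run the same
code path.

## Synthetic data

The generator emulates an inbred diploid panel with block-structured LD
and a replicated ordinal-like trial. LD is planted, not coalescent:
each chromosome is tiled with fixed-length blocks, and every individual
draws its (identical, inbred) haplotype per block from a small ancestral
pool, independently across blocks. With the default 2-haplotype pool the
ancestors are complementary, so within-block r² is exactly 1 whenever
both ancestors are present and between-block r² is pure sampling noise —
which makes planted-boundary recovery an exact, deterministic check.
Larger pools are random haplotypes nudged to stay polymorphic.

Marker effects are centred Gaussian. `h2` is **entry-mean** heritability
for the configured replicate count: residual plot variance is set to
r·var(g)·(1−h2)/h2, so the package's own estimator targets h2 and
`h2=1` yields replicate-identical scores. Scores are an affine rescale
of genetic value plus noise into [1, 9], clipped — a deliberate
approximation of ordinal severity scores by the same linear-model lens
used to analyse them. The generator does not model recombination
gradients, selfing history, genotyping error, non-additive effects, or
true ordinal thresholds; passing tests therefore certify the selection
and simulation machinery under controlled LD and additivity, not
robustness to those real-data features.

The shipped 4-individual × 2-block fixture is hand-enumerable: OHS
optimum 15 at three tied pairs, OPV optimum 22 at one pair, individual
totals (10, 8, 13, 6); every fitness function and optimizer is checked
against these by exhaustive enumeration.

## Known limitations

* Ordinal traits are analysed with linear models; threshold models are
  out of scope.
* No mate-allocation or expected-progeny-value fitness; no inbreeding
  penalty; no hybrid metaheuristics.
* The simulation tracks additive values only, with a closed population
  and no genotype-by-environment interaction.
* Grid REML for λ is bounded by the grid's range; pathological datasets
  wanting λ outside [1e-5, 1e7] saturate at the boundary.
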