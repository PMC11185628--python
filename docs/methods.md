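# Methods

## The model

`admixmate` simulates a closed, hermaphroditic, discrete-generation
population of N diploid individuals founded by a single two-way admixture
pulse: a fraction *m* of founders carry pure source-1 ancestry (global
ancestry proportion x = 1), the remainder pure source-2 ancestry (x = 0).
Each generation consists of exactly N mating events. Parent 1 is sampled
uniformly with replacement; parent 2 is sampled proportional to a
mate-choice weight ψᵢⱼ ≥ 0, with selfing excluded and weights renormalized
over the remaining candidates. Each event produces one child from two
recombinant gametes. There is no selection, no sex, no spatial structure,
and no genotype-level variation: the state of a haplotype is purely its
partition into source-labeled ancestry tracts.

Social group membership s ∈ {A, B} is a cultural label: it coincides with
source at founding and is thereafter copied from parent 1, so recombination
cannot erode it directly — only cross-group mating can decouple it from
genetic ancestry.

### Mate-choice kernels

All kernels share one strength parameter α, defined so that at founding an
individual is exactly α times more likely to take a mate from its own
source population than from the other; equivalently the expected
first-generation admixed-offspring fraction is A = 1/(1+α). α = 1 is random
mating; we consider α ≥ 1 (positive assortment).

| kind | weight ψᵢⱼ | behavior over time |
|---|---|---|
| `random` | 1 | — |
| `stationary` | exp(−ln(α)·\|xᵢ−xⱼ\|) | fixed preference; selectiveness effectively vanishes as σ²ₓ(t) → 0 |
| `increasing` | exp(−(ln(α)·σ²ₓ(0)/σ²ₓ(t))·\|xᵢ−xⱼ\|) | preference sharpens as variance decays; sustains r |
| `broad` | exp(−(xᵢ−xⱼ)²·ln α) | Gaussian with σ² = 1/(2 ln α); weak near-range discrimination |
| `social` | 1−1/(α+1) within group, 1/(α+1) between | variance-preserving barrier; sustains r for α > 2 |

Two calibration choices deserve note. For the broad kernel the Gaussian
width is fixed by requiring ψ(Δx=0)/ψ(Δx=1) = α, giving σ² = 1/(2 ln α);
the normalizing constant is dropped since weights are renormalized at every
draw, and α = 1 falls back to uniform weights (the infinite-width limit).
For the increasing kernel the per-generation exponent is c·σ²ₓ(0)/σ²ₓ(t)
rather than c/σ²ₓ(t): scaling by the founding variance makes the kernel
coincide exactly with the stationary kernel in the first generation, which
is the property that makes α comparable across kernels. σ²ₓ(t) is computed
once over the parental generation before any mating event; σ²ₓ(t) = 0 falls
back to uniform weights. Numerically, mate draws use shifted log-weights,
so the increasing kernel remains well-behaved even when σ²ₓ(t) is tiny and
raw weights underflow.

### Genome and meiosis

The default genome is 22 independently segregating chromosomes with the
relative sizes of the human autosomes (GRCh38), linearly rescaled to a
total of L = 2.88 Gb, with a uniform recombination rate r = 1e-8 per bp per
generation — so 1 cM ≡ 1 Mb and a gamete carries 28.8 crossovers in
expectation. Crossover counts are Poisson (no interference) with uniform
integer positions; each chromosome independently starts from a fair-coin
haplotype choice. Haplotypes are stored as flat genome-wide arrays of tract
boundaries; a meiosis is a handful of vectorized merge operations
(~0.2 ms), which is what makes full-scale runs (N = 10,000, 20 generations
≈ 400,000 meioses) take about 80 s each. Coordinates are 0-based half-open;
tracts exactly tile every chromosome and are maximally merged within
chromosomes (never across chromosome ends).

### Migration

In the continuous-migration scenario, after the N mating events a fraction
(default 1%) of the newborn generation, chosen uniformly, is replaced by
fresh unadmixed migrants, exactly half from each source, carrying the
source-associated group label and a migrant flag. Migrants therefore appear
in the census of the generation they arrive in and mate from the following
generation onward (the natural reading of discrete Wright-Fisher
bookkeeping). Mating records always describe the N events that occurred,
including the ~1% whose child was displaced by a migrant.

### Statistics

r(t) is the Pearson correlation of (xᵢ, xⱼ) over the N *ordered* mating
events that produced generation t (a symmetrized version is reported as a
cross-check; the two differ negligibly because parental roles are
exchangeable). When a margin is constant the correlation is reported as
NaN, not an error. The permutation null permutes the parent-2 column
(default 1,000 permutations) with the one-sided empirical p-value
(1 + #{r_perm ≥ r_obs})/(n_perm + 1), so p < 0.001 means the observed r
never overlapped the permuted distribution. Ancestry variance is the
population (divide-by-N) variance. Pair densities are binned on a hexagonal
lattice of pitch 0.025 (a square grid with the same pitch is provided
because it is exactly testable; the visual content is equivalent).
Bimodality of the x distribution is summarized by an interior-valley
heuristic — the tallest histogram bin in [0.4, 0.6] must be under half of
each flanking mode — which is a documented stand-in for visual inspection,
not a formal dip test.

### Dating

Under a single pulse t generations ago, tract lengths are approximately
exponential with rate λ = (t+1)·m per Morgan, so t̂ = λ̂/m − 1 with
λ̂ = 1/mean(length) (closed-form MLE; the analytic references at t = 20,
m = 0.5 are a 9.52 cM mean and a 28.53 cM 95th percentile). Lengths are
converted bp → Morgans through the uniform map. Tracts truncated by
chromosome ends are *included, uncensored* by default — the naive fit that
empirical pipelines apply — which is why random-mating runs recover
t̂ ≈ 19.6 rather than exactly 20 at N = 2,000; a right-censoring-aware MLE
(#uncensored / total length) is available as an option. Assortative mating
preserves long tracts, biasing t̂ downward, and leaves an excess of long
tracts over the fitted exponential (the tail-excess diagnostic at the 95th
percentile). That signature is produced by near-chromosome-length preserved
blocks, not by a smooth exponential mixture: a mean-matched exponential fit
to a scale mixture actually *over*-predicts the 95th percentile, so the
diagnostic is informative specifically for point-mass-like contamination.

## Choices where the design was open

- **Chromosome lengths**: only relative autosome sizes matter for anything
  reported here; they are configurable, and the defaults rescale GRCh38 to
  exactly 2.88 Gb (residual absorbed on chromosome 1).
- **Rounding**: founder and migrant counts use banker's rounding.
- **Mating records**: r is computed over events as recorded (ordered
  pairs, with replacement), not deduplicated pairs.
- **Reproducibility**: every run is seeded from (seed, replicate); the
  random kernel and the α = 1 stationary kernel consume the stream
  identically, so they are bit-for-bit interchangeable under a shared seed.

## What the simulations do and do not show

The generator *is* the study system: there is no external data. Defaults
(N = 10,000, m = 0.5, 22 chromosomes / 2.88 Gb, r = 1e-8, single pulse,
α ∈ [1, 10], 1%/generation migration in the continuous scenario) are the
study conditions. Reduced-scale test runs use N = 2,000 (qualitative
contrasts) or a 2 × 50 Mb genome (unit tests); these sizes were chosen so
the full suite completes in minutes while keeping binomial/Monte-Carlo
error well below the effects being asserted. Real admixed populations
violate most of the simplifying assumptions (two-way single-pulse
demography, no sex differences, no geography, error-free local-ancestry
calls), so passing tests validate the mechanistic claims about the models,
not any particular empirical population.

Replicate-to-replicate spread matters when comparing to point summaries:
r(20) estimated over N = 10,000 pairs has a sampling standard error of
about 0.01 even before between-replicate drift, so per-replicate values of
small correlations (~0.03) scatter by ±0.02–0.03 across seeds.

## Known limitations

- No crossover interference, non-uniform maps, or gene conversion.
- Two sources, two groups, symmetric barriers, hermaphroditic mating only.
- The tail-excess diagnostic cannot distinguish assortative mating from
  continuous migration; both fatten the tract-length tail.
- The increasing kernel becomes implausibly selective as σ²ₓ(t) → 0; this
  is a property of the model class, reproduced deliberately.
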