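# Methods

## The model

`invasim` is a forward-in-time, individual-based simulator of a
single-introduction invasion. A propagule of *n* diploid individuals is
sampled from a large Hardy–Weinberg source population and then iterated
through discrete, non-overlapping generations in a single closed patch. Each
generation applies, in order:

1. **Extinction lottery** — with probability *e* an external catastrophe
   removes the whole population. The lottery is independent across
   generations, so for propagules large enough that demographic extinction is
   negligible the survival probability to generation *t* is geometric,
   S(t) = (1 − e)^t. Placing the lottery first in the cycle means the
   per-generation rate applies to every generation including the first, so
   survival curves decline from generation 1.
2. **Reproduction** — promiscuous random mating: every female draws an
   offspring count from Poisson(*f*) with mean fecundity *f* = 100; each
   offspring receives one uniformly chosen allele copy per locus from its
   mother and one from an independently, uniformly chosen father, and a
   fair-coin sex. A population lacking either sex, or producing zero
   offspring, dies a *demographic* death — tracked separately from the
   lottery because the two causes mean different things for small propagules.
3. **Mutation** — every allele copy flips 0↔1 independently with probability
   μ = 5·10⁻⁶ (symmetric, reversible biallelic mutation; at this rate it is
   demographically invisible over 30 generations and merely prevents loci
   from being absorbed permanently).
4. **Regulation** — the offspring pool is culled to a target by uniform
   random subsampling. In the default **ceiling** mode the target is the
   carrying capacity K = 96,000 (96 individuals/m² over 1,000 m²). In
   **logistic** mode the target is the discrete logistic step
   N\* = N_t + r·N_t·(1 − N_t/K) from the parent census, capped at K; with
   fecundity 100 the ceiling mode is the r → ∞ limit and the census saturates
   within two to three generations from any propagule of 10 or more.

Genetics: *L* = 5,000 unlinked, neutral, biallelic SNPs (0/1 allele coding).
The reported diversity statistic is multilocus observed heterozygosity Ho —
the fraction of individuals whose two copies differ at a locus, averaged
across loci; expected heterozygosity He = mean of 2p(1 − p) (Nei's gene
diversity) is computed alongside because the drift expectations are stated in
He. Monomorphic loci stay in the panel so retention ratios Ho_t/Ho_0 always
refer to a fixed locus set.

## Source synthesis

The scenarios require a large random-mating source at observed
heterozygosity 0.5, 0.3 or 0.1. The source is constructed directly: the
per-locus frequency solving 2p(1 − p) = Ho (minor root, mirrored at random
per locus) in the default **two-point** mode, or frequencies drawn from a
symmetric Beta(α, α) with α = Ho/(1 − 2·Ho) in **beta-spectrum** mode, whose
mean heterozygosity α/(2α + 1) equals the target. Both allele copies are then
independent Bernoulli(p) draws — Hardy–Weinberg by construction. Direct
construction replaces a long burn-in whose only observable role is delivering
a HWE source at the stated Ho; an optional constant-census burn-in (drift +
mutation) is retained for users who want spectrum conditioning. The aggregate
Ho does not pin down the frequency spectrum; the two-point default makes the
closed-form oracles exact, and the beta mode exists because retention
dynamics can in principle depend on the spectrum.

The source census defaults to 10,000 individuals: founder sampling effects
scale as 1/(2n) in the propagule size, and the finite-source correction for
n ≤ 1,000 drawn from 10,000 is already far below the Monte-Carlo noise of a
20-replicate design, so a million-individual source would change nothing
measurable while costing two orders of magnitude more memory.

## The experiment and its summaries

A scenario grid crosses propagule size {2, 10, 100, 1,000} × initial Ho
{0.5, 0.3, 0.1} × extinction rate {2, 5, 10, 20}%, with 20 replicates of 30
generations per cell (the packaged `study.yaml`). Propagules are sampled
without replacement, sex-balanced by default (⌊n/2⌋ females) so a pair
propagule always contains a mating pair. Two response surfaces are computed:

- **survival rate**: fraction of a cell's replicates alive at generation t
  (monotone non-increasing; no resurrection);
- **retention**: mean over replicates *alive at t* of Ho_t/Ho_0, where Ho_0
  is the founding propagule's own observed heterozygosity. Conditioning on
  survival is explicit — the survivor count is always reported with the
  mean — because averaging heterozygosity over extinct replicates would be
  meaningless.

Replicate seeds derive from (base_seed, scenario id, replicate index) through
`numpy.random.SeedSequence`, so any trajectory reproduces in isolation and
reruns are byte-identical.

## Analytic oracles

Three closed forms anchor the verification of the stochastic engine:
geometric survival (1 − e)^t; expected He retention Π_t (1 − 1/(2N_t)) under
pure drift through a census trajectory; and the discrete logistic census map.
The oracles are expectation-level, not distribution-level: tests build their
envelopes from binomial/normal approximations at stated replicate counts.
For the Poisson-fecundity promiscuous-mating cycle the effective size is
close to, but not exactly, the census; tests therefore accept a fitted Ne
within 25% of N rather than asserting Ne = N.

## Numerical choices

- **Fused generation step.** `step_generation` decides which offspring
  survive regulation before synthesizing genotypes. Regulation keeps a
  uniform subset chosen independently of genotype, and symmetric per-copy
  mutation commutes with subset selection, so the fused path is
  distributionally identical to the literal reproduce → mutate → regulate
  composition (a test compares the census and Ho moments of the two paths)
  while touching only min(pool, K) genomes per generation.
- **Mutation placement.** The number of flips is a single Binomial draw over
  all allele copies, placed at uniformly chosen positions — exact, and far
  cheaper than a uniform variate per copy at μ = 5·10⁻⁶.
- **Survival-only mode** (L = 0) collapses reproduction to one aggregate
  Poisson draw for the pool size and one Binomial draw for survivor sexes,
  making 1,000+-replicate demographic runs take seconds. Survival dynamics
  are independent of the genetics, so this changes nothing but cost.
- **Degenerate inputs.** Empty populations raise on statistics ("no
  individuals"); stepping an extinct replicate is an error; a retention query
  with no survivors returns a distinguished no-survivors result (NaN mean
  with survivor count 0), never 0.

## Problem sizes used in tests and the acceptance script

Retention runs use 500 loci and K = 9,600 instead of 5,000 and 96,000.
Retention is a per-locus average, so halving-by-ten the panel only widens the
Monte-Carlo band (≈1/√L per replicate), and once the census exceeds a few
thousand the per-generation drift loss 1/(2N) is already below 10⁻⁴ per
generation, so a tenfold smaller ceiling changes cumulative retention for
n ≥ 10 by well under one percentage point. Survival checks run at 1,000–3,000
replicates (binomial s.e. ≈ 1–1.6 points), the full-capacity ceiling check at
K = 96,000, and source synthesis at the full 10,000 × 5,000 size.

## What the generator does and does not emulate

The synthetic source reproduces the stated study conditions — HWE, random
mating, equal expected sex ratios, the three Ho levels, 5,000 neutral
biallelic SNPs — but not features of real SNP panels: linkage, multiallelic
sites, a realistic site-frequency spectrum, selection, or demographic history
in the native range. Passing tests therefore demonstrate the internal
consistency of the neutral single-patch model, not predictions about any real
invader.

## Known limitations and open choices

- The logistic growth rate r of the original design is not recoverable; the
  default is ceiling regulation (fast growth). Heterozygosity losses for the
  smallest propagules (n = 2) are sensitive to this choice — slow growth
  keeps the census small for several generations and multiplies the early
  drift loss — so quantities asserted in tests are restricted to those
  insensitive to the growth regime, and logistic mode with tunable r is
  provided for exploration.
- Whether the 20 replicates of a cell should share one source or
  re-synthesize it per replicate is undetermined; the engine builds one
  source per Ho level and resamples propagules per replicate, which keeps
  founder sampling as the only between-replicate variation at t = 0.
- Single closed patch, single introduction event: no propagule pressure,
  spatial structure, age structure, or post-founding gene flow.
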