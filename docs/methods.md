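# Methods

## Scientific background

Deleterious mutations segregating at linked sites interfere with one
another: selection acting on one variant perturbs the transmission of its
neighbours (Hill-Robertson interference, HRI), and haplotypes carrying two
deleterious alleles are removed faster than haplotypes carrying one.  Both
effects push pairs of deleterious derived alleles toward *repulsion* — they
are found on different haplotypes more often than matched neutral variants —
which is visible as a deficit in signed linkage disequilibrium (LD) between
nonsynonymous (NS) variants relative to synonymous (S) variants of the same
frequency.  This package provides the machinery to generate that prediction
from forward simulations and to test for it in data: frequency-matched LD
statistics on phased haplotypes, an unphased two-locus statistic, and a
covariate-matched permutation test.

## Forward Wright-Fisher simulator

`ldrepulsion.wf` implements a discrete-generation diploid Wright-Fisher
model with viability selection, uniform recombination and infinite-sites
mutation at base-pair resolution.

**Genome.**  A chromosome (default ~5 Mb) is tiled by genes separated by
intergenic spacers, each gene alternating exons and introns.  Element
lengths follow the canonical gene-structure recipe calibrated to empirical
exon/intron length distributions: exon lengths
`int(lognormal(log 50, log 2)) + 1`, intron lengths
`int(lognormal(log 100, log 1.5)) + 10`, intergenic spacers uniform on
[100, 5000) bp, with probability 0.8 of a further intron+exon pair after
each exon.  About 9-10% of the sequence is exonic.

**Mutation.**  Poisson at `mu = 1.5e-8` per bp per gamete per generation.
An exonic mutation is nonsynonymous with probability 2.31/3.31 (the codon
degeneracy-derived NS:S ratio of 2.31:1) and draws a selection coefficient
from the configured DFE; synonymous and non-exonic mutations are neutral.
A mutation hitting an occupied base is re-drawn (infinite sites at bp
resolution); back-mutation is impossible.

**Distribution of fitness effects.**  The default deleterious DFE is a
gamma distribution over |s| with shape 0.186 and mean |s| = 0.01314833
(`E[s] = -0.01314833`), a human exome-derived estimate; `fixed` DFEs
(including `s = 0` for neutral controls) support the constant-s scenarios.
Dominance is a single coefficient `h` (0.5 additive by default; 0.0 fully
recessive).

**Fitness and reproduction.**  Per-site genotype fitness is 1, `1 + h s`,
`1 + s` and combines multiplicatively across sites.  Each offspring draws
two parents with probability proportional to fitness (selfing possible, as
in a standard Wright-Fisher model); each parent transmits one recombinant
gamete with `Poisson(r L)` crossovers placed uniformly, with
`r` constant per run (`1e-9` to `1e-6` per bp).

**Demography.**  Three named models: Model 1, a constant population of
10,000 diploids; Model 2, the three-population out-of-Africa model of
Gravel et al. (2011) with its published sizes, split times, growth and
migration rates; Model 3, Model 2 with migration removed.  Samples (default
50 diploids) are drawn from the African population.  Migration is
implemented as the fraction of offspring in a population whose parents come
from another population; splits found daughter populations from parental
gametes.

**Rescaling.**  A factor `Q >= 1` divides population sizes and event times
and multiplies `mu`, `r`, `|s|`, growth and migration rates, preserving the
population-scaled compound parameters (N mu, N r, N s, N m).  Scaled
selection coefficients are clipped at -1 (lethal).  Replicated studies in
the tests and the acceptance script use `Q = 20`; truncation of the gamma
tail at |s Q| > 1 makes the strongly deleterious class effectively lethal,
which if anything weakens interference among observable variants, so the
rescaled runs are conservative for the NS-vs-S contrasts.

**Initialization and burn-in.**  Two modes:

* `"coalescent"` (default): the founding population is a neutral
  mutation-drift equilibrium sample simulated with msprime at the root
  size, followed by `burn_in_factor * N_root` forward generations (default
  2N) before the first demographic event.  The coalescent provides the
  exact neutral equilibrium; the forward burn relaxes the selected class
  (initialized with neutral frequencies) toward selection-drift balance.
  Burn-length calibration runs show that neutral-only dynamics are
  stationary under this initialization (mean D' of low-frequency pairs
  stays at the coalescent level from 1N to 6N of forward burn), while the
  NS-vs-S repulsion contrast is still strengthening between 2N and 6N
  (mean D' difference roughly -0.04 at 1N, -0.07 at 2N, -0.11 at 6N of
  burn, 1 Mb Model 1 replicates at r = 1e-9, Q = 20).  The default of 2N
  therefore *understates* the equilibrium interference signal: analyses
  initialized this way are conservative for the NS-vs-S contrasts, and the
  burn length is exposed (`burn_in_factor`) for users who want the fully
  relaxed regime at ~3x the cost.
* `"empty"`: mutation-free start with a `10 N_root`-generation burn, the
  classical convention (Model 1's "10,000 diploids for 100,000
  generations").  The engine-validation tests use this mode so that the
  forward dynamics are checked against a coalescent oracle rather than
  initialized from one.

**Bookkeeping.**  Globally lost and globally fixed sites are purged every 5
generations (fixed deleterious sites change fitness by a constant factor
and cannot affect relative fitness).  Mutation inputs are tallied by class
before selection acts, which is the correct denominator for the NS:S 2.31:1
calibration check (surviving NS variants are depleted by selection).
Restricting mutation tracking to exons (`track_noncoding=False`) is exactly
distribution-preserving for every NS/S statistic, because neutral
noncoding mutations never feed back into fitness; replicate studies use
this mode.

## LD statistics with frequency matching

For derived allele frequencies `p_A`, `p_B` and double-derived haplotype
frequency `p_AB`:

    D   = p_AB - p_A p_B
    r^2 = D^2 / (p_A p_a p_B p_b)
    D'  = D / min(p_A p_B, p_a p_b)   if D < 0
          D / min(p_A p_b, p_a p_B)   if D > 0
          0                           if D = 0 (a documented convention;
                                      the piecewise definition is silent)

All statistics are oriented by the derived alleles, so `D' = 1` means the
two derived alleles always co-occur and `D' = -1` (complete repulsion)
means they never share a haplotype.  Pairs are frequency-matched: only
pairs with identical derived allele count, identical annotation (NS-NS or
S-S) and distance <= 10 kb (inclusive boundary; distance-0 pairs excluded)
on the same chromosome enter the analysis.  Decay summaries report per-bin
mean, SE = sd/sqrt(n) (0 for single-pair bins, with `n_pairs` exposed) and
counts, in 1.5 kb physical bins or cM quantile bins computed on pooled
records.  The normalized difference in D is
`(mean D_NS - mean D_S) / mean D_S` per bin, NaN where `mean D_S = 0`.

## The unphased statistic H_R^(j)

For pairs of variants at derived allele count `j` (same annotation,
<= 10 kb apart), `n11` counts individuals heterozygous at both loci, and

    H_R^(j) = (1 / l_j) * sum over the l_j qualifying pairs of n11

Individuals homozygous for the derived allele are tallied but never counted
in `n11` (rare at low `j` in 50 diploids, with little information loss).
Pairs with any missing genotype at either site are excluded; the sites
stay.  Both sites of a pair must have the same `j`; the statistic is
undefined (reported as NaN with `l_j = 0`) when no pair qualifies.  `j` is
generic, but only `j <= 5` is exercised, matching the low-frequency range
where selection is informative in a sample of 50.

## Covariates

* **Polarization**: sites are oriented by a high-confidence ancestral
  allele (uppercase single base); when ALT is ancestral the genotype
  encoding is flipped (an involution); sites with missing/low-confidence
  ancestral alleles, or an ancestral allele matching neither REF nor ALT,
  are dropped.
* **Genetic distance**: piecewise-linear interpolation of cM at each
  position between map anchors (male and female maps averaged at anchor
  level first); positions outside the anchored span give a missing
  distance and the pair is dropped from cM-based analyses.  This implements
  the "cM per bp rate times physical distance" imputation.
* **B-values**: background-selection strength per site from half-open
  `[start, end)` intervals; a pair's covariate is the mean of its two
  sites; uncovered sites make the pair ineligible for B-matched analyses.
* **Masks**: BED-style half-open accessibility intervals; both sites of a
  pair must be inside the mask.
* Coordinates are 0-based internally; VCF (1-based) is converted at I/O.

## Matched-pairs permutation test

Each NS pair is matched to one S pair without replacement, exactly on
(chromosome, allele count), with |delta bp distance| < 50 and, when the
covariates exist, |delta cM| and |delta mean B| within calipers defaulting
to 0.25 pooled standard deviations.  Candidate edges are processed in
ascending |delta bp| with a deterministic tie-break, so competing NS pairs
resolve in favour of the closest match and the result is reproducible.  For
pooled independent simulation replicates, each replicate is its own
chromosome and matching is allowed across replicates
(`match_across_chromosomes=True`): replicates are exchangeable, and
within-replicate S candidates are too few at the replicate sizes used here.
Every emitted match is re-validated against every caliper at run time.

The test statistic is the mean within-match difference (NS minus S) of the
chosen LD statistic.  The null distribution flips the sign of each
difference independently with probability 1/2 (= swapping NS/S labels
within a match); the alternative is one-sided (NS below S).  With <= 20
matches all 2^k assignments are enumerated exactly; otherwise 10,000
Monte-Carlo permutations with the add-one estimator
`p = (1 + #{T* <= T_obs}) / (B + 1)`, which cannot return zero.

## Replicated studies and the downsampling procedure

Simulation studies pool frequency-matched pairs over independent
replicates.  Decay envelopes follow the grouped convention: replicates are
split into 3 groups, each group contributes one per-bin mean, and the
min/max of group means are the error bars.  `downsample_to_empirical`
resamples simulated pairs (with replacement, per annotation-by-allele-count
stratum) to an empirical composition, recomputing the normalized difference
in D per resample to form an envelope, with under-filled strata skipped
with a warning.

## Problem sizes in tests and the acceptance script

The replicated analyses run at `Q = 20` with exon-only tracking:

* H_R / D' concordance: 200 Model 2 replicates of 1 Mb at `r = 1e-8`,
  1.5 kb bins pooled per annotation.  Both the acceptance script and
  the test suite pool the singleton and doubleton bins (j = 1, 2; 28
  points) for the rank correlation between binned mean H_R^(j) and mean
  D'; the test asserts rho > 0.9, the level calibration shows is reliably
  attainable at this replicate count (the full-scale studies at thousands
  of replicates report > 0.945; rescaled replicates carry more bin noise,
  and the doubleton-only correlation alone is markedly less stable).
* Matched-pairs inference: Model 1 replicates of 5 Mb at `r = 1e-9` (the
  rate at which the repulsion contrast is strongest), allele counts 1-5.
  Calibration runs put the matched mean D' difference near -0.04 with a
  per-match SD of ~0.72, so a few thousand matches are required; the
  replicate counts (tests 200, acceptance script 190, about 16-17 matched
  pairs per replicate) are sized to give an expected standardized effect
  near -3.5 to -4.
* Type-I control reuses the matched differences with labels destroyed by
  random within-match sign flips (a construction under which the labels are
  exchangeable by definition), 200 repetitions, Kolmogorov-Smirnov check
  at alpha = 0.01.

## What the generator does and does not emulate

The synthetic data reproduce the study conditions: exon/intron gene
structure, the human-scale mutation rate, uniform recombination in the
stated range, the gamma DFE over NS mutations at a 2.31:1 NS:S ratio,
additive or recessive dominance, the three demographies, and 50-diploid
sampling.  They do **not** include empirical recombination-map structure,
gene conversion, crossover interference, epistasis, sequencing or phasing
error, batch effects, or functional annotation error — so passing tests
demonstrate the statistical machinery and the interference signal under
the model's own assumptions, not that real data are free of those
confounders.  B-values and genetic maps are consumed as external tracks in
empirical mode and are absent from simulations (uniform `r` makes cM
proportional to bp there).

## Numerical choices and degenerate inputs

* Scaled log-fitness uses `log1p`; lethal genotypes (`1 + s = 0`) are
  floored at log-fitness -700 to keep exact zeros out of the weighted
  parent draw without NaNs.
* `D' = -1` detection uses tolerance 1e-9 after computing from integer
  counts; `D = 0` maps to `D' = 0`.
* Monomorphic columns are rejected in two-locus tallies; samples only ever
  contain segregating sites.
* Pair tables at identical positions cannot arise from the simulator
  (infinite sites); distance-0 pairs from external data are excluded.
* Quantile bin edges that collapse (all distances identical) degrade to a
  single degenerate bin instead of failing.
* All randomness flows from a single seeded `numpy` Generator per
  simulation; msprime sub-seeds are drawn from it; identical configs give
  byte-identical samples.

## Known limitations

* The engine is a dense-matrix design: performance degrades for
  chromosome lengths or population sizes far beyond the rescaled study
  conditions (it is not a general-purpose replacement for compiled
  simulators).
* `Q = 20` rescaling truncates the strongly deleterious gamma tail
  (scaled |s| clipped at 1); contrasts are expected to be conservative.
* The coalescent initialization assumes the pre-study history is neutral
  at the root size; histories with ancient selection or structure would
  need the `"empty"` mode and an explicit long burn.
* Matching is greedy (ascending caliper discrepancy), not optimal
  assignment; on small constructed instances it coincides with the
  exhaustive optimum (tested), but global optimality is not guaranteed.
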