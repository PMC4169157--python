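# Methods

## Model overview

`wormsweep` simulates experimental evolution in androdioecious
*C. elegans* populations founded from five wild genetic backgrounds and
analyses pooled resequencing of such populations. The simulator is
individual-based and forward in time, with non-overlapping generations.
Genotypes are tracked at 200-kb window resolution: each worm carries, per
chromosome, two vectors of founder-background labels. This matches the
resolution of the genomic analysis (window-averaged diagnostic-allele
frequencies) and makes whole-experiment replicate sweeps cheap; it cannot
represent variation segregating *within* a window (see Limitations).

The default genome grid freezes ceil(length / 200 kb) windows per
chromosome from the WS235 reference lengths — I 76, II 77, III 69, IV 88,
V 105, X 89; 504 windows total — so simulations are reproducible without
the reference genome on disk. Custom grids are accepted everywhere.

All worms are genotypically XX; maleness is phenotypic (the experimental
populations carry a temperature-sensitive sex-determination genotype), so
all six chromosomes recombine and segregate identically and no
sex-chromosome bookkeeping is needed.

## Generation cycle

For generation *n* (order matters and is fixed):

1. **Fitness.** Each worm's relative fitness starts at 1.0 and is
   multiplied by a locus multiplier for every favored allele it carries at
   each QTL (0, 1 or 2 per locus). Under the equal-effects
   parameterization the multiplier is `Wmax^(1/(2L))` for `L` diploid
   loci, so the all-favored homozygote has fitness Wmax exactly; the
   0-locus null model gives every worm fitness 1.
2. **Sex.** Each worm is male with probability equal to the outcrossing
   rate for generation *n* (constant, or a step schedule dropping from a
   high initial rate to a low one at a switch generation, default 25).
   Founder sexes (10 hermaphrodites + 12 males per background) are part of
   the generation-0 composition and are not redrawn; random assignment
   applies from generation 1 on. This choice keeps the stated founding
   composition meaningful; its practical effect is a male-rich first
   generation that thoroughly mixes the founder backgrounds once, exactly
   as a multi-strain founding cross should.
3. **Reproduction.** N offspring are generated one by one: a first parent
   is drawn from the whole population with probability proportional to
   fitness; a hermaphrodite first parent self-fertilizes, a male first
   parent outcrosses with a hermaphrodite mother drawn
   fitness-proportionally from the hermaphrodites. Males never self and
   never serve as mothers. The two gametes of a selfed brood come from
   independent meioses. Offspring are sexless until their own generation's
   sex-assignment step.

**Meiosis.** Every tetrad undergoes exactly one crossover per chromosome
(the worm's strong chiasma interference), at a breakpoint uniform over the
w−1 inter-window boundaries; the crossover involves two of the four
chromatids, and the transmitted chromatid is sampled uniformly — so a
gamete is recombinant with probability 1/2 and otherwise an intact
parental haplotype. Breakpoints never fall inside a window (the window is
the resolution unit; no genetic map is imposed, so the recombination rate
is uniform per window, not per bp). Single-window chromosomes degrade to
free Mendelian segregation. The implementation draws one integer per
(gamete, chromosome) encoding start haplotype, recombinant flag and
breakpoint, then assembles gametes with a compiled segment-copy kernel
(numba) or an equivalent vectorized numpy path; both paths consume
identical random draws, so results do not depend on which is active.

## Experiment, statistics and inference

A run evolves 20 independent populations for 50 generations and ranks the
final generations by mean relative fitness. "Average fitness" is the
final-generation mean; a multi-generation average would be an equally
defensible reading, but fitness is only defined per worm per generation
and the final generation is what is sequenced. Exact ties (certain under
the null model) are broken by a seeded shuffle so the top-3 choice is
reproducible but unbiased. On the top 3 populations:

* **s**: fraction of the 504 windows whose dominant (argmax-frequency)
  background agrees across all three. Argmax ties break to the lowest
  background index, deterministically.
* **f**: mean over the three populations of the fraction of windows whose
  dominant background frequency is ≥ 0.9. The threshold is inclusive and
  configurable.

Replicate distributions (default 200 replicates) yield empirical 95% CIs
(2.5th/97.5th percentiles, linear interpolation between order statistics —
numpy's default, Hyndman–Fan type 7) and two-tailed add-one empirical
p-values, `p = min(1, 2·min(#{v ≤ obs}+1, #{v ≥ obs}+1)/(n+1))`. The
original analysis did not spell out its p-value formula; the add-one
two-tailed form is adopted because the smallest reportable value with 200
replicates is then 2/201 ≈ 0.01, matching the floor the original
analysis printed. Summaries print `<0.01` below that floor.

**Randomness.** One root `SeedSequence` per run; replicate, population and
tie-break substreams are spawned from it. Results are bit-reproducible
given (seed, config) and identical whether replicates run serially or in
parallel; extending a replicate set leaves earlier replicates unchanged.

## QTL map fixtures

The package ships example equal-effects maps with 83, 22, 16 and 11 loci
(`model1`–`model4`). The original maps were inferred from the observed
evolved genotypes by a procedure whose details are not reproducible from
the main text, so these fixtures are synthetic stand-ins: loci are
apportioned across chromosomes in proportion to window counts (largest
remainder), evenly spaced within each chromosome, and each favors the
background of a fixed reference mosaic of chromosome-scale blocks (I:
CB4856; II: N2 then MY2; III: JU258; IV: AB1; V: CB4856 then N2; X: MY2)
that mimics the qualitative block-fixation pattern of the evolved lines.
Scenario outcomes that depend on the detailed geometry of the true maps
(especially lower tail behaviour of f) should be read with that
approximation in mind.

## Pool-seq analysis

* **Filtering**: biallelic SNPs with QUAL ≥ 30 and depth ≤ 100× in every
  sample (the high-depth cut guards against collapsed paralogous repeats);
  multiallelic records and indels are dropped and counted. Requires
  per-sample DP and AD FORMAT fields; filters are idempotent.
* **Diagnostic SNPs**: at sites covered ≥ 10× in all five founder
  samples, an allele (ref or alt) with read frequency ≥ 0.9 in exactly one
  background and ≤ 0.05 in the other four. The source analysis says only
  "unique" alleles at ≥ 10× coverage; the 0.9/0.05 operationalization
  absorbs sequencing error and residual heterozygosity in the inbred
  founder strains, and both thresholds are parameters.
* **Window ancestry**: per pooled sample, the diagnostic-allele read
  proportion at each covered diagnostic site, averaged (unweighted, by
  default; a depth-weighted estimator is available) per background over
  half-open 200-kb windows `[k·200000, (k+1)·200000)` on 1-based
  coordinates. A background with no informative site in a window is
  reported missing (NaN), never zero.
* **Novel mutations**: sites with alt frequency strictly > 0.9 at ≥ 10×
  depth in an evolved line, and zero alt reads at ≥ 10× depth in the
  pooled ancestor and every founder. This is a deterministic filter, not a
  statistical test; no multiplicity machinery applies. Sites missing from
  the ancestor or founder call sets fail the coverage requirement and are
  never called.

## Synthetic data

The generator emulates the end product of the experiment's sequencing, not
the reads: diagnostic sites are a Poisson process at one SNP per 750 bp
genome-wide (uniform, unclustered — real diagnostic density varies along
the genome), per-site depth is Poisson (default mean 30×), and a read
shows the wrong allele of a biallelic site with probability `error_rate`
(default 0.002); at monitored invariant sites a specific alternate base
arises at `error_rate/3`, spreading miscalls over three bases. Site
placement is a deterministic function of the spec seed alone, so founder
panels and pooled samples generated from one spec share a site map.
Mapping artifacts, indels, depth autocorrelation and batch effects are not
modeled — so passing round-trip tests demonstrates the pipeline's
correctness on its own terms, not robustness to real-data pathologies.

## Problem sizes and numerical choices

Scenario tests and the acceptance script run the neutral model at the full
design size (N = 1000, 20 populations, 50 generations) — the null
distributions of s and f are sensitive to drift, hence to N — and the
strong-selection scenarios at N = 200 with 200 replicates, the smallest of
the design's tested alternative population sizes, which the original
supplementary comparisons found to give consistent results. The neutral
scenario uses 400 replicates rather than 200: the neutral s distribution
has a rare (~0.4% of replicates) heavy-tail event in which one founder
background drifts to genome-wide dominance in all three scored
populations, and with 400 replicates the add-one empirical-p floor (2/401)
still reports ≤ 0.01 when one such replicate lands in the batch. The
asymptotic two-tailed p of the observed s = 0.56 under this null is
≈ 0.0075, so the neutral rejection is real but sits near the resolution of
any few-hundred-replicate estimate. The deterministic-recursion
check tolerates 3 Monte-Carlo standard errors plus a 3×10⁻³ floor for the
O(1/N) lag of a finite population behind the infinite-N recursion.
Frequencies are exact multiples of 1/(2N) (integer counts), so the f
threshold comparison `≥ 0.9` involves no floating-point fragility at
sensible N.

## Known limitations

* Window-resolution genotypes: no within-window variation, no bp-level
  breakpoints, no genetic map (crossover uniform per boundary).
* Equal-effect, multiplicative, sex-independent QTL; no dominance,
  epistasis or environment dependence (the multiplier field permits
  unequal effects, but nothing in the package fits them).
* The simulator does not model novel mutations; those are handled only on
  the genomics side.
* Sperm competition, male mating success differences and outbreeding
  depression are outside the two-parent rule used here.
* The packaged QTL maps are stand-ins (see above); quantitative agreement
  with results conditioned on the original maps is approximate,
  particularly distribution tails.
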