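# Methods

## The detection model

The pipeline looks for megabase-scale regions in which SNPs are inherited
as a unit — the pattern produced by a chromosomal inversion polymorphism,
where recombination between the two arrangements is suppressed and every
arrangement-tagging SNP is correlated with every other one regardless of
physical distance. The working statistic is composite LD: for two sites
with diploid dosage vectors *g₁*, *g₂* over the samples,
r² = corr(g₁, g₂)². No phasing is attempted; with a few tens of unrelated
diploids, phased haplotype r² is not estimable without strong model
assumptions, and the genotype correlation captures the same block signal.

All-pairs r² over a whole chromosome is quadratic in SNP count, so the scan
subsamples every *k*-th SNP (stride, default 250, in 1-based counting:
SNPs k, 2k, 3k, …, giving ⌊N/k⌋ subset SNPs). Each subset SNP gets the mean
of its r² against all other subset SNPs on the chromosome. Two regimes are
expected: for loci independent of everything else the squared sample
correlation has expectation 1/(n−1) — ≈ 0.033 at n = 31, ≈ 0.053 at
n = 20 — so the profile floor is set by sample size, not by genuine LD;
inside a block the mean rises roughly to the fraction of subset SNPs
sharing the arrangement. The block spans from the first to the last subset
SNP with mean r² strictly above the threshold (default 0.1), with edges
placed one SNP *outside* those: by default the neighbouring subset SNP
(one stride away), because the intervening untyped SNPs may be linked;
optionally the literal neighbouring SNP. One block per chromosome is the
default (an interior run of sub-threshold SNPs — a linkage gap — stays
inside the block, matching how real supergene blocks present); `max_gap`
splits runs separated by more than that many consecutive sub-threshold
subset SNPs.

## Differentiation statistics

Weir–Cockerham variance components are computed per SNP from per-population
sample sizes nᵢ, alt-allele frequencies pᵢ and observed heterozygote
proportions hᵢ (the 1984 moment estimator, two-level design): a (among
populations), b (among individuals within populations), c (within
individuals), θ = a/(a+b+c). θ is undefined (flagged NaN, excluded from
means) when a+b+c = 0, i.e. the site is monomorphic in the pooled sample,
and can legitimately be negative in small samples. Means over SNP sets are
ratio-of-sums Σa/Σ(a+b+c) — the convention of the standard hierarchical-F
packages — not means of per-SNP ratios; the worked example and summary
tables use it throughout. The chromosome-wide θ track uses the
multi-population estimator (all populations at once); pairwise tables use
two populations.

Exonic SNP subsets follow the replication design: on block-bearing
chromosomes all exonic SNPs, split inside/outside the block; elsewhere
every 10th exonic SNP pooled as the genome background. In-block vs
out-of-block per-SNP θ distributions are compared with the two-sample
two-sided Kolmogorov–Smirnov test (asymptotic p).

PCA treats samples as observations and SNP dosages as variables, centred
but not scaled (the convention of the standard R PCA the analysis
replicates). In-block SNPs produce three PC1 clusters — arrangement
homozygotes at the extremes, heterozygotes between — and a 1-D 3-means on
PC1 assigns block genotypes; the middle cluster is AB, and the AA/BB
polarity is arbitrary (PC1 sign is arbitrary), so accuracy against truth is
scored up to that swap. Degenerate score distributions (range < 1e-9, or
cluster centres closer than 1e-6 of the range) return all-unassigned rather
than a fabricated clustering; at least 3 strongly linked subset SNPs in the
block are required.

## Annotation and enrichment

SNP classes partition as exon ≻ intron ≻ intergenic, with exon precedence
applied across genes (a SNP in one gene's exon and another's intron is
exonic). Intervals are 1-based inclusive; exons are merged per gene at
load. Enrichment of a density or proportion is reported as
100·(in/out − 1) rounded to the nearest percent. Gene–block membership is
any-overlap (≥ 1 base) by default, containment optional. GO enrichment is a
per-term one-sided Fisher exact test of in-block vs background carriers
with Benjamini–Hochberg adjustment across tested terms; terms with no
in-block carrier are skipped. This deliberately replaces the
graph-decorrelating weight01 algorithm of topGO: p-values are therefore
comparable only in structure, not numerically, to tables produced with
weight01, and no ontology-graph propagation is applied (terms are taken as
annotated).

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes, not
a demographic simulation:

- Each individual draws two arrangement haplotypes Bernoulli(q_pop), q_pop
  the population's arrangement-B frequency. Defaults (three populations,
  10+10+11 diploids, q = 0.50/0.85/0.15) give the three-cluster PCA and the
  strong/weak pairwise θ contrast characteristic of the study system.
- Arrangement-linked in-block SNPs equal the carried arrangement exactly,
  with a random ref/alt polarity per SNP — an old, non-recombining block in
  full internal LD.
- In-block *unlinked* SNPs model recent mutations inside the inversion:
  independent low-MAF draws (U(MAF floor, 0.15)), placed in the block
  interior only (a 5% margin at each breakpoint carries none). Rationale:
  recombination suppression is strongest at inversion breakpoints, and the
  empirical pattern this mirrors is an interior gap of unlinked loci; the
  consequence, relied on by the edge rule, is that the outermost in-block
  SNPs are arrangement-linked.
- Background SNPs come from a founder-haplotype copying chain: 16 founder
  haplotypes with per-SNP frequencies U(MAF floor, 0.5); each sample
  haplotype walks along the chromosome copying one founder and re-chooses
  its template with probability 0.1 per SNP. This yields LD that decays
  over ~10 SNPs and none at stride spacing — exactly the two regimes the
  scan needs — at a negligible cost compared with a coalescent simulation,
  and deterministically per seed.
- Positions are uniform, with in-block density multiplied by 1.4 (the
  observed supergene-block elevation is a few tens of percent); in-block
  genes get a 1.4× exon fraction so the exonic SNP proportion is also
  elevated. A ~10 Mb chromosome at ≈5×10⁻³ SNPs/base background density
  (~51k SNPs) with a 2.5 Mb block reproduces, scaled, the per-chromosome
  SNP loads of the study data.
- Truth output records the planted block, per-sample arrangement genotypes,
  per-SNP class (arrangement-linked / in-block-unlinked / background),
  per-population empirical allele frequencies, and per-SNP genomic class
  computed by a naive per-gene scan that is independent of the package's
  interval classifier.

What the generator does **not** emulate: realistic allele-frequency spectra
and LD decay (copying chain, not coalescent), demography (migration,
growth, bottlenecks), selection dynamics, partial recombination/gene flux
between arrangements, genotyping error and missingness structure, and real
gene/GO annotations. Tests passing on this generator therefore demonstrate
that the statistics and the calling rule behave as designed under the
assumed structure — not that the pipeline is robust to everything real
resequencing data can do.

## The two-population recovery design

Edge recovery is hardest at n = 20 (two populations of 10): the null mean
r² floor is 1/19 ≈ 0.053, leaving under 0.05 of headroom below the 0.1
threshold, and two failure modes meet in that gap. First, every background
subset SNP's correlations to all arrangement-linked subset SNPs collapse to
essentially one shared draw r²(background SNP, arrangement) ~
Beta(1/2, (n−2)/2), so a background SNP's mean exceeds the threshold with
probability P[r₁ > (0.1 − (1−f)/(n−1))·1/f], f the linked share of subset
SNPs — a fat tail that grows quickly with f. Second, all linked subset
SNPs' means rise and fall together (they share the same background draws),
so if the linked count ends up low the whole block drops below threshold at
once; with a mixed linked/unlinked block the linked count is binomial and
this happens at a few-percent rate. The two-population recovery
configuration therefore uses a fully linked 0.5 Mb block (a young
inversion, no interior mutations) on the 10 Mb chromosome: the in-block
subset count is then fixed by the stride (~14 of ~186 subset SNPs,
f ≈ 0.075), putting the in-block means ≈3.5 standard deviations above the
threshold and the spurious-background tail below 10⁻³ per dataset. The
mixed-block behaviour (interior gap inside a single called span) is
exercised separately at n = 31, where the lower floor (0.033) leaves ample
headroom.

## Numerical and testing choices

- MAF filter is inclusive (≥ 0.05); QUAL filter is strict (> 30), read as
  site QUAL (per-genotype quality is an alternative reading; site-level is
  the common downstream convention and the one implemented). MAF is
  estimated from called genotypes, missing excluded from numerator and
  denominator. Multi-allelic records are dropped, not decomposed.
- Monomorphic-in-sample sites give undefined r² (NaN), excluded from means
  rather than coded 0, to avoid deflating in-block means; an all-undefined
  row stays NaN. The r² threshold and the mean-r² comparison are strict
  inequalities. r² is clipped to [0, 1] against floating-point excursion.
- Coordinates are 1-based inclusive everywhere internally; only BED output
  is 0-based half-open. Block length = end − start + 1.
- 3-means uses 10 restarts with a fixed random state (from the run seed);
  cluster order is by centre, so AB is always the middle cluster.
- Determinism: a dataset is byte-identical for a given seed; the pipeline
  writes byte-identical tables for identical inputs, config and seed.
- Test problem sizes: unit tests run ~17k-SNP datasets; the acceptance
  suite uses five ~52k-SNP datasets for edge recovery (through the on-disk
  VCF), a 52k-SNP null run for the LD floor, 400 tiny (≈2k-SNP) datasets
  for the θ-recovery comparison against an 8,000-replicate Monte-Carlo
  oracle (the θ estimator has a per-dataset sd of ≈0.17 at the planted
  frequencies, and linked SNPs share one genotype table, so averaging is
  only across datasets), and 1,000 random tables for oracle equivalence.
  These sizes were chosen to make the stochastic checks decisive at their
  stated tolerances.

## Known limitations

- The threshold-and-adjacent-SNP edge rule resolves edges only to one
  stride; sub-stride localisation would need a second, denser pass.
- The single-span default assumes at most one supergene block per
  chromosome; chromosomes with two genuine distant blocks need `max_gap`.
- The scan's null floor depends on sample size; with very few samples the
  0.1 threshold loses meaning (at n = 12 the floor itself is ~0.09).
- GO results depend entirely on the supplied flat annotation; no
  graph-aware correction is applied.
- The KS p-value is asymptotic; for very small SNP sets an exact variant
  would be preferable.
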