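# ldblocks

De novo detection of linkage-disequilibrium "supergene" blocks — the
signature of chromosomal inversion polymorphisms — from whole-genome SNP
genotypes, plus block-partitioned population-differentiation analysis and a
synthetic inversion-polymorphism data generator with machine-readable truth.

Built for population geneticists working with a multi-sample VCF of
biallelic SNPs, GFF gene models, and a sample→population map — the typical
output of a resequencing study of a few tens of wild-caught diploids (the
motivating system is marine fish spawning populations, where megabase-scale
inversion blocks on a handful of chromosomes carry most of the observable
differentiation while the genomic background behaves as one outbreeding
population).

## Method

**Block detection.** Sites are filtered to biallelic SNPs with QUAL > 30,
complete genotyping, and minor-allele frequency ≥ 0.05. On each chromosome
every 250th SNP is retained and all pairwise LD among these subset SNPs is
computed as *r²*, the squared Pearson correlation of diploid dosage vectors
(composite LD — no phasing). For each subset SNP the mean *r²* against all
other subset SNPs on the chromosome is taken; for *n* samples of independent
loci this mean sits at its sampling floor 1/(n−1) (≈ 0.033 at n = 31), while
SNPs locked inside a non-recombining block rise far above it. The block is
called from the first and last subset SNP with mean *r²* > 0.1, with the
edges placed on the adjacent SNPs (the neighbouring subset SNP by default,
since untested linked loci live in the untyped gap; the literal neighbouring
SNP as an option). Single-span mode keeps internal linkage gaps inside one
block; a `max_gap` splitter is available.

**Differentiation.** Per-SNP Weir–Cockerham variance components
*a* (among populations), *b* (among individuals), *c* (within individuals)
give θ = a/(a+b+c); means over SNP sets are ratio-of-sums Σa/Σ(a+b+c).
Exonic SNPs are split in/out of each block (every 10th exonic SNP for the
rest of the genome), θ distributions are compared with a two-sided
two-sample Kolmogorov–Smirnov test, and PCA (centred, unscaled dosages)
is run inside and outside each block: in-block SNPs separate the samples
into three PC1 clusters — the two arrangement homozygotes and the
heterozygotes — which a 1-D 3-means assigns as block genotypes AA/AB/BB.

**Block content.** SNPs are binned exon/intron/intergenic (exon precedence
across overlapping genes), SNP density and exonic proportion are compared
in-block vs genome background as percent enrichment, in-block gene lists
are extracted, and GO-term enrichment is a per-term one-sided Fisher exact
test with Benjamini–Hochberg FDR.

**Simulator.** `SimConfig`/`simulate_dataset` emit VCF 4.2 + GFF3 + popmap
+ truth JSON for 2–3 populations of ~10 diploids: each individual draws two
arrangement haplotypes at its population's arrangement frequency;
arrangement-linked in-block SNPs mirror the carried arrangement; in-block
unlinked SNPs are low-MAF interior mutations; the background is a
founder-haplotype copying chain with short-range LD only; in-block SNP
density and exonic fraction are elevated. Deterministic per seed.

## Worked example

```bash
python analysis/01_simulate.py --seed 1 --out scratch/dataset
python analysis/02_scan_ld.py  --data scratch/dataset
python analysis/03_differentiation.py --data scratch/dataset
python analysis/04_block_content.py   --data scratch/dataset --seed 1
```

Step 1 plants a 2.5 Mb block (3,000,001–5,500,000) among ~51k SNPs for 31
samples in three populations with arrangement-B frequencies
0.50/0.85/0.15. The remaining steps print, for seed 1:

```
46126 SNPs retained; 184 subset SNPs
background mean r2: 0.0335 (expect ~1/(n-1) = 0.0333)
called block 2,989,382-5,529,037 (2.54 Mb); planted 3,000,001-5,500,000
  strongly linked: 35/61 subset SNPs (57%)

mean pairwise F_ST (exonic SNPs, ratio-of-sums):
subset  georges_bank_vs_spring  georges_bank_vs_winter  spring_vs_winter
    in                  0.2657                  0.4840            0.0296
   out                 -0.0001                  0.0001           -0.0008

KS tests, in-block vs out-of-block theta distributions:
georges_bank_vs_winter  D=0.5487  p=9.8e-269
block-genotype assignment from in-block PC1: 100% agreement

density_change_pct 42   exonic_change_pct 34
```

Read: the called edges land within one subset-SNP spacing of the planted
inversion; the background mean r² sits on the 1/(n−1) floor; mean θ is two
to three orders of magnitude higher inside the block than outside, with the
strongest contrast for the most-diverged arrangement frequencies
(0.85 vs 0.15); PC1 of in-block SNPs recovers every sample's arrangement
genotype; and the planted in-block density/exonic enrichments are
recovered. Small tables land under `results/`.

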