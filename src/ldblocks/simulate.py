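"""Synthetic inversion-polymorphism datasets with machine-readable truth.

The generator emulates the statistical structure the LD-block analysis
assumes: diploid samples from a few populations; one non-recombining block
per chromosome segregating as two "arrangements" (A/B) at population-specific
frequencies; arrangement-linked SNPs inside the block perfectly correlated
with the carried arrangement; a scattering of low-frequency *unlinked* SNPs
inside the block (recent mutations within an old inversion), placed in the
block interior away from the breakpoints where recombination suppression is
strongest; and a recombining neutral background produced by a
haplotype-copying chain (short-range LD that decays within a few SNPs, no
long-range LD). SNP density inside the block is elevated relative to the
background. Outputs are VCF 4.2 + GFF3 + popmap TSV + truth JSON, all
deterministic given the seed.

The module also hosts the *scalar* Weir-Cockerham formulas and a Monte-Carlo
expectation oracle, kept deliberately independent of the vectorized
estimator in :mod:`ldblocks.popgen` so the two can cross-check each other.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

# Truth classes for individual SNPs
LINKED, INBLOCK_UNLINKED, BACKGROUND = (
    "arrangement-linked",
    "inblock-unlinked",
    "background",
)


@dataclass
class SimConfig:
    """Study conditions for one simulated chromosome.

    Defaults mirror the sampling design the pipeline targets: three
    populations totalling 31 diploids, background SNP density ~5e-3 per base,
    a multi-megabase block at modestly elevated density, half of the in-block
    SNPs arrangement-linked, and arrangement frequencies that differentiate
    the populations.
    """

    seed: int = 0
    pops: tuple[tuple[str, int], ...] = (
        ("spring", 10),
        ("winter", 10),
        ("georges_bank", 11),
    )
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    n_snps_background: int = 35_000
    block: tuple[int, int] = (3_000_001, 5_500_000)
    n_snps_block: int | None = None  # default: from density_multiplier_block
    arrangement_freq: Mapping[str, float] = field(
        default_factory=lambda: {
            "spring": 0.50,
            "winter": 0.85,
            "georges_bank": 0.15,
        }
    )
    linked_fraction: float = 0.5
    background_ld_decay: float = 0.1  # per-SNP template-switch probability
    maf_floor: float = 0.05
    density_multiplier_block: float = 1.4
    breakpoint_margin_fraction: float = 0.05  # unlinked SNPs kept out of margins
    n_founder_haplotypes: int = 16
    gene_count: int = 300
    exon_fraction: float = 0.3
    # exonic fraction of in-block genes is boosted, emulating the elevated
    # exonic SNP proportion observed inside supergene blocks
    exon_fraction_multiplier_block: float = 1.4
    qual: float = 60.0

    def validate(self) -> None:
        bs, be = self.block
        if not (1 <= bs < be <= self.chrom_length):
            raise ValueError("block must satisfy 1 <= start < end <= length")
        for p, f in self.arrangement_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"arrangement_freq[{p}] outside [0, 1]")
        if not (0.0 <= self.linked_fraction <= 1.0):
            raise ValueError("linked_fraction outside [0, 1]")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor outside (0, 0.5)")
        if self.resolved_n_snps_block() > be - bs + 1:
            raise ValueError("more block SNPs than block bases")
        missing = [p for p, _ in self.pops if p not in self.arrangement_freq]
        if missing:
            raise ValueError(f"no arrangement frequency for: {missing}")

    def resolved_n_snps_block(self) -> int:
        if self.n_snps_block is not None:
            return self.n_snps_block
        bs, be = self.block
        block_len = be - bs + 1
        bg_len = self.chrom_length - block_len
        bg_density = self.n_snps_background / max(bg_len, 1)
        return int(round(self.density_multiplier_block * bg_density * block_len))

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{label}_{i + 1:02d}" for label, n in self.pops for i in range(n)
        ]


@dataclass
class SimTruth:
    """Ground truth emitted beside every dataset."""

    chrom: str
    block: tuple[int, int]
    samples: list[str]
    populations: list[str]                   # per sample
    arrangement_genotype: np.ndarray          # per sample, copies of B (0/1/2)
    positions: np.ndarray                     # per SNP, sorted ascending
    snp_class: np.ndarray                     # per SNP truth class
    genomic_class: np.ndarray                 # per SNP exon/intron/intergenic
    pop_allele_freq: dict[str, np.ndarray]    # per pop, per-SNP alt freq
    dosage: np.ndarray                        # sites x samples
    genes: list[tuple[str, int, int, tuple[tuple[int, int], ...]]]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "chrom": self.chrom,
            "block": list(self.block),
            "samples": self.samples,
            "populations": self.populations,
            "arrangement_genotype": self.arrangement_genotype.tolist(),
            "positions": self.positions.tolist(),
            "snp_class": self.snp_class.tolist(),
            "genomic_class": self.genomic_class.tolist(),
            "pop_allele_freq": {
                k: np.round(v, 6).tolist()
                for k, v in self.pop_allele_freq.items()
            },
            "genes": [
                [gid, s, e, [list(x) for x in exons]]
                for gid, s, e, exons in self.genes
            ],
        }
        Path(path).write_text(json.dumps(obj))


def two_pop_config(
    seed: int = 0, freq1: float = 0.3, freq2: float = 0.7, **overrides
) -> SimConfig:
    """Two-population recovery design: 10 + 10 diploids, a 0.5 Mb
    fully-linked block (a young inversion, no interior unlinked mutations)
    on a 10 Mb chromosome, ~52k SNPs total.

    At n = 20 samples the null mean r² already sits at 1/(n-1) ~ 0.053, so
    the 0.1 calling threshold leaves little headroom: the block must take a
    small share (~7%) of the subset SNPs to keep the shared-draw tail of the
    background means below threshold, and a fully linked block keeps the
    in-block subset count deterministic so the in-block means sit safely
    above it. See the methods note for the failure-mode calculation."""
    kwargs: dict = dict(
        seed=seed,
        pops=(("pop1", 10), ("pop2", 10)),
        arrangement_freq={"pop1": freq1, "pop2": freq2},
        n_snps_background=48_000,
        block=(4_750_001, 5_250_000),
        linked_fraction=1.0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# scalar Weir-Cockerham oracle
# ---------------------------------------------------------------------------

def wc_abc_scalar(
    dosages_by_pop: Sequence[Sequence[int]],
) -> tuple[float, float, float]:
    """Weir-Cockerham variance components for ONE biallelic site, written as
    plain scalar arithmetic straight from the component formulas (independent
    of the vectorized implementation)."""
    r = len(dosages_by_pop)
    if r < 2:
        raise ValueError("need >= 2 populations")
    n_i = [float(len(d)) for d in dosages_by_pop]
    if any(n < 2 for n in n_i):
        raise ValueError("each population needs >= 2 individuals")
    p_i = [sum(d) / (2.0 * n) for d, n in zip(dosages_by_pop, n_i)]
    h_i = [
        sum(1 for g in d if g == 1) / n for d, n in zip(dosages_by_pop, n_i)
    ]
    n_bar = sum(n_i) / r
    n_c = (r * n_bar - sum(n * n for n in n_i) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / (
        (r - 1) * n_bar
    )
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def wc_theta_scalar(dosages_by_pop: Sequence[Sequence[int]]) -> float:
    """theta = a/(a+b+c) for one site; NaN when the site is monomorphic
    across the pooled sample."""
    a, b, c = wc_abc_scalar(dosages_by_pop)
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return a / denom


def expected_wc_fst_oracle(
    freq_by_pop: Sequence[float],
    n_by_pop: Sequence[int],
    reps: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo expectation of the WC theta estimator: draw genotype
    tables by binomial (Hardy-Weinberg) sampling at the given allele
    frequencies and average the scalar estimator over replicates (undefined
    replicates excluded)."""
    if len(freq_by_pop) < 2:
        raise ValueError("need >= 2 populations")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        tables = [
            rng.binomial(2, p, size=n).tolist()
            for p, n in zip(freq_by_pop, n_by_pop)
        ]
        t = wc_theta_scalar(tables)
        if not math.isnan(t):
            vals.append(t)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _unique_sorted_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int
) -> np.ndarray:
    """n distinct positions uniform on [lo, hi], sorted."""
    span = hi - lo + 1
    if n > span:
        raise ValueError("more SNPs requested than available bases")
    return np.sort(rng.choice(span, size=n, replace=False).astype(np.int64) + lo)


def _copying_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    founders: np.ndarray,
    switch_p: float,
) -> np.ndarray:
    """Haplotype-copying chain: each haplotype walks left to right copying a
    founder template, re-choosing the template with probability ``switch_p``
    per SNP. Produces LD that decays over ~1/switch_p SNPs."""
    K, L = founders.shape
    switch = rng.random((n_hap, L)) < switch_p
    switch[:, 0] = True
    cand = rng.integers(0, K, size=(n_hap, L))
    site = np.arange(L, dtype=np.int64)
    last_switch = np.where(switch, site[None, :], 0)
    last_switch = np.maximum.accumulate(last_switch, axis=1)
    tmpl = np.take_along_axis(cand, last_switch, axis=1)
    return founders[tmpl, site[None, :]]


def _make_genes(
    cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[str, int, int, tuple[tuple[int, int], ...]]]:
    """Non-overlapping genes in regular slots, each with evenly spaced exons
    covering ~exon_fraction of the gene span."""
    genes = []
    slot = cfg.chrom_length // cfg.gene_count
    bs, be = cfg.block
    for k in range(cfg.gene_count):
        slot_start = k * slot + 1
        max_len = max(min(15_000, slot - 2), 200)
        min_len = min(2_000, max_len - 1)
        glen = int(rng.integers(min_len, max_len + 1))
        offset = int(rng.integers(0, slot - glen))
        start = slot_start + offset
        end = start + glen - 1
        ex_frac = cfg.exon_fraction
        if start <= be and end >= bs:
            ex_frac = min(ex_frac * cfg.exon_fraction_multiplier_block, 0.9)
        n_ex = 3
        exon_total = max(int(round(ex_frac * glen)), n_ex)
        ex_len = max(exon_total // n_ex, 1)
        gap = (glen - n_ex * ex_len) // n_ex if n_ex * ex_len < glen else 0
        exons = []
        cursor = start
        for _ in range(n_ex):
            a = cursor
            b = min(a + ex_len - 1, end)
            exons.append((a, b))
            cursor = b + 1 + gap
            if cursor > end:
                break
        genes.append((f"gene{k + 1:05d}", start, end, tuple(exons)))
    return genes


def _classify_naive(
    positions: np.ndarray,
    genes: list[tuple[str, int, int, tuple[tuple[int, int], ...]]],
) -> np.ndarray:
    """Truth-side genomic classes by per-gene linear scan (kept independent
    of annotation.classify_snps on purpose)."""
    out = np.full(len(positions), "intergenic", dtype=object)
    for _, gstart, gend, exons in genes:
        in_gene = (positions >= gstart) & (positions <= gend)
        for i in np.flatnonzero(in_gene):
            p = positions[i]
            if any(a <= p <= b for a, b in exons):
                out[i] = "exon"
            elif out[i] != "exon":
                out[i] = "intron"
    return out


@dataclass
class SimDataset:
    """In-memory simulated dataset (see :func:`simulate_dataset` for files)."""

    config: SimConfig
    truth: SimTruth


def simulate_matrices(cfg: SimConfig) -> SimDataset:
    """Generate the dataset in memory; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    bs, be = cfg.block
    n_block = cfg.resolved_n_snps_block()
    n_bg = cfg.n_snps_background

    samples = cfg.sample_names
    populations = [label for label, n in cfg.pops for _ in range(n)]
    n_samples = len(samples)

    # (1) arrangement haplotypes per individual: Bernoulli(freq_B) twice
    arr_h = np.concatenate(
        [
            rng.random((n, 2)) < cfg.arrangement_freq[label]
            for label, n in cfg.pops
        ]
    ).astype(np.int8)
    arr_geno = arr_h.sum(axis=1)  # copies of arrangement B per individual

    # (5) positions: uniform background outside the block, denser block
    left_len = bs - 1
    right_len = cfg.chrom_length - be
    n_left = int(round(n_bg * left_len / max(left_len + right_len, 1)))
    n_right = n_bg - n_left
    pos_left = (
        _unique_sorted_positions(rng, 1, bs - 1, n_left)
        if n_left
        else np.empty(0, dtype=np.int64)
    )
    pos_right = (
        _unique_sorted_positions(rng, be + 1, cfg.chrom_length, n_right)
        if n_right
        else np.empty(0, dtype=np.int64)
    )
    pos_block = (
        _unique_sorted_positions(rng, bs, be, n_block)
        if n_block
        else np.empty(0, dtype=np.int64)
    )

    # linked/unlinked split inside the block: unlinked SNPs only in the
    # interior, clear of the breakpoint margins
    n_linked = int(round(cfg.linked_fraction * n_block))
    n_unlinked = n_block - n_linked
    margin = int(round(cfg.breakpoint_margin_fraction * (be - bs + 1)))
    interior = np.flatnonzero(
        (pos_block >= bs + margin) & (pos_block <= be - margin)
    )
    if n_unlinked > len(interior):
        n_unlinked = len(interior)
        n_linked = n_block - n_unlinked
    unlinked_sel = rng.choice(interior, size=n_unlinked, replace=False)
    is_unlinked = np.zeros(n_block, dtype=bool)
    is_unlinked[unlinked_sel] = True

    # (2) arrangement-linked in-block SNPs: allele == arrangement, random
    # ref/alt polarity per SNP
    d_arr = arr_geno.astype(np.int16)  # dosage of the B-tagging allele
    flips = rng.random(n_block) < 0.5
    dos_block = np.empty((n_block, n_samples), dtype=np.int16)
    dos_block[~is_unlinked] = np.where(
        flips[~is_unlinked, None], 2 - d_arr[None, :], d_arr[None, :]
    )

    # (3) in-block unlinked SNPs: independent low-MAF draws (recent mutations)
    if n_unlinked:
        maf_u = rng.uniform(cfg.maf_floor, 0.15, size=n_unlinked)
        haps_u = (
            rng.random((n_unlinked, n_samples, 2)) < maf_u[:, None, None]
        ).astype(np.int16)
        dos_block[is_unlinked] = haps_u.sum(axis=2)

    # (4) background: founder pool + copying chain, two haplotypes/individual
    pos_bg = np.concatenate([pos_left, pos_right])
    n_bg_total = len(pos_bg)
    if n_bg_total:
        p_bg = rng.uniform(cfg.maf_floor, 0.5, size=n_bg_total)
        founders = (
            rng.random((cfg.n_founder_haplotypes, n_bg_total)) < p_bg[None, :]
        ).astype(np.int8)
        haps = _copying_haplotypes(
            rng, 2 * n_samples, founders, cfg.background_ld_decay
        )
        dos_bg = (
            haps.reshape(n_samples, 2, n_bg_total).sum(axis=1).T.astype(np.int16)
        )
    else:
        dos_bg = np.empty((0, n_samples), dtype=np.int16)

    # assemble in ascending-position order
    positions = np.concatenate([pos_bg, pos_block])
    dosage = np.vstack([dos_bg, dos_block])
    classes = np.concatenate(
        [
            np.full(n_bg_total, BACKGROUND, dtype=object),
            np.where(is_unlinked, INBLOCK_UNLINKED, LINKED),
        ]
    )
    order = np.argsort(positions, kind="mergesort")
    positions, dosage, classes = positions[order], dosage[order], classes[order]

    genes = _make_genes(cfg, rng)
    genomic_class = _classify_naive(positions, genes)

    pop_freq: dict[str, np.ndarray] = {}
    col = 0
    for label, n in cfg.pops:
        pop_freq[label] = dosage[:, col:col + n].sum(axis=1) / (2.0 * n)
        col += n

    truth = SimTruth(
        chrom=cfg.chrom,
        block=cfg.block,
        samples=samples,
        populations=populations,
        arrangement_genotype=arr_geno.astype(np.int64),
        positions=positions,
        snp_class=classes,
        genomic_class=genomic_class,
        pop_allele_freq=pop_freq,
        dosage=dosage,
        genes=genes,
    )
    return SimDataset(config=cfg, truth=truth)


_GT = np.array(["0/0", "0/1", "1/1"])
_BASES = "ACGT"


def write_vcf(ds: SimDataset, path: str | Path) -> None:
    """Serialize the dataset as VCF 4.2 (GT only, constant passing QUAL)."""
    cfg, truth = ds.config, ds.truth
    rng = np.random.default_rng(cfg.seed + 1_000_003)  # alleles only
    ref_idx = rng.integers(0, 4, size=len(truth.positions))
    alt_off = rng.integers(1, 4, size=len(truth.positions))
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={cfg.chrom},length={cfg.chrom_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(truth.samples),
    ]
    qual = f"{cfg.qual:g}"
    gts = _GT[truth.dosage]
    lines = header + [
        f"{cfg.chrom}\t{pos}\t.\t{_BASES[ref_idx[i]]}\t"
        f"{_BASES[(ref_idx[i] + alt_off[i]) % 4]}\t{qual}\t.\t.\tGT\t"
        + "\t".join(gts[i])
        for i, pos in enumerate(truth.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_gff(ds: SimDataset, path: str | Path) -> None:
    cfg = ds.config
    lines = ["##gff-version 3"]
    for gid, start, end, exons in ds.truth.genes:
        lines.append(
            f"{cfg.chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}"
        )
        for j, (a, b) in enumerate(exons):
            lines.append(
                f"{cfg.chrom}\tsim\texon\t{a}\t{b}\t.\t+\t.\t"
                f"ID={gid}.exon{j + 1};Parent={gid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_popmap(ds: SimDataset, path: str | Path) -> None:
    lines = [
        f"{s}\t{p}" for s, p in zip(ds.truth.samples, ds.truth.populations)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_dataset(
    cfg: SimConfig, outdir: str | Path
) -> tuple[Path, Path, Path, SimTruth]:
    """Generate and write VCF + GFF + popmap + truth JSON + run manifest to
    ``outdir``; returns (vcf, gff, popmap) paths and the in-memory truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_matrices(cfg)
    vcf = outdir / "sim.vcf"
    gff = outdir / "sim.gff3"
    popmap = outdir / "popmap.tsv"
    write_vcf(ds, vcf)
    write_gff(ds, gff)
    write_popmap(ds, popmap)
    ds.truth.to_json(outdir / "truth.json")
    manifest = {
        "seed": cfg.seed,
        "paths": {
            "vcf": str(vcf),
            "gff": str(gff),
            "popmap": str(popmap),
            "truth": str(outdir / "truth.json"),
        },
        "n_snps": int(len(ds.truth.positions)),
        "n_samples": len(ds.truth.samples),
        "block": list(cfg.block),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return vcf, gff, popmap, ds.truth
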