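"""Input/output layer: VCF genotypes, GFF gene models, population maps, BED.

All genomic coordinates are held 1-based inclusive internally (the VCF/GFF
convention); only BED output converts to 0-based half-open. Genotypes are
stored as alternate-allele dosages (0, 1, 2) with ``MISSING = -1`` for
uncalled or partial genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing or partially-called genotype.
MISSING: int = -1


@dataclass(frozen=True)
class SnpRecord:
    """A retained biallelic SNP site.

    ``idx`` is the 0-based ordinal of the site among retained SNPs on its
    chromosome, in ascending position order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    idx: int


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid dosage matrix plus per-site metadata.

    ``dosage[i, j]`` counts alternate alleles of sample ``j`` at site ``i``
    (0, 1, 2, or :data:`MISSING`). Rows are sorted by (chrom, pos).
    """

    snps: list[SnpRecord]
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.snps), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chroms(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.snps:
            seen.setdefault(s.chrom, None)
        return list(seen)

    def positions(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            return np.array([s.pos for s in self.snps], dtype=np.int64)
        return np.array(
            [s.pos for s in self.snps if s.chrom == chrom], dtype=np.int64
        )

    def site_indices(self, chrom: str) -> np.ndarray:
        """Row indices of the sites on ``chrom``."""
        return np.array(
            [i for i, s in enumerate(self.snps) if s.chrom == chrom],
            dtype=np.int64,
        )

    def take_sites(self, rows: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site rows (order preserved),
        re-assigning per-chromosome ordinals."""
        rows = np.asarray(rows, dtype=np.int64)
        snps = [self.snps[i] for i in rows]
        return GenotypeMatrix(
            snps=_reindex(snps), samples=list(self.samples),
            dosage=self.dosage[rows],
        )

    def allele_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency from called genotypes only."""
        d = self.dosage
        called = d != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class GeneModel:
    """A gene span with merged, non-overlapping exon intervals (1-based incl.)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for a, b in self.exons:
            if not (self.start <= a <= b <= self.end):
                raise ValueError(
                    f"gene {self.gene_id}: exon ({a},{b}) outside span"
                )


PopulationMap = Mapping[str, str]


def _reindex(snps: Iterable[SnpRecord]) -> list[SnpRecord]:
    out: list[SnpRecord] = []
    counters: dict[str, int] = {}
    for s in snps:
        k = counters.get(s.chrom, 0)
        out.append(replace(s, idx=k))
        counters[s.chrom] = k + 1
    return out


def read_vcf_genotypes(
    path: str | Path, samples: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained (multi-allelic and indel records
    are dropped and counted). Dosage is the alternate-allele count of the GT
    field; missing or partial genotypes become :data:`MISSING`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path), gts012=True)
    if samples is not None:
        missing = sorted(set(samples) - set(vcf.samples))
        if missing:
            raise KeyError(f"samples not present in VCF: {missing}")
        vcf.set_samples(list(samples))
    sample_names = list(vcf.samples)

    rows: list[tuple[str, int, str, str, float, np.ndarray]] = []
    n_dropped = 0
    for v in vcf:
        alts = v.ALT
        if (
            len(alts) != 1
            or len(v.REF) != 1
            or len(alts[0]) != 1
            or v.REF not in "ACGT"
            or alts[0] not in "ACGT"
        ):
            n_dropped += 1
            continue
        # gts012=True: 0/1/2 = dosage, 3 = unknown
        d = np.asarray(v.gt_types, dtype=np.int16)
        d[d == 3] = MISSING
        qual = float(v.QUAL) if v.QUAL is not None else float("nan")
        rows.append((v.CHROM, v.POS, v.REF, alts[0], qual, d))
    if n_dropped:
        logger.info("read_vcf_genotypes: dropped %d non-biallelic-SNP records",
                    n_dropped)

    rows.sort(key=lambda r: (r[0], r[1]))
    snps = _reindex(
        SnpRecord(chrom=c, pos=p, ref=r, alt=a, qual=q, idx=0)
        for c, p, r, a, q, _ in rows
    )
    dosage = (
        np.vstack([r[5] for r in rows])
        if rows
        else np.empty((0, len(sample_names)), dtype=np.int16)
    )
    gm = GenotypeMatrix(snps=snps, samples=sample_names, dosage=dosage)
    gm.n_dropped_records = n_dropped  # type: ignore[attr-defined]
    return gm


def apply_site_filters(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    min_qual: float = 30.0,
    require_complete: bool = True,
) -> GenotypeMatrix:
    """Apply the site filters: QUAL strictly above ``min_qual``, complete
    genotyping across all samples (optional), and minor-allele frequency at or
    above ``maf_min`` (inclusive; MAF estimated from called genotypes).

    Idempotent; returns an empty matrix (with a warning) if nothing survives.
    """
    if gm.n_sites == 0:
        return gm
    qual = np.array([s.qual for s in gm.snps], dtype=float)
    keep_q = qual > min_qual
    complete = (gm.dosage != MISSING).all(axis=1)
    keep_c = complete if require_complete else np.ones(gm.n_sites, dtype=bool)
    maf = gm.maf()
    keep_m = np.nan_to_num(maf, nan=-1.0) >= maf_min
    keep = keep_q & keep_c & keep_m
    logger.info(
        "apply_site_filters: %d/%d pass QUAL>%g, %d pass completeness, "
        "%d pass MAF>=%g; %d retained",
        int(keep_q.sum()), gm.n_sites, min_qual, int(keep_c.sum()),
        int(keep_m.sum()), maf_min, int(keep.sum()),
    )
    if not keep.any():
        logger.warning("apply_site_filters: all %d sites removed", gm.n_sites)
    return gm.take_sites(np.flatnonzero(keep))


def read_popmap(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id <TAB> population) -> assignment dict."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed popmap line: {line!r}")
        out[parts[0]] = parts[1]
    return out


def check_popmap(pm: PopulationMap, gm: GenotypeMatrix) -> None:
    """Every sample mapped, and >= 2 populations for differentiation work."""
    unmapped = [s for s in gm.samples if s not in pm]
    if unmapped:
        raise KeyError(f"samples missing from population map: {unmapped}")
    if len({pm[s] for s in gm.samples}) < 2:
        raise ValueError("population map has fewer than 2 populations")


def _merge_intervals(iv: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    if not iv:
        return ()
    iv = sorted(iv)
    merged = [list(iv[0])]
    for a, b in iv[1:]:
        if a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into :class:`GeneModel` records.

    Exons are attached through their Parent attribute (one level of mRNA
    indirection is resolved); overlapping exons are merged. Orphan exons are
    skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        genes[g.id] = {
            "chrom": g.seqid, "start": g.start, "end": g.end, "exons": [],
        }
    transcript_parent: dict[str, str] = {}
    for ft in ("mRNA", "transcript"):
        try:
            for t in db.features_of_type(ft):
                p = t.attributes.get("Parent", [None])[0]
                if p in genes:
                    transcript_parent[t.id] = p
        except Exception:  # feature type absent
            continue
    for ex in db.features_of_type("exon"):
        parents = ex.attributes.get("Parent", [])
        gene_id = None
        for p in parents:
            if p in genes:
                gene_id = p
                break
            if p in transcript_parent:
                gene_id = transcript_parent[p]
                break
        if gene_id is None:
            logger.warning("exon at %s:%d-%d has no resolvable gene parent; "
                           "skipped", ex.seqid, ex.start, ex.end)
            continue
        genes[gene_id]["exons"].append((ex.start, ex.end))
    return [
        GeneModel(
            gene_id=gid,
            chrom=info["chrom"],
            start=info["start"],
            end=info["end"],
            exons=_merge_intervals(info["exons"]),
        )
        for gid, info in genes.items()
    ]


def write_block_bed(blocks: Sequence, path: str | Path) -> None:
    """Write called blocks as BED (0-based half-open), with a name and the
    in-block mean-LD score columns."""
    lines = ["#chrom\tstart\tend\tname\tmean_r2"]
    for i, b in enumerate(blocks):
        score = getattr(b, "mean_r2_in_block", float("nan"))
        lines.append(
            f"{b.chrom}\t{b.start - 1}\t{b.end}\tblock_{i + 1}\t{score:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_block_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a block BED back to 1-based inclusive (chrom, start, end) tuples."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out
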