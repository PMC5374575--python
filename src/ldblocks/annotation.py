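"""Genomic-context annotation of SNPs and block-content enrichment.

SNPs are binned into exon / intron / intergenic (exon wins over intron across
overlapping genes); density and class-proportion changes inside a block are
summarised as percent enrichment; in-block gene lists and per-GO-term Fisher
exact tests with Benjamini-Hochberg correction describe block gene content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import GeneModel, SnpRecord

EXON, INTRON, INTERGENIC = "exon", "intron", "intergenic"


def _merged_sorted(intervals: Iterable[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge 1-based inclusive intervals; return sorted (starts, ends)."""
    iv = sorted(intervals)
    starts: list[int] = []
    ends: list[int] = []
    for a, b in iv:
        if starts and a <= ends[-1]:
            ends[-1] = max(ends[-1], b)
        else:
            starts.append(a)
            ends.append(b)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    j = np.searchsorted(starts, pos, side="right") - 1
    j_ok = j >= 0
    hit = np.zeros(len(pos), dtype=bool)
    hit[j_ok] = pos[j_ok] <= ends[j[j_ok]]
    return hit


def classify_snps(
    snps: Sequence[SnpRecord], genes: Sequence[GeneModel]
) -> np.ndarray:
    """Per-SNP class array in {exon, intron, intergenic}.

    Precedence: inside any (merged) exon interval -> exon; else inside any
    gene span -> intron; else intergenic. Exon precedence applies across
    genes, so a SNP in one gene's exon that lies in another gene's intron is
    still exonic.
    """
    by_chrom_exons: dict[str, list[tuple[int, int]]] = {}
    by_chrom_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom_spans.setdefault(g.chrom, []).append((g.start, g.end))
        by_chrom_exons.setdefault(g.chrom, []).extend(g.exons)
    out = np.full(len(snps), INTERGENIC, dtype=object)
    pos_by_chrom: dict[str, list[int]] = {}
    idx_by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(snps):
        pos_by_chrom.setdefault(s.chrom, []).append(s.pos)
        idx_by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, positions in pos_by_chrom.items():
        pos = np.asarray(positions, dtype=np.int64)
        idx = np.asarray(idx_by_chrom[chrom], dtype=np.int64)
        ex_s, ex_e = _merged_sorted(by_chrom_exons.get(chrom, []))
        sp_s, sp_e = _merged_sorted(by_chrom_spans.get(chrom, []))
        in_exon = _in_intervals(pos, ex_s, ex_e)
        in_gene = _in_intervals(pos, sp_s, sp_e)
        out[idx[in_exon]] = EXON
        out[idx[in_gene & ~in_exon]] = INTRON
    return out


def snp_density(
    positions: np.ndarray | Sequence[int], span: tuple[int, int]
) -> float:
    """SNPs per base inside a 1-based inclusive span."""
    start, end = span
    length = end - start + 1
    if length < 1:
        raise ValueError("region length must be >= 1")
    pos = np.asarray(positions, dtype=np.int64)
    return float(((pos >= start) & (pos <= end)).sum()) / length


def enrichment_ratio(baseline: float, inblock: float) -> float:
    """Percent change of ``inblock`` over ``baseline``, rounded to the
    nearest integer percent; NaN when the baseline is 0."""
    if baseline == 0:
        return float("nan")
    return float(round(100.0 * (inblock / baseline - 1.0)))


def genes_in_block(
    genes: Sequence[GeneModel], block, mode: str = "overlap"
) -> list[GeneModel]:
    """Genes belonging to a block: any >= 1 base overlap by default, or full
    containment with ``mode='contained'``."""
    if mode not in ("overlap", "contained"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for g in genes:
        if g.chrom != block.chrom:
            continue
        if mode == "overlap":
            if g.start <= block.end and g.end >= block.start:
                out.append(g)
        else:
            if g.start >= block.start and g.end <= block.end:
                out.append(g)
    return out


@dataclass
class EnrichmentRow:
    go_id: str
    term: str
    annotated: int    # background genes carrying the term
    significant: int  # in-block genes carrying the term
    fisher_p: float
    p_adj: float


def go_fisher_enrichment(
    block_genes: Sequence[str],
    background_genes: Sequence[str],
    go_annotation: Mapping[str, set[str] | Sequence[str]],
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term one-sided Fisher exact enrichment of in-block genes over the
    background, Benjamini-Hochberg adjusted across tested terms.

    Terms with zero in-block members are skipped. Returns a DataFrame with
    columns (go_id, term, annotated, significant, fisher_p, p_adj), sorted by
    p_adj then fisher_p.
    """
    if not go_annotation:
        raise ValueError("empty GO annotation")
    bg = list(dict.fromkeys(background_genes))
    blk = set(block_genes)
    stray = blk - set(bg)
    if stray:
        raise ValueError(f"block genes not in background: {sorted(stray)[:5]}")
    n_bg = len(bg)
    n_blk = len(blk)
    terms: dict[str, set[str]] = {}
    for gene in bg:
        for t in go_annotation.get(gene, ()):  # genes without terms allowed
            terms.setdefault(t, set()).add(gene)
    rows = []
    for t, carriers in sorted(terms.items()):
        annotated = len(carriers)
        significant = len(carriers & blk)
        if significant == 0:
            continue
        table = [
            [significant, annotated - significant],
            [n_blk - significant, (n_bg - annotated) - (n_blk - significant)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append((t, annotated, significant, float(p)))
    if not rows:
        return pd.DataFrame(
            columns=["go_id", "term", "annotated", "significant",
                     "fisher_p", "p_adj"]
        )
    p_vals = [r[3] for r in rows]
    _, p_adj, _, _ = multipletests(p_vals, method="fdr_bh")
    df = pd.DataFrame(
        {
            "go_id": [r[0] for r in rows],
            "term": [
                (term_names or {}).get(r[0], "") for r in rows
            ],
            "annotated": [r[1] for r in rows],
            "significant": [r[2] for r in rows],
            "fisher_p": p_vals,
            "p_adj": p_adj,
        }
    )
    return df.sort_values(
        ["p_adj", "fisher_p", "go_id"], kind="mergesort"
    ).reset_index(drop=True)


def read_go_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id <TAB> go_id) -> gene -> set of terms."""
    from pathlib import Path

    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene, term = line.split("\t")[:2]
        out.setdefault(gene, set()).add(term)
    return out
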