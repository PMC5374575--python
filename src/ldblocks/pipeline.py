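"""End-to-end orchestration: filter -> classify -> LD scan -> block calling
-> exonic subsetting -> F_ST -> KS -> PCA -> block genotypes -> gene content
and enrichment tables, with a manifest and per-stage logging.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, ld_scan, popgen
from .data_io import (
    GenotypeMatrix,
    apply_site_filters,
    check_popmap,
    read_gene_models,
    read_popmap,
    read_vcf_genotypes,
    write_block_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis parameters. Defaults are the replication parameter set:
    stride 250 for the LD subsample, mean-r² threshold 0.1, MAF floor 0.05,
    site QUAL > 30, every 10th exonic SNP for the genome-wide subset."""

    vcf: str
    gff: str
    popmap: str
    outdir: str
    go_map: str | None = None
    stride_ld: int = 250
    stride_exonic_genome: int = 10
    ld_threshold: float = 0.1
    maf_min: float = 0.05
    min_qual: float = 30.0
    edge_rule: str = "adjacent-subset"
    max_gap: int | None = None
    block_chroms: tuple[str, ...] = ()  # empty = scan all chromosomes
    seed: int = 0

    def validate(self) -> None:
        if self.stride_ld < 1 or self.stride_exonic_genome < 1:
            raise ValueError("strides must be >= 1")
        if not (0.0 < self.ld_threshold < 1.0):
            raise ValueError("ld_threshold must be in (0, 1)")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def exonic_subsets(
    gm: GenotypeMatrix,
    classes: np.ndarray,
    blocks: dict[str, ld_scan.LdBlock],
    stride_genome: int = 10,
) -> dict[str, np.ndarray]:
    """Partition exonic SNPs for differentiation analyses: on each
    block-bearing chromosome all exonic SNPs split in/out of its block; on
    the remaining chromosomes every ``stride_genome``-th exonic SNP pooled
    into a "genome" subset."""
    is_exon = classes == annotation.EXON
    subsets: dict[str, list[int]] = {}
    genome_rows: list[int] = []
    per_chrom_count: dict[str, int] = {}
    for i, snp in enumerate(gm.snps):
        if not is_exon[i]:
            continue
        blk = blocks.get(snp.chrom)
        if blk is not None:
            key = (
                f"{snp.chrom}:in"
                if blk.start <= snp.pos <= blk.end
                else f"{snp.chrom}:out"
            )
            subsets.setdefault(key, []).append(i)
        else:
            k = per_chrom_count.get(snp.chrom, 0)
            if (k + 1) % stride_genome == 0:
                genome_rows.append(i)
            per_chrom_count[snp.chrom] = k + 1
    out = {k: np.asarray(v, dtype=np.int64) for k, v in subsets.items()}
    if genome_rows:
        out["genome"] = np.asarray(genome_rows, dtype=np.int64)
    return out


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory. Any stage failure
    aborts with the stage name; tables written so far are preserved."""
    cfg.validate()
    missing = [
        str(getattr(cfg, name))
        for name in ("vcf", "gff", "popmap", "go_map")
        if getattr(cfg, name) is not None and not Path(getattr(cfg, name)).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("ldblocks")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
        "inputs": {},
        "stages": {},
    }
    for name in ("vcf", "gff", "popmap", "go_map"):
        p = getattr(cfg, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    stage = "init"
    try:
        t0 = time.time()
        stage = "read+filter"
        gm_raw = read_vcf_genotypes(cfg.vcf)
        gm = apply_site_filters(
            gm_raw, maf_min=cfg.maf_min, min_qual=cfg.min_qual,
            require_complete=True,
        )
        pops = read_popmap(cfg.popmap)
        check_popmap(pops, gm)
        pop_labels = sorted({pops[s] for s in gm.samples})
        manifest["stages"][stage] = {
            "sites_read": gm_raw.n_sites,
            "sites_retained": gm.n_sites,
            "samples": gm.n_samples,
            "populations": pop_labels,
        }
        logger.info("[%s] %d/%d sites retained, %d samples", stage,
                    gm.n_sites, gm_raw.n_sites, gm.n_samples)

        stage = "classify-snps"
        genes = read_gene_models(cfg.gff)
        classes = annotation.classify_snps(gm.snps, genes)
        cls_counts = pd.Series(classes).value_counts().to_dict()
        manifest["stages"][stage] = {"genes": len(genes), "classes": cls_counts}
        logger.info("[%s] %d genes, class counts %s", stage, len(genes),
                    cls_counts)

        stage = "ld-scan"
        scan_chroms = (
            list(cfg.block_chroms) if cfg.block_chroms else gm.chroms()
        )
        profiles: dict[str, ld_scan.LdProfile] = {}
        blocks: dict[str, ld_scan.LdBlock] = {}
        block_rows = []
        for chrom in scan_chroms:
            prof = ld_scan.ld_profile(gm, chrom, stride=cfg.stride_ld)
            profiles[chrom] = prof
            _write_tsv(
                pd.DataFrame(
                    {"chrom": chrom, "pos": prof.subset_pos,
                     "mean_r2": prof.mean_r2}
                ),
                outdir / f"ld_profile_{chrom}.tsv",
            )
            called = ld_scan.call_blocks(
                prof, threshold=cfg.ld_threshold, edge_rule=cfg.edge_rule,
                max_gap=cfg.max_gap,
            )
            if called:
                # single-span default: one block per chromosome; keep the
                # widest when max_gap splitting produced several
                blk = max(called, key=lambda b: b.length)
                blocks[chrom] = blk
                for b in called:
                    block_rows.append(
                        {
                            "chrom": b.chrom, "start": b.start, "end": b.end,
                            "length": b.length,
                            "n_subset_in_block": b.n_subset_in_block,
                            "n_strongly_linked": b.n_strongly_linked,
                        }
                    )
        write_block_bed(list(blocks.values()), outdir / "blocks.bed")
        _write_tsv(pd.DataFrame(block_rows), outdir / "blocks.tsv")
        manifest["stages"][stage] = {
            "chroms_scanned": scan_chroms,
            "blocks_called": {c: [b.start, b.end] for c, b in blocks.items()},
        }
        logger.info("[%s] %d chromosome(s), %d block(s)", stage,
                    len(scan_chroms), len(blocks))

        stage = "exonic-subsets"
        subsets = exonic_subsets(
            gm, classes, blocks, stride_genome=cfg.stride_exonic_genome
        )
        manifest["stages"][stage] = {k: int(len(v)) for k, v in subsets.items()}
        logger.info("[%s] %s", stage, manifest["stages"][stage])

        stage = "fst"
        pairs = list(combinations(pop_labels, 2))
        fst_rows = []
        summary: dict[str, dict[str, float]] = {}
        theta_by: dict[tuple[str, tuple[str, str]], np.ndarray] = {}
        for key, rows in subsets.items():
            summary[key] = {}
            for pair in pairs:
                ft = popgen.wc_fst(gm, pops, pair=pair, snp_set=rows)
                summary[key][f"{pair[0]}_vs_{pair[1]}"] = ft.mean_theta
                theta_by[(key, pair)] = ft.table["theta"].to_numpy()
                tab = ft.table.assign(
                    subset=key, pair=f"{pair[0]}_vs_{pair[1]}"
                )
                fst_rows.append(tab[["chrom", "pos", "subset", "pair", "theta"]])
        if fst_rows:
            _write_tsv(pd.concat(fst_rows), outdir / "fst_per_snp.tsv")
        summary_df = pd.DataFrame(summary).T.rename_axis("subset").reset_index()
        _write_tsv(summary_df, outdir / "fst_summary.tsv")
        # chromosome-wide multi-population theta track at the LD subsample
        if len(pop_labels) >= 2:
            track_rows = []
            for chrom, prof in profiles.items():
                if len(prof.subset_idx) == 0:
                    continue
                chrom_rows = gm.site_indices(chrom)[prof.subset_idx]
                ft = popgen.wc_fst(gm, pops, pair=None, snp_set=chrom_rows)
                track_rows.append(ft.table[["chrom", "pos", "theta"]])
            if track_rows:
                _write_tsv(pd.concat(track_rows), outdir / "fst_track.tsv")
        manifest["stages"][stage] = {
            "pairs": [f"{a}_vs_{b}" for a, b in pairs],
            "mean_theta": summary,
        }
        logger.info("[%s] %d pair(s) x %d subset(s)", stage, len(pairs),
                    len(subsets))

        stage = "ks"
        ks_rows = []
        for chrom in blocks:
            for pair in pairs:
                key_in, key_out = f"{chrom}:in", f"{chrom}:out"
                if key_in not in subsets or key_out not in subsets:
                    continue
                ks = popgen.fst_distribution_test(
                    theta_by[(key_in, pair)], theta_by[(key_out, pair)]
                )
                ks_rows.append(
                    {
                        "chrom": chrom, "pair": f"{pair[0]}_vs_{pair[1]}",
                        "D": ks.D, "p": ks.p, "n_in": ks.n_in,
                        "n_out": ks.n_out,
                    }
                )
        _write_tsv(pd.DataFrame(ks_rows), outdir / "ks_tests.tsv")
        manifest["stages"][stage] = {"comparisons": len(ks_rows)}

        stage = "pca"
        for chrom in blocks:
            for side in ("in", "out"):
                key = f"{chrom}:{side}"
                if key not in subsets or len(subsets[key]) == 0:
                    continue
                pr = popgen.pca_genotypes(gm, snp_set=subsets[key])
                _write_tsv(
                    pd.DataFrame(
                        {
                            "sample": gm.samples,
                            "population": [pops[s] for s in gm.samples],
                            "PC1": pr.scores[:, 0],
                            "PC2": pr.scores[:, 1],
                        }
                    ),
                    outdir / f"pca_{chrom}_{side}.tsv",
                )
        manifest["stages"][stage] = {"blocks": list(blocks)}

        stage = "block-genotypes"
        bg_rows = []
        for chrom, blk in blocks.items():
            try:
                bg = popgen.assign_block_genotypes(
                    gm, blk, profiles[chrom], threshold=cfg.ld_threshold,
                    random_state=cfg.seed,
                )
            except ValueError as e:
                logger.warning("[%s] %s: %s", stage, chrom, e)
                continue
            for s, lab, pc1 in zip(gm.samples, bg.labels, bg.pc1):
                bg_rows.append(
                    {"chrom": chrom, "sample": s, "block_genotype": lab,
                     "PC1": pc1}
                )
        _write_tsv(pd.DataFrame(bg_rows), outdir / "block_genotypes.tsv")
        manifest["stages"][stage] = {"rows": len(bg_rows)}

        stage = "block-content"
        positions_all = gm.positions()
        chrom_arr = np.array([s.chrom for s in gm.snps], dtype=object)
        enr_rows = []
        for chrom, blk in blocks.items():
            in_block_genes = annotation.genes_in_block(genes, blk)
            _write_tsv(
                pd.DataFrame(
                    {
                        "gene_id": [g.gene_id for g in in_block_genes],
                        "start": [g.start for g in in_block_genes],
                        "end": [g.end for g in in_block_genes],
                    }
                ),
                outdir / f"genes_in_block_{chrom}.tsv",
            )
            on_chrom = chrom_arr == chrom
            in_blk = on_chrom & (positions_all >= blk.start) & (
                positions_all <= blk.end
            )
            bg_mask = ~in_blk
            dens_in = annotation.snp_density(
                positions_all[in_blk], (blk.start, blk.end)
            )
            # background density over the rest of the dataset's span
            bg_span = int(positions_all.max()) - int(positions_all.min()) + 1
            dens_bg = bg_mask.sum() / max(bg_span - blk.length, 1)
            ex_in = float(np.mean(classes[in_blk] == annotation.EXON)) \
                if in_blk.any() else float("nan")
            ex_bg = float(np.mean(classes[bg_mask] == annotation.EXON)) \
                if bg_mask.any() else float("nan")
            enr_rows.append(
                {
                    "chrom": chrom,
                    "n_genes_in_block": len(in_block_genes),
                    "snp_density_in": dens_in,
                    "snp_density_out": dens_bg,
                    "density_change_pct": annotation.enrichment_ratio(
                        dens_bg, dens_in
                    ),
                    "exonic_prop_in": ex_in,
                    "exonic_prop_out": ex_bg,
                    "exonic_change_pct": annotation.enrichment_ratio(
                        ex_bg, ex_in
                    ),
                }
            )
            if cfg.go_map is not None:
                go = annotation.read_go_map(cfg.go_map)
                bg_ids = [g.gene_id for g in genes]
                blk_ids = [g.gene_id for g in in_block_genes]
                enr = annotation.go_fisher_enrichment(blk_ids, bg_ids, go)
                _write_tsv(enr, outdir / f"go_enrichment_{chrom}.tsv")
        _write_tsv(pd.DataFrame(enr_rows), outdir / "block_enrichment.tsv")
        manifest["stages"][stage] = {"blocks": list(blocks)}

        manifest["elapsed_s"] = round(time.time() - t0, 2)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("pipeline complete in %.1f s", manifest["elapsed_s"])
        return outdir
    except Exception as e:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.error("pipeline aborted at stage %r: %s", stage, e)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    finally:
        root.removeHandler(handler)
        handler.close()
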