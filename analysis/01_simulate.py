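#!/usr/bin/env python
"""Step 1 — generate the study dataset.

Simulates the default three-population design (spring / winter / Georges
Bank-style labels, 31 diploids) on a 10 Mb chromosome: ~51k biallelic SNPs,
one 2.5 Mb inversion-like block at 1.4x SNP density whose two arrangements
segregate at population-specific frequencies (0.50 / 0.85 / 0.15), plus a
toy gene annotation. Writes VCF + GFF3 + popmap + truth JSON.

The VCF is tens of megabytes, so it goes under scratch/ by default; the
downstream steps read it from there and write their small tables under
results/.
"""

import argparse
from pathlib import Path

from ldblocks.simulate import SimConfig, simulate_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/dataset"))
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    vcf, gff, popmap, truth = simulate_dataset(cfg, args.out)
    n_linked = int((truth.snp_class == "arrangement-linked").sum())
    print(f"dataset written to {args.out}")
    print(f"  {len(truth.positions)} SNPs x {len(truth.samples)} samples "
          f"on {cfg.chrom} ({cfg.chrom_length/1e6:.0f} Mb)")
    print(f"  planted block {cfg.block[0]:,}-{cfg.block[1]:,} "
          f"({(cfg.block[1]-cfg.block[0]+1)/1e6:.1f} Mb), "
          f"{n_linked} arrangement-linked SNPs "
          f"of {cfg.resolved_n_snps_block()} in block")
    print(f"  arrangement frequencies: {dict(cfg.arrangement_freq)}")
    counts = {g: int((truth.arrangement_genotype == g).sum()) for g in (0, 1, 2)}
    print(f"  arrangement genotype counts (copies of B): {counts}")


if __name__ == "__main__":
    main()
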