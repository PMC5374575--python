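from __future__ import annotations

import numpy as np
import pytest

import ldblocks as lb
from ldblocks.simulate import SimConfig, SimDataset, simulate_matrices


def gm_from_truth(ds: SimDataset) -> lb.GenotypeMatrix:
    """Build a GenotypeMatrix straight from simulator truth (skips the VCF
    round trip; data_io tests exercise that path separately)."""
    tr = ds.truth
    snps = [
        lb.SnpRecord(
            chrom=ds.config.chrom, pos=int(p), ref="A", alt="G",
            qual=ds.config.qual, idx=i,
        )
        for i, p in enumerate(tr.positions)
    ]
    return lb.GenotypeMatrix(snps=snps, samples=tr.samples, dosage=tr.dosage)


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """Fast three-population dataset (~17k SNPs, 31 samples) for unit tests."""
    kwargs: dict = dict(
        seed=seed,
        chrom_length=4_000_000,
        n_snps_background=12_000,
        block=(1_200_001, 2_200_000),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_ds() -> SimDataset:
    return simulate_matrices(small_config())


@pytest.fixture(scope="session")
def small_gm(small_ds) -> lb.GenotypeMatrix:
    return gm_from_truth(small_ds)


@pytest.fixture(scope="session")
def small_popmap(small_ds) -> dict[str, str]:
    return dict(zip(small_ds.truth.samples, small_ds.truth.populations))


@pytest.fixture(scope="session")
def written_dataset(tmp_path_factory):
    """A small dataset written to disk (VCF + GFF + popmap + truth)."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = small_config(seed=23, gene_count=50)
    vcf, gff, popmap, truth = lb.simulate_dataset(cfg, outdir)
    return {"cfg": cfg, "vcf": vcf, "gff": gff, "popmap": popmap,
            "truth": truth, "dir": outdir}


def best_label_accuracy(pred: list[str], truth_geno: np.ndarray) -> float:
    """Assignment accuracy up to the AA/BB polarity ambiguity (PC1 sign is
    arbitrary; AB is anchored as the middle cluster)."""
    truth_lab = np.array(["AA", "AB", "BB"])[truth_geno]
    pred = np.asarray(pred)
    swap = np.where(pred == "AA", "BB", np.where(pred == "BB", "AA", pred))
    return float(max(np.mean(pred == truth_lab), np.mean(swap == truth_lab)))
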