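"""Population differentiation statistics partitioned by LD block.

Implements the Weir & Cockerham (1984) moment estimator of F_ST from its
variance components a (among populations), b (among individuals within
populations) and c (within individuals), per SNP and as a ratio-of-sums mean
over SNP sets; two-sample Kolmogorov-Smirnov comparison of per-SNP theta
distributions; PCA of dosage matrices; and 3-means assignment of per-sample
block genotypes (the two arrangement homozygotes and the heterozygote) from
the leading principal component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .data_io import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_components(
    dosage: np.ndarray, pop_cols: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c).

    ``dosage`` is sites x samples with no missing entries; ``pop_cols`` lists,
    per population, the column indices of its members. Uses the two-level
    (population / individual) decomposition with observed heterozygosity.
    Biallelic sites only: components are computed for the alternate allele
    (theta is allele-symmetric).
    """
    d = np.asarray(dosage, dtype=float)
    if d.ndim == 1:
        d = d[None, :]
    if (d == MISSING).any():
        raise ValueError("wc_components requires complete genotypes")
    r = len(pop_cols)
    if r < 2:
        raise ValueError("need >= 2 populations")
    n_i = np.array([len(c) for c in pop_cols], dtype=float)  # (r,)
    if (n_i < 2).any():
        raise ValueError("each population needs >= 2 individuals")
    # per-pop alt-allele frequency and observed het proportion, (sites, r)
    p_i = np.stack([d[:, c].mean(axis=1) / 2.0 for c in pop_cols], axis=1)
    h_i = np.stack([(d[:, c] == 1).mean(axis=1) for c in pop_cols], axis=1)

    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=1) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=1) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def theta_from_components(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Per-site theta = a / (a+b+c); NaN where the denominator is 0
    (monomorphic across the pooled sample)."""
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom != 0, a / np.where(denom == 0, 1, denom), np.nan)


def mean_theta(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums mean over a SNP set: sum(a) / sum(a+b+c), undefined
    sites (zero denominator) excluded. This is the `hierfstat`-style overall
    estimate, not the average of per-SNP ratios."""
    denom = a + b + c
    ok = (denom != 0) & ~np.isnan(denom)
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


@dataclass
class FstTable:
    """Per-SNP WC components for one population comparison plus the
    ratio-of-sums mean."""

    pair: tuple[str, ...]
    table: pd.DataFrame  # columns: chrom, pos, a, b, c, theta
    mean_theta: float


def wc_fst(
    gm: GenotypeMatrix,
    pops: PopulationMap,
    pair: tuple[str, ...] | None = None,
    snp_set: np.ndarray | None = None,
) -> FstTable:
    """Weir-Cockerham F_ST between the populations in ``pair`` (default: all
    populations in the map — the multi-population estimator used for
    chromosome-wide theta tracks) over the sites in ``snp_set``."""
    labels = [pops[s] for s in gm.samples]
    if pair is None:
        pair = tuple(dict.fromkeys(labels))
    missing_pops = [p for p in pair if p not in labels]
    if missing_pops:
        raise KeyError(f"populations absent from data: {missing_pops}")
    if snp_set is None:
        snp_set = np.arange(gm.n_sites)
    snp_set = np.asarray(snp_set, dtype=np.int64)
    if snp_set.size == 0:
        raise ValueError("snp_set is empty")
    pop_cols = [
        np.array([j for j, lab in enumerate(labels) if lab == p], dtype=np.int64)
        for p in pair
    ]
    a, b, c = wc_components(gm.dosage[snp_set], pop_cols)
    theta = theta_from_components(a, b, c)
    tab = pd.DataFrame(
        {
            "chrom": [gm.snps[i].chrom for i in snp_set],
            "pos": [gm.snps[i].pos for i in snp_set],
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )
    return FstTable(pair=tuple(pair), table=tab, mean_theta=mean_theta(a, b, c))


# ---------------------------------------------------------------------------
# KS comparison of theta distributions
# ---------------------------------------------------------------------------

@dataclass
class KsComparison:
    D: float
    p: float
    n_in: int
    n_out: int


def fst_distribution_test(
    fst_in: np.ndarray, fst_out: np.ndarray
) -> KsComparison:
    """Two-sample two-sided KS test between in-block and out-of-block per-SNP
    theta distributions (NaN thetas removed first)."""
    x = np.asarray(fst_in, dtype=float)
    y = np.asarray(fst_out, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError(
            f"empty theta sample after NaN removal (n_in={x.size}, "
            f"n_out={y.size})"
        )
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return KsComparison(
        D=float(res.statistic), p=float(res.pvalue), n_in=x.size, n_out=y.size
    )


# ---------------------------------------------------------------------------
# PCA and block-genotype assignment
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray              # samples x components
    explained_variance: np.ndarray  # per component
    loadings: np.ndarray            # components x SNPs


def pca_genotypes(
    gm: GenotypeMatrix,
    snp_set: np.ndarray | None = None,
    n_components: int = 2,
) -> PcaResult:
    """PCA with samples as observations and SNP dosages as variables;
    variables are centred but not scaled."""
    if gm.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    if snp_set is None:
        snp_set = np.arange(gm.n_sites)
    snp_set = np.asarray(snp_set, dtype=np.int64)
    if snp_set.size == 0:
        raise ValueError("snp_set is empty")
    X = gm.dosage[snp_set].T.astype(float)  # samples x SNPs
    if (X == MISSING).any():
        raise ValueError("PCA requires complete genotypes")
    k = min(n_components, gm.n_samples - 1, snp_set.size)
    k = max(k, 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    if k < n_components:  # pad so callers can always index component 2
        pad = np.zeros((scores.shape[0], n_components - k))
        scores = np.hstack([scores, pad])
    return PcaResult(
        scores=scores,
        explained_variance=pca.explained_variance_,
        loadings=pca.components_,
    )


@dataclass
class BlockGenotypes:
    """Per-sample block-genotype call: AA/BB the two arrangement homozygote
    classes, AB the heterozygote (middle) class, 'NA' when degenerate."""

    labels: list[str]
    pc1: np.ndarray
    centers: np.ndarray      # sorted ascending, length 3 (or empty)
    distances: np.ndarray    # samples x 3 |pc1 - center|


def assign_block_genotypes(
    gm: GenotypeMatrix,
    block,
    profile,
    threshold: float = 0.1,
    random_state: int = 0,
) -> BlockGenotypes:
    """Cluster samples into the three block genotypes from PC1 of the
    in-block SNPs (1-D 3-means; AB is the middle cluster)."""
    n_strong = sum(
        1
        for p, m in zip(profile.subset_pos, profile.mean_r2)
        if block.start <= p <= block.end and m > threshold
    )
    if n_strong < 3:
        raise ValueError(
            f"block has only {n_strong} strongly linked subset SNPs (< 3)"
        )
    rows = np.array(
        [
            i
            for i, s in enumerate(gm.snps)
            if s.chrom == block.chrom and block.start <= s.pos <= block.end
        ],
        dtype=np.int64,
    )
    pca = pca_genotypes(gm, snp_set=rows, n_components=1)
    pc1 = pca.scores[:, 0]
    span = float(np.ptp(pc1))
    n_samp = len(pc1)
    unassigned = BlockGenotypes(
        labels=["NA"] * n_samp,
        pc1=pc1,
        centers=np.empty(0),
        distances=np.empty((n_samp, 0)),
    )
    if span < 1e-9 or len(np.unique(np.round(pc1, 9))) < 3:
        return unassigned
    km = KMeans(n_clusters=3, n_init=10, random_state=random_state)
    cl = km.fit_predict(pc1[:, None])
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    centers_sorted = centers[order]
    if np.min(np.diff(centers_sorted)) < 1e-6 * span:
        return unassigned
    class_of = {order[0]: "AA", order[1]: "AB", order[2]: "BB"}
    labels = [class_of[c] for c in cl]
    distances = np.abs(pc1[:, None] - centers_sorted[None, :])
    return BlockGenotypes(
        labels=labels, pc1=pc1, centers=centers_sorted, distances=distances
    )
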