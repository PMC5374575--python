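"""LD-block detection: stride subsampling, pairwise dosage r², mean-r²
profiles, and threshold-plus-adjacent-SNP block calling.

r² here is the squared Pearson correlation of diploid dosage vectors across
samples (composite LD) — no phasing is assumed or performed. Sites that are
monomorphic within the sample have undefined correlation and are carried as
NaN, excluded from all means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import GenotypeMatrix

DEFAULT_STRIDE = 250
DEFAULT_THRESHOLD = 0.1


def subsample_snps(n_snps: int, stride: int) -> np.ndarray:
    """0-based indices of every ``stride``-th SNP in 1-based counting,
    i.e. {stride-1, 2*stride-1, ...}; length floor(n_snps / stride)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    return np.arange(stride - 1, n_snps, stride, dtype=np.int64)


def pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """Symmetric matrix of squared Pearson correlations between dosage rows.

    Rows with zero variance (monomorphic in the sample) get NaN against every
    other row. Diagonal is 1.
    """
    d = np.asarray(dosage, dtype=float)
    if d.ndim != 2:
        raise ValueError("dosage must be 2-D (sites x samples)")
    if d.shape[1] < 2:
        raise ValueError("need at least 2 samples for correlation")
    x = d - d.mean(axis=1, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ x.T) / np.outer(norms, norms)
    r2 = r * r
    degenerate = norms == 0
    r2[degenerate, :] = np.nan
    r2[:, degenerate] = np.nan
    np.fill_diagonal(r2, 1.0)
    # numerical guard: clip tiny float excursions outside [0, 1]
    return np.clip(r2, 0.0, 1.0, out=r2)


def mean_r2_profile(r2: np.ndarray) -> np.ndarray:
    """Per-SNP mean of off-diagonal r², NaN entries excluded; all-NaN rows
    stay NaN."""
    m = np.array(r2, dtype=float)
    np.fill_diagonal(m, np.nan)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(m), axis=1)
        sums = np.nansum(m, axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@dataclass
class LdProfile:
    """Subsampled-SNP LD profile of one chromosome."""

    chrom: str
    subset_idx: np.ndarray  # 0-based indices into the chromosome SNP list
    subset_pos: np.ndarray  # 1-based positions of those SNPs
    r2: np.ndarray          # |subset| x |subset| symmetric matrix
    mean_r2: np.ndarray     # per-subset-SNP mean off-diagonal r2
    all_pos: np.ndarray | None = field(default=None, repr=False)


@dataclass
class LdBlock:
    """A called LD block (1-based inclusive span) with subset-SNP bookkeeping."""

    chrom: str
    start: int
    end: int
    first_high: int          # subset index of first mean_r2 > threshold SNP
    last_high: int
    n_subset_in_block: int
    n_strongly_linked: int
    mean_r2_in_block: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("block start must be < end")
        if self.first_high > self.last_high:
            raise ValueError("first_high must be <= last_high")


def ld_profile(
    gm: GenotypeMatrix, chrom: str, stride: int = DEFAULT_STRIDE
) -> LdProfile:
    """Subsample the chromosome's SNPs at ``stride`` and build the pairwise
    r² matrix and per-SNP mean-r² profile."""
    rows = gm.site_indices(chrom)
    pos = gm.positions(chrom)
    sub = subsample_snps(len(rows), stride)
    if len(sub) == 0:
        return LdProfile(
            chrom=chrom,
            subset_idx=sub,
            subset_pos=np.empty(0, dtype=np.int64),
            r2=np.empty((0, 0)),
            mean_r2=np.empty(0),
            all_pos=pos,
        )
    r2 = pairwise_r2(gm.dosage[rows[sub]])
    return LdProfile(
        chrom=chrom,
        subset_idx=sub,
        subset_pos=pos[sub],
        r2=r2,
        mean_r2=mean_r2_profile(r2),
        all_pos=pos,
    )


def count_strongly_linked(
    profile: LdProfile, block: LdBlock, threshold: float = DEFAULT_THRESHOLD
) -> tuple[int, int]:
    """(n subset SNPs in span with mean r² > threshold, n subset SNPs in span)."""
    inside = (profile.subset_pos >= block.start) & (
        profile.subset_pos <= block.end
    )
    with np.errstate(invalid="ignore"):
        high = inside & (profile.mean_r2 > threshold)
    return int(high.sum()), int(inside.sum())


def _runs_of_high(high_idx: np.ndarray, max_gap: int | None) -> list[tuple[int, int]]:
    """Split ordered subset indices of high-LD SNPs into runs; a new run
    starts when more than ``max_gap`` sub-threshold subset SNPs intervene."""
    if max_gap is None:
        return [(int(high_idx[0]), int(high_idx[-1]))]
    runs: list[tuple[int, int]] = []
    start = prev = int(high_idx[0])
    for i in high_idx[1:]:
        i = int(i)
        if i - prev - 1 > max_gap:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    return runs


def call_blocks(
    profile: LdProfile,
    threshold: float = DEFAULT_THRESHOLD,
    edge_rule: str = "adjacent-subset",
    max_gap: int | None = None,
) -> list[LdBlock]:
    """Call LD blocks from a mean-r² profile.

    A block spans from the SNP adjacent to the first subset SNP with
    mean r² strictly above ``threshold`` to the SNP adjacent to the last one.
    ``edge_rule`` picks what "adjacent" means:

    - ``"adjacent-subset"`` (default): the neighbouring *subset* SNP (one
      stride away), on the grounds that untested linked loci sit in the
      untyped gap between subset neighbours;
    - ``"adjacent-snp"``: the literal neighbouring SNP in the full list
      (requires ``profile.all_pos``).

    Default single-span mode emits one block covering every high-LD subset
    SNP (interior sub-threshold stretches, like an internal linkage gap, stay
    inside). With ``max_gap`` set, runs separated by more than ``max_gap``
    consecutive sub-threshold subset SNPs become separate blocks.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if edge_rule not in ("adjacent-subset", "adjacent-snp"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    with np.errstate(invalid="ignore"):
        high = np.nan_to_num(profile.mean_r2, nan=-1.0) > threshold
    high_idx = np.flatnonzero(high)
    if high_idx.size == 0:
        return []

    m = len(profile.subset_pos)
    blocks: list[LdBlock] = []
    for f_h, l_h in _runs_of_high(high_idx, max_gap):
        if edge_rule == "adjacent-subset":
            start = int(profile.subset_pos[max(f_h - 1, 0)])
            end = int(profile.subset_pos[min(l_h + 1, m - 1)])
        else:
            if profile.all_pos is None:
                raise ValueError("edge_rule 'adjacent-snp' needs all_pos")
            n = len(profile.all_pos)
            start = int(profile.all_pos[max(int(profile.subset_idx[f_h]) - 1, 0)])
            end = int(profile.all_pos[min(int(profile.subset_idx[l_h]) + 1, n - 1)])
        blk = LdBlock(
            chrom=profile.chrom,
            start=start,
            end=end,
            first_high=int(f_h),
            last_high=int(l_h),
            n_subset_in_block=0,
            n_strongly_linked=0,
        )
        n_strong, n_in = count_strongly_linked(profile, blk, threshold)
        blk.n_strongly_linked = n_strong
        blk.n_subset_in_block = n_in
        inside = (profile.subset_pos >= blk.start) & (profile.subset_pos <= blk.end)
        with np.errstate(invalid="ignore"):
            blk.mean_r2_in_block = float(np.nanmean(profile.mean_r2[inside])) \
                if inside.any() else float("nan")
        blocks.append(blk)
    return blocks
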