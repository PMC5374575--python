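"""Stride subsampling, dosage r², mean-r² profiles, and block calling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ldblocks as lb
from ldblocks.ld_scan import LdProfile
from ldblocks.simulate import simulate_matrices, two_pop_config

from conftest import gm_from_truth, small_config


class TestSubsample:
    @pytest.mark.parametrize(
        "n,stride,expected",
        [(147_356, 250, 589), (204_124, 250, 816), (139_785, 250, 559)],
    )
    def test_reproduces_chromosome_subset_sizes(self, n, stride, expected):
        assert len(lb.subsample_snps(n, stride)) == expected

    def test_indices_are_every_kth_in_one_based_counting(self):
        assert lb.subsample_snps(1000, 250).tolist() == [249, 499, 749, 999]

    def test_identity_stride(self):
        assert lb.subsample_snps(5, 1).tolist() == [0, 1, 2, 3, 4]

    def test_stride_larger_than_n_gives_empty(self):
        assert len(lb.subsample_snps(10, 11)) == 0

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(0, 10_000), stride=st.integers(1, 1_000))
    def test_length_is_floor_n_over_stride(self, n, stride):
        assert len(lb.subsample_snps(n, stride)) == n // stride


class TestPairwiseR2:
    def test_identical_vectors_fully_linked(self):
        d = np.array([[0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2]])
        assert lb.pairwise_r2(d)[0, 1] == pytest.approx(1.0)

    def test_orthogonal_vectors_unlinked(self):
        # covariance terms cancel exactly by hand Pearson computation
        d = np.array([[0, 0, 1, 1, 2, 2], [0, 1, 0, 1, 0, 1]])
        assert lb.pairwise_r2(d)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_repulsion_is_still_r2_one(self):
        g1 = np.array([0, 1, 2, 0, 1, 2])
        assert lb.pairwise_r2(np.vstack([g1, 2 - g1]))[0, 1] == pytest.approx(1.0)

    def test_monomorphic_row_is_undefined(self):
        d = np.array([[1, 1, 1, 1], [0, 1, 2, 0]])
        r2 = lb.pairwise_r2(d)
        assert np.isnan(r2[0, 1]) and np.isnan(r2[1, 0])
        assert r2[1, 1] == 1.0

    def test_matrix_properties_and_allele_relabel_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 31)).astype(np.int16)
        r2 = lb.pairwise_r2(d)
        assert np.allclose(r2, r2.T, equal_nan=True)
        finite = r2[~np.isnan(r2)]
        assert ((finite >= 0) & (finite <= 1)).all()
        assert np.allclose(np.diag(r2), 1.0)
        flip = rng.random(20) < 0.5
        d2 = np.where(flip[:, None], 2 - d, d)
        assert np.allclose(lb.pairwise_r2(d2), r2, equal_nan=True)

    def test_single_sample_is_fatal(self):
        with pytest.raises(ValueError):
            lb.pairwise_r2(np.array([[0], [1]]))


def test_mean_r2_profile_arithmetic_and_nan_exclusion():
    r2 = np.array(
        [
            [1.0, 0.2, 0.4],
            [0.2, 1.0, np.nan],
            [0.4, np.nan, 1.0],
        ]
    )
    mean = lb.mean_r2_profile(r2)
    assert mean[0] == pytest.approx(0.3)   # (0.2 + 0.4) / 2
    assert mean[1] == pytest.approx(0.2)   # NaN partner excluded
    all_nan = np.full((2, 2), np.nan)
    np.fill_diagonal(all_nan, 1.0)
    assert np.isnan(lb.mean_r2_profile(all_nan)).all()


def _profile_from_means(mean_r2, positions=None, all_pos=None):
    m = len(mean_r2)
    positions = (
        np.asarray(positions) if positions is not None
        else (np.arange(m, dtype=np.int64) + 1) * 1000
    )
    return LdProfile(
        chrom="chrT",
        subset_idx=np.arange(m) * 10 + 9,
        subset_pos=positions,
        r2=np.eye(m),
        mean_r2=np.asarray(mean_r2, dtype=float),
        all_pos=all_pos,
    )


class TestCallBlocks:
    def test_no_high_ld_no_blocks(self):
        prof = _profile_from_means([0.02] * 30)
        assert lb.call_blocks(prof) == []

    def test_adjacent_subset_edges(self):
        means = np.full(30, 0.03)
        means[10:21] = 0.5  # high at subset indices 10..20
        prof = _profile_from_means(means)
        (blk,) = lb.call_blocks(prof, edge_rule="adjacent-subset")
        assert blk.start == prof.subset_pos[9]
        assert blk.end == prof.subset_pos[21]
        assert blk.first_high == 10 and blk.last_high == 20

    def test_adjacent_snp_edges_use_full_list_neighbor(self):
        means = np.full(5, 0.03)
        means[2] = 0.5
        all_pos = np.arange(1, 101, dtype=np.int64) * 7  # 100 SNPs
        prof = _profile_from_means(
            means, positions=all_pos[np.arange(5) * 10 + 9], all_pos=all_pos
        )
        (blk,) = lb.call_blocks(prof, edge_rule="adjacent-snp")
        # subset index 2 -> full-list index 29; neighbors 28 and 30
        assert blk.start == all_pos[28] and blk.end == all_pos[30]

    def test_single_span_keeps_internal_gap(self):
        means = np.full(40, 0.03)
        means[5:12] = 0.4
        means[20:30] = 0.4  # linkage gap between index 12 and 19
        prof = _profile_from_means(means)
        blocks = lb.call_blocks(prof)
        assert len(blocks) == 1
        assert blocks[0].start == prof.subset_pos[4]
        assert blocks[0].end == prof.subset_pos[30]

    def test_max_gap_splits_runs(self):
        means = np.full(40, 0.03)
        means[5:12] = 0.4
        means[20:30] = 0.4
        prof = _profile_from_means(means)
        blocks = lb.call_blocks(prof, max_gap=3)
        assert [(b.first_high, b.last_high) for b in blocks] == [(5, 11), (20, 29)]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        means = rng.uniform(0, 0.3, size=60)
        means[20:35] += 0.3
        prof = _profile_from_means(means)
        prev = None
        for thr in (0.05, 0.1, 0.2, 0.3):
            blocks = lb.call_blocks(prof, threshold=thr)
            if not blocks:
                break
            b = blocks[0]
            if prev is not None:
                assert b.start >= prev.start and b.end <= prev.end
            prev = b

    def test_all_high_counts_equal(self):
        prof = _profile_from_means([0.5] * 10)
        (blk,) = lb.call_blocks(prof)
        assert blk.n_strongly_linked == blk.n_subset_in_block == 10


def test_null_ld_level_matches_one_over_n_minus_one():
    """Independent loci at n=31 diploids: mean off-diagonal r2 ~ 1/30,
    the background level seen in empirical mean-LD profiles."""
    cfg = small_config(seed=31, n_snps_block=0, n_snps_background=14_000)
    ds = simulate_matrices(cfg)
    gm = gm_from_truth(ds)
    prof = lb.ld_profile(gm, cfg.chrom, stride=50)  # spacing >> copying length
    assert len(prof.subset_pos) >= 200
    off = prof.r2[~np.eye(len(prof.r2), dtype=bool)]
    emp = np.nanmean(off)
    assert emp == pytest.approx(1 / 30, rel=0.2)


def _edge_errors_within_one_stride(cfg, prof, blk):
    sp = prof.subset_pos
    i0 = int(np.searchsorted(sp, cfg.block[0]))
    i1 = int(np.searchsorted(sp, cfg.block[1], side="right")) - 1
    slack_l = sp[i0] - sp[max(i0 - 1, 0)]
    slack_r = sp[min(i1 + 1, len(sp) - 1)] - sp[i1]
    return (
        abs(cfg.block[0] - blk.start) <= slack_l
        and abs(blk.end - cfg.block[1]) <= slack_r
    )


def test_planted_block_recovery_and_linked_fraction():
    """Called edges fall within one stride of the planted inversion edges,
    and the strongly-linked fraction tracks the planted linked fraction."""
    strong, total = 0, 0
    for seed in (101, 102, 103):
        # mixed linked/unlinked block, wide enough for the interior mixture
        cfg = two_pop_config(
            seed=seed, linked_fraction=0.6,
            n_snps_background=45_000, block=(4_500_001, 5_500_000),
        )
        ds = simulate_matrices(cfg)
        gm = lb.apply_site_filters(gm_from_truth(ds))
        prof = lb.ld_profile(gm, cfg.chrom)
        blocks = lb.call_blocks(prof)
        assert len(blocks) == 1
        assert _edge_errors_within_one_stride(cfg, prof, blocks[0])
        strong += blocks[0].n_strongly_linked
        total += blocks[0].n_subset_in_block
    assert strong / total == pytest.approx(0.6, abs=0.1)
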