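"""Weir-Cockerham F_ST, KS distribution contrasts, PCA, block genotypes."""

from __future__ import annotations

import numpy as np
import pytest

import ldblocks as lb
from ldblocks.ld_scan import LdBlock, LdProfile
from ldblocks.popgen import theta_from_components, wc_components
from ldblocks.simulate import simulate_matrices, two_pop_config, wc_theta_scalar

from conftest import best_label_accuracy, gm_from_truth


def _theta_vec(dosages_by_pop):
    cols, pops, start = [], [], 0
    for d in dosages_by_pop:
        cols.extend(d)
        pops.append(np.arange(start, start + len(d)))
        start += len(d)
    a, b, c = wc_components(np.asarray(cols)[None, :], pops)
    return theta_from_components(a, b, c)[0]


class TestWcFst:
    def test_identical_population_tables_give_nonpositive_theta(self):
        d = [0, 0, 1, 1, 2, 1, 0, 2, 1, 1]
        t = _theta_vec([d, d])
        assert t <= 1e-12

    def test_fixed_alternative_alleles_give_theta_one(self):
        assert _theta_vec([[0] * 10, [2] * 10]) == pytest.approx(1.0)

    def test_negative_theta_is_legal_output(self):
        # near-identical small samples push the estimator below zero
        t = _theta_vec([[0, 1, 1, 0, 1], [1, 0, 1, 1, 0]])
        assert t < 0

    def test_monomorphic_site_is_undefined(self):
        assert np.isnan(_theta_vec([[0] * 5, [0] * 5]))

    def test_matches_scalar_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n_pops = int(rng.integers(2, 4))
            tables = [
                rng.integers(0, 3, size=int(rng.integers(2, 16))).tolist()
                for _ in range(n_pops)
            ]
            t_vec = _theta_vec(tables)
            t_ora = wc_theta_scalar(tables)
            if np.isnan(t_ora):
                assert np.isnan(t_vec)
            else:
                assert t_vec == pytest.approx(t_ora, abs=1e-10)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(3)
        t1 = rng.integers(0, 3, 12)
        t2 = rng.integers(0, 3, 9)
        assert _theta_vec([t1, t2]) == pytest.approx(
            _theta_vec([2 - t1, 2 - t2]), abs=1e-12
        )

    def test_mean_theta_is_ratio_of_sums(self):
        a = np.array([0.1, 0.3, 0.0])
        b = np.array([0.2, 0.0, 0.0])
        c = np.array([0.2, 0.0, 0.0])
        # ratio of sums 0.4/0.8, NOT the mean of per-site ratios (0.6);
        # third site has zero denominator -> excluded
        assert lb.mean_theta(a, b, c) == pytest.approx(0.5)

    def test_wc_fst_dataframe_and_missing_population(self, small_gm, small_popmap):
        gm = lb.apply_site_filters(small_gm)
        ft = lb.wc_fst(gm, small_popmap, pair=("spring", "winter"),
                       snp_set=np.arange(50))
        assert len(ft.table) == 50
        assert set(ft.table.columns) >= {"chrom", "pos", "a", "b", "c", "theta"}
        with pytest.raises(KeyError):
            lb.wc_fst(gm, small_popmap, pair=("spring", "atlantis"))


class TestKs:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 50)
        ks = lb.fst_distribution_test(x, x)
        assert ks.D == pytest.approx(0.0)
        assert ks.p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        ks = lb.fst_distribution_test([0.9] * 30, [0.0] * 30)
        assert ks.D == pytest.approx(1.0)

    def test_empty_after_nan_filter_is_fatal(self):
        with pytest.raises(ValueError):
            lb.fst_distribution_test([np.nan], [0.1, 0.2])

    def test_differentiated_block_vs_background(self, small_gm, small_ds,
                                                small_popmap):
        gm = lb.apply_site_filters(small_gm)
        bs, be = small_ds.config.block
        pos = gm.positions()
        inb = np.flatnonzero((pos >= bs) & (pos <= be))
        out = np.flatnonzero((pos < bs) | (pos > be))
        pair = ("winter", "georges_bank")  # planted freqs 0.85 vs 0.15
        t_in = lb.wc_fst(gm, small_popmap, pair, inb).table["theta"]
        t_out = lb.wc_fst(gm, small_popmap, pair, out).table["theta"]
        ks = lb.fst_distribution_test(t_in.to_numpy(), t_out.to_numpy())
        assert ks.p < 1e-10


class TestPca:
    def test_identical_samples_score_zero(self):
        d = np.tile([1], (30, 8)).astype(np.int16)
        gm = lb.GenotypeMatrix(
            snps=[lb.SnpRecord("c", i + 1, "A", "G", 60, i) for i in range(30)],
            samples=[f"s{j}" for j in range(8)],
            dosage=d,
        )
        res = lb.pca_genotypes(gm)
        assert np.allclose(res.scores, 0.0)

    def test_scores_centered_and_variance_sorted(self, small_gm):
        res = lb.pca_genotypes(lb.apply_site_filters(small_gm),
                               snp_set=np.arange(500), n_components=3)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)
        assert (np.diff(res.explained_variance) <= 1e-9).all()

    def test_inblock_pc1_separates_three_genotype_clusters(self, small_gm,
                                                           small_ds):
        gm = lb.apply_site_filters(small_gm)
        tr = small_ds.truth
        bs, be = small_ds.config.block
        pos = gm.positions()
        inb = np.flatnonzero((pos >= bs) & (pos <= be))
        res = lb.pca_genotypes(gm, snp_set=inb)
        pc1 = res.scores[:, 0]
        geno = tr.arrangement_genotype
        centers = sorted(pc1[geno == g].mean() for g in (0, 1, 2))
        spread = max(pc1[geno == g].std() for g in (0, 1, 2))
        gaps = np.diff(centers)
        assert (gaps > spread).all()  # between-cluster gap > within spread

    def test_outblock_has_no_comparable_pc1_clustering(self, small_gm,
                                                       small_ds):
        from sklearn.metrics import silhouette_score

        gm = lb.apply_site_filters(small_gm)
        tr = small_ds.truth
        bs, be = small_ds.config.block
        pos = gm.positions()
        geno = tr.arrangement_genotype
        sil = {}
        for name, mask in (
            ("in", (pos >= bs) & (pos <= be)),
            ("out", (pos < bs) | (pos > be)),
        ):
            res = lb.pca_genotypes(gm, snp_set=np.flatnonzero(mask))
            sil[name] = silhouette_score(res.scores[:, :1], geno)
        assert sil["in"] > sil["out"]

    def test_sample_reordering_changes_scores_only_up_to_sign(self, small_gm):
        gm = lb.apply_site_filters(small_gm)
        rows = np.arange(400)
        ref = lb.pca_genotypes(gm, snp_set=rows).scores
        perm = np.random.default_rng(1).permutation(gm.n_samples)
        gm_perm = lb.GenotypeMatrix(
            snps=gm.snps,
            samples=[gm.samples[j] for j in perm],
            dosage=gm.dosage[:, perm],
        )
        got = lb.pca_genotypes(gm_perm, snp_set=rows).scores
        for k in range(ref.shape[1]):
            same = np.allclose(got[:, k], ref[perm, k], atol=1e-6)
            flip = np.allclose(got[:, k], -ref[perm, k], atol=1e-6)
            assert same or flip


class TestBlockGenotypes:
    def test_perfect_assignment_on_planted_arrangements(self):
        for seed in (7, 8):
            cfg = two_pop_config(seed=seed)
            ds = simulate_matrices(cfg)
            gm = lb.apply_site_filters(gm_from_truth(ds))
            prof = lb.ld_profile(gm, cfg.chrom)
            (blk,) = lb.call_blocks(prof)
            res = lb.assign_block_genotypes(gm, blk, prof)
            acc = best_label_accuracy(res.labels, ds.truth.arrangement_genotype)
            assert acc == 1.0

    def test_degenerate_scores_flagged_unassigned(self):
        # all samples carry the same arrangement -> PC1 collapses to zero
        n = 10
        d = np.tile([2], (40, n)).astype(np.int16)
        gm = lb.GenotypeMatrix(
            snps=[lb.SnpRecord("c", 100 + i, "A", "G", 60, i) for i in range(40)],
            samples=[f"s{j}" for j in range(n)],
            dosage=d,
        )
        prof = LdProfile(
            chrom="c",
            subset_idx=np.arange(4),
            subset_pos=np.array([105, 115, 125, 135]),
            r2=np.eye(4),
            mean_r2=np.full(4, 0.9),
        )
        blk = LdBlock(chrom="c", start=100, end=140, first_high=0, last_high=3,
                      n_subset_in_block=4, n_strongly_linked=4)
        res = lb.assign_block_genotypes(gm, blk, prof)
        assert res.labels == ["NA"] * n

    def test_too_few_strong_snps_is_fatal(self, small_gm):
        prof = LdProfile(
            chrom="chr1", subset_idx=np.arange(2),
            subset_pos=np.array([10, 20]), r2=np.eye(2),
            mean_r2=np.array([0.5, 0.01]),
        )
        blk = LdBlock(chrom="chr1", start=5, end=25, first_high=0, last_high=0,
                      n_subset_in_block=2, n_strongly_linked=1)
        with pytest.raises(ValueError, match="strongly linked"):
            lb.assign_block_genotypes(small_gm, blk, prof)

    def test_midway_sample_assigned_heterozygote(self):
        # 3 homozygous-ref, 3 homozygous-alt, one exactly intermediate
        d = np.array([[0, 0, 0, 1, 2, 2, 2]] * 20, dtype=np.int16)
        gm = lb.GenotypeMatrix(
            snps=[lb.SnpRecord("c", 100 + i, "A", "G", 60, i) for i in range(20)],
            samples=[f"s{j}" for j in range(7)],
            dosage=d,
        )
        prof = LdProfile(
            chrom="c", subset_idx=np.arange(3),
            subset_pos=np.array([101, 108, 115]),
            r2=np.eye(3), mean_r2=np.full(3, 0.8),
        )
        blk = LdBlock(chrom="c", start=100, end=120, first_high=0, last_high=2,
                      n_subset_in_block=3, n_strongly_linked=3)
        res = lb.assign_block_genotypes(gm, blk, prof)
        assert res.labels[3] == "AB"
        assert {res.labels[0], res.labels[6]} == {"AA", "BB"}
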