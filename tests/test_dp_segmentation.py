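import numpy as np
import pytest

from scseg.depth_matrix import ValidationError, concat_chromosomes, slice_chromosome
from scseg.dp_segmentation import (
    backtrack,
    build_l_table,
    dp_fill,
    segment_chromosome,
    segment_genome,
    segments_to_frame,
)
from scseg.mbic_core import MBICParams, mbic_penalty, score_segmentation, segment_loglik, segment_stat
from scseg.reference import exhaustive_best

from conftest import make_matrix, make_pair, random_pair

KAPPA1 = MBICParams(kappa1=1.0)


class TestLTable:
    def test_diploid_matrix_gives_all_zero_table(self):
        raw, norm = make_pair(np.full((6, 3), 2))
        l = build_l_table(raw, norm, KAPPA1)
        iu = np.triu_indices(6)
        np.testing.assert_array_equal(l[iu], 0.0)

    def test_diagonal_matches_direct_single_bin_loglik(self):
        rng = np.random.default_rng(7)
        raw, norm = random_pair(rng, 6, 4)
        l = build_l_table(raw, norm, KAPPA1)
        for i in range(6):
            direct = segment_loglik(segment_stat(raw, norm, i, i), KAPPA1)
            assert l[i, i] == pytest.approx(direct, rel=1e-12)

    def test_every_entry_matches_naive_evaluation(self):
        rng = np.random.default_rng(8)
        raw, norm = random_pair(rng, 6, 3)
        l = build_l_table(raw, norm, KAPPA1)
        for i in range(6):
            for j in range(i, 6):
                naive = segment_loglik(segment_stat(raw, norm, i, j), KAPPA1)
                assert l[i, j] == pytest.approx(naive, rel=1e-10, abs=1e-10)

    def test_nonpositive_normalized_matrix_rejected(self):
        raw = make_matrix([[1], [2]])
        norm = make_matrix([[0.0], [1.0]], kind="normalized")
        with pytest.raises(ValidationError, match="strictly positive"):
            build_l_table(raw, norm, KAPPA1)


class TestDPFill:
    def test_flat_matrix_penalty_dominates(self):
        raw, norm = make_pair(np.full((10, 4), 2))
        tables = dp_fill(build_l_table(raw, norm, KAPPA1), KAPPA1, K=5)
        final = tables.beta[:, -1]
        assert all(a > b for a, b in zip(final, final[1:]))
        assert backtrack(tables).n_segments == 1

    def test_k_larger_than_m_rejected(self):
        raw, norm = make_pair(np.full((4, 2), 2))
        with pytest.raises(ValidationError):
            dp_fill(build_l_table(raw, norm, KAPPA1), KAPPA1, K=5)

    def test_two_block_matrix_back_pointer_at_block_boundary(self):
        # bins 0-3 diploid, bins 4-7 at CN 4 in half the cells
        cn = np.full((8, 4), 2)
        cn[4:, :2] = 4
        raw, norm = make_pair(cn)
        tables = dp_fill(build_l_table(raw, norm, KAPPA1), KAPPA1, K=4)
        assert tables.T[1, 7] == 3

    def test_beta_equals_loglik_plus_layer_penalty(self):
        rng = np.random.default_rng(9)
        raw, norm = random_pair(rng, 9, 3)
        tables = dp_fill(build_l_table(raw, norm, KAPPA1), KAPPA1, K=6)
        for k in range(1, 7):
            pen = mbic_penalty(9, k, KAPPA1)
            row = tables.L[k - 1]
            finite = np.isfinite(row)
            np.testing.assert_allclose(tables.beta[k - 1, finite], row[finite] + pen)

    def test_every_layer_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            m, n = int(rng.integers(4, 9)), int(rng.integers(1, 5))
            raw, norm = random_pair(rng, m, n)
            tables = dp_fill(build_l_table(raw, norm, KAPPA1), KAPPA1, K=m)
            by_k, _, best = exhaustive_best(raw, norm, KAPPA1)
            for k in range(1, m + 1):
                assert tables.beta[k - 1, m - 1] == pytest.approx(by_k[k], abs=1e-9)
            seg = backtrack(tables)
            assert seg.mbic == pytest.approx(best, abs=1e-9)
            achieved = score_segmentation(raw, norm, seg, KAPPA1)
            assert achieved == pytest.approx(best, abs=1e-9)


class TestBacktrack:
    def test_single_segment_has_no_turning_points(self):
        raw, norm = make_pair(np.full((5, 2), 2))
        seg = backtrack(dp_fill(build_l_table(raw, norm, KAPPA1), KAPPA1))
        assert seg.turning_points == [] and seg.n_segments == 1
        assert seg.mbic == 0.0 and seg.loglik == 0.0

    def test_default_synthetic_design_recovers_six_turning_points(
        self, default_truth, default_counts
    ):
        raw, norm = default_counts
        seg = segment_chromosome(raw, norm)
        assert seg.n_segments == 7
        assert seg.turning_points == default_truth.turning_points

    def test_reported_mbic_reproducible_by_direct_scoring(self, default_counts):
        raw, norm = default_counts
        seg = segment_chromosome(raw, norm)
        rescored = score_segmentation(raw, norm, seg)
        assert rescored == pytest.approx(seg.mbic, abs=1e-9)


class TestSegmentChromosome:
    def test_single_bin_chromosome_degenerates_gracefully(self):
        raw, norm = make_pair(np.full((1, 3), 4))
        seg = segment_chromosome(raw, norm, KAPPA1)
        assert seg.n_segments == 1 and seg.turning_points == []

    def test_planted_noise_free_steps_found_exactly(self):
        cn = np.full((10, 6), 2)
        cn[3:7, :3] = 4   # step at bins 2|3 and 6|7
        cn[7:, 3:] = 1
        raw, norm = make_pair(cn)
        seg = segment_chromosome(raw, norm, KAPPA1)
        assert seg.turning_points == [2, 6]

    def test_multi_chromosome_input_rejected(self):
        a, an = make_pair(np.full((3, 2), 2), chrom="chr1")
        b, bn = make_pair(np.full((3, 2), 2), chrom="chr2")
        with pytest.raises(ValidationError):
            segment_chromosome(concat_chromosomes([a, b]), concat_chromosomes([an, bn]))

    def test_output_invariant_to_cell_permutation(self, default_counts):
        raw, norm = default_counts
        rng = np.random.default_rng(11)
        perm = rng.permutation(raw.n)
        raw_p = make_matrix(raw.values[:, perm], chrom="chr22")
        norm_p = make_matrix(norm.values[:, perm], kind="normalized", chrom="chr22")
        a = segment_chromosome(raw, norm)
        b = segment_chromosome(raw_p, norm_p)
        assert a.turning_points == b.turning_points
        assert a.mbic == pytest.approx(b.mbic, rel=1e-12)

    def test_loglik_layers_non_decreasing_on_count_data(self, default_counts):
        raw, norm = default_counts
        params = MBICParams().resolved(raw.n)
        tables = dp_fill(build_l_table(raw, norm, params), params, K=12)
        m = raw.m
        final = tables.L[:, m - 1]
        assert all(b >= a - 1e-9 for a, b in zip(final, final[1:]))


class TestSegmentGenome:
    def test_identical_chromosomes_yield_identical_segmentations(self):
        cn = np.full((8, 4), 2)
        cn[4:, :2] = 4
        a, an = make_pair(cn, chrom="chr1")
        b, bn = make_pair(cn, chrom="chr2")
        segs = segment_genome(
            concat_chromosomes([a, b]), concat_chromosomes([an, bn]), KAPPA1
        )
        assert [s.chrom for s in segs] == ["chr1", "chr2"]
        assert segs[0].turning_points == segs[1].turning_points
        assert segs[0].mbic == pytest.approx(segs[1].mbic)

    def test_chromosome_block_order_does_not_change_results(self):
        cn1 = np.full((6, 3), 2)
        cn1[3:, 0] = 4
        cn2 = np.full((5, 3), 2)
        cn2[:2, 1:] = 1
        a, an = make_pair(cn1, chrom="chrA")
        b, bn = make_pair(cn2, chrom="chrB")
        fwd = segment_genome(concat_chromosomes([a, b]), concat_chromosomes([an, bn]), KAPPA1)
        rev = segment_genome(concat_chromosomes([b, a]), concat_chromosomes([bn, an]), KAPPA1)
        by_chrom_f = {s.chrom: s.turning_points for s in fwd}
        by_chrom_r = {s.chrom: s.turning_points for s in rev}
        assert by_chrom_f == by_chrom_r

    def test_segment_frame_has_bp_coordinates(self):
        cn = np.full((8, 4), 2)
        cn[4:, :2] = 4
        raw, norm = make_pair(cn)
        segs = segment_genome(raw, norm, KAPPA1)
        df = segments_to_frame(segs, raw)
        assert list(df["start_bin"]) == [0, 4]
        assert list(df["end_bin"]) == [3, 7]
        assert df["start_bp"].iloc[0] == 1


def test_runtime_scales_quadratically_in_bins():
    """Doubling m should cost at most ~4.5x (quadratic plus overhead)."""
    import time

    rng = np.random.default_rng(12)

    def run(m):
        raw, norm = random_pair(rng, m, 20)
        best = np.inf
        for _ in range(3):
            t0 = time.perf_counter()
            tables = dp_fill(build_l_table(raw, norm, KAPPA1), KAPPA1, K=10)
            best = min(best, time.perf_counter() - t0)
        return best

    t1, t2 = run(120), run(240)
    assert t2 / t1 < 4.5
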