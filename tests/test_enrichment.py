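import numpy as np
import pytest
from scipy import stats

from netla import build_block_map, build_edge_index
from netla.edge_models import EdgeWeightMap, pearson_edge_map
from netla.enrichment import (
    EnrichmentConfig,
    block_contingency,
    chi_square_block,
    fwer_pvalues,
    hypergeometric_block_p,
    mcc_reliability,
    observed_block_statistics,
    overlap_percentage,
    permutation_null,
    zscore_binarize,
    PermutationNull,
)
from netla.synthetic import generate_partition


class TestZscoreBinarize:
    def test_gaussian_strong_fraction_matches_tail_mass(self):
        # P(|Z| > 2) = 2 Phi(-2) = 0.0455
        rng = np.random.default_rng(1)
        wmap = EdgeWeightMap("pearson", rng.normal(size=100_000))
        frac = zscore_binarize(wmap, 2.0).mean()
        assert frac == pytest.approx(2 * stats.norm.cdf(-2), abs=0.003)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            zscore_binarize(EdgeWeightMap("pearson", np.full(10, 0.3)))

    def test_outlier_is_strong(self):
        values = np.zeros(100)
        values[:99] = np.random.default_rng(2).normal(size=99)
        values[99] = 10 * values[:99].std()
        mask = zscore_binarize(EdgeWeightMap("pearson", values), 2.0)
        assert mask[99]

    def test_selected_only_zscoring_for_feature_selection(self):
        rng = np.random.default_rng(3)
        values = np.zeros(1000)
        sel = np.zeros(1000, dtype=bool)
        sel[:100] = True
        values[:100] = rng.normal(size=100)
        wmap = EdgeWeightMap("pearson_fs_lsvr", values, selected_mask=sel)
        mask = zscore_binarize(wmap, 2.0)
        assert not mask[~sel].any()  # unselected edges never strong
        # Z-scoring over the selected pool only: ~4.6% of 100 edges strong
        assert 0 < mask[sel].sum() < 20


class TestBlockContingency:
    def test_empty_and_full_masks(self, small_block_map):
        e = small_block_map.edge_count
        k, m, big_k, big_m = block_contingency(np.zeros(e, dtype=bool), small_block_map)
        assert big_k == 0 and np.all(k == 0)
        k, m, big_k, big_m = block_contingency(np.ones(e, dtype=bool), small_block_map)
        assert big_k == big_m == e
        assert np.array_equal(k, m)

    def test_counts_match_bruteforce_tally(self):
        part = generate_partition(9, [3, 3, 3])
        idx = build_edge_index(9)
        bm = build_block_map(part, idx)
        rng = np.random.default_rng(4)
        mask = rng.random(idx.edge_count) < 0.3
        k, m, big_k, big_m = block_contingency(mask, bm)
        # brute force: walk every edge
        tally_k = np.zeros(bm.block_count, dtype=int)
        tally_m = np.zeros(bm.block_count, dtype=int)
        for e in range(idx.edge_count):
            i, j = idx.pair_of(e)
            a, b = sorted([part.labels[i], part.labels[j]])
            blk = bm.block_id(a, b)
            tally_m[blk] += 1
            tally_k[blk] += int(mask[e])
        assert np.array_equal(k, tally_k)
        assert np.array_equal(m, tally_m)
        assert k.sum() == big_k and m.sum() == big_m


class TestChiSquare:
    def test_proportional_counts_give_zero(self):
        chi2, p = chi_square_block(2, 4, 5, 10)
        assert chi2 == pytest.approx(0.0)
        assert p == 1.0

    def test_hand_computed_table(self):
        # 2x2 table [[4,0],[1,5]]: chi2 = 20/3
        chi2, _ = chi_square_block(4, 4, 5, 10)
        assert chi2 == pytest.approx(20 / 3)

    def test_enrichment_depletion_symmetry(self):
        # with margins m=4, K=5, M=10, the extreme tables k=4 and k=0 both
        # deviate by |O-E| = 2 in every cell and give the same statistic
        chi_hi, _ = chi_square_block(4, 4, 5, 10)
        chi_lo, _ = chi_square_block(0, 4, 5, 10)
        assert chi_hi == pytest.approx(chi_lo) == pytest.approx(20 / 3)

    def test_no_strong_edges_is_null(self):
        chi2, p = chi_square_block(0, 4, 0, 10)
        assert chi2 == 0 and p == 1.0

    def test_degenerate_block_rejected(self):
        with pytest.raises(ValueError):
            chi_square_block(0, 0, 5, 10)
        with pytest.raises(ValueError):
            chi_square_block(5, 10, 5, 10)

    def test_matches_scipy_contingency_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            big_m = int(rng.integers(10, 500))
            m = int(rng.integers(1, big_m))
            big_k = int(rng.integers(1, big_m))
            k = int(rng.integers(max(0, big_k - (big_m - m)), min(m, big_k) + 1))
            table = np.array(
                [[k, m - k], [big_k - k, (big_m - m) - (big_k - k)]]
            )
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            expected = stats.chi2_contingency(table, correction=False)
            chi2, p = chi_square_block(k, m, big_k, big_m)
            assert chi2 == pytest.approx(expected.statistic, rel=1e-10, abs=1e-12)
            assert p == pytest.approx(expected.pvalue, rel=1e-8, abs=1e-12)


class TestHypergeometric:
    def test_zero_overlap_gives_one(self):
        assert hypergeometric_block_p(0, 4, 5, 10) == pytest.approx(1.0)

    def test_exact_enumeration(self):
        # P(X >= 4) for X ~ Hypergeom(M=10, K=5, m=4) = C(5,4)C(5,0)/C(10,4)
        assert hypergeometric_block_p(4, 4, 5, 10) == pytest.approx(5 / 210)

    def test_monotone_in_k(self):
        ps = [hypergeometric_block_p(k, 4, 5, 10) for k in range(5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestPermutationNull:
    def test_single_permutation_single_row(self, null_dataset_pair, small_block_map):
        ds, _ = null_dataset_pair
        cfg = EnrichmentConfig(n_permutations=1, seed=6)
        null = permutation_null(ds, "pearson", cfg, small_block_map)
        assert null.null_chi2.shape == (1, small_block_map.block_count)

    def test_same_seed_identical(self, null_dataset_pair, small_block_map):
        ds, _ = null_dataset_pair
        cfg = EnrichmentConfig(n_permutations=5, seed=7)
        a = permutation_null(ds, "pearson", cfg, small_block_map)
        b = permutation_null(ds, "pearson", cfg, small_block_map)
        assert np.array_equal(a.null_chi2, b.null_chi2)

    def test_null_data_calibration_ks(self, null_dataset_pair, small_block_map):
        # on global-null data, observed single-fit chi2 values and permuted
        # chi2 values are exchangeable: two-sample KS should not reject for
        # the majority of blocks
        from netla.enrichment import _grouped_subsample

        ds, _ = null_dataset_pair
        n_draws = 200
        cfg = EnrichmentConfig(n_permutations=n_draws, seed=8)
        null = permutation_null(ds, "pearson", cfg, small_block_map)
        observed = np.empty((n_draws, small_block_map.block_count))
        for d in range(n_draws):
            rng = np.random.default_rng([9, d])
            idx = _grouped_subsample(ds.family_ids, 0.8, rng)
            wmap = pearson_edge_map(ds.edges[idx], ds.ages[idx])
            mask = zscore_binarize(wmap, 2.0)
            k, m, big_k, big_m = block_contingency(mask, small_block_map)
            observed[d], _ = chi_square_block(k, m, big_k, big_m)
        reject = 0
        for b in range(small_block_map.block_count):
            if stats.ks_2samp(observed[:, b], null.null_chi2[:, b]).pvalue <= 0.01:
                reject += 1
        assert reject < small_block_map.block_count / 2


class TestFwerPvalues:
    def test_observed_above_all_maxima(self):
        null = PermutationNull(np.ones((9, 3)))
        p = fwer_pvalues(np.array([5.0, 5.0, 5.0]), null)
        assert p == pytest.approx(np.full(3, 1 / 10))

    def test_zero_statistic_gives_one(self):
        null = PermutationNull(np.ones((9, 3)))
        p = fwer_pvalues(np.array([0.0, 5.0, 0.0]), null)
        assert p[0] == 1.0 and p[2] == 1.0

    def test_hand_enumerated_maxima(self):
        # permutation maxima: 3, 7, 2, 9
        null = PermutationNull(
            np.array([[1, 3, 2], [7, 1, 0], [2, 1, 1], [9, 0, 3]], dtype=float)
        )
        p = fwer_pvalues(np.array([4.0, 8.0, 2.5]), null)
        #   obs=4: maxima >= 4 are {7, 9} -> (1+2)/5
        #   obs=8: maxima >= 8 are {9} -> (1+1)/5
        #   obs=2.5: maxima >= 2.5 are {3, 7, 9} -> (1+3)/5
        assert p == pytest.approx([3 / 5, 2 / 5, 4 / 5])

    def test_attaches_to_block_statistics(self, null_dataset_pair, small_block_map):
        ds, _ = null_dataset_pair
        wmap = pearson_edge_map(ds.edges, ds.ages)
        obs = observed_block_statistics(wmap, small_block_map)
        cfg = EnrichmentConfig(n_permutations=10, seed=10)
        null = permutation_null(ds, "pearson", cfg, small_block_map)
        fwer_pvalues(obs, null)
        assert all(s.fwer_p is not None and 0 < s.fwer_p <= 1 for s in obs)


class TestMCC:
    def test_identical_masks(self):
        m = np.array([True, False, True, False])
        assert mcc_reliability(m, m).mcc == pytest.approx(1.0)

    def test_hand_computed_confusion(self):
        # TP=2 TN=3 FP=1 FN=1 -> MCC = (2*3 - 1*1)/sqrt(3*3*4*4) = 5/12,
        # which also equals the Pearson correlation of the two binary vectors
        day1 = np.array([1, 1, 1, 0, 0, 0, 0], dtype=bool)
        day2 = np.array([1, 1, 0, 1, 0, 0, 0], dtype=bool)
        res = mcc_reliability(day1, day2)
        assert (res.tp, res.tn, res.fp, res.fn) == (2, 3, 1, 1)
        assert res.mcc == pytest.approx(5 / 12)
        assert res.mcc == pytest.approx(
            np.corrcoef(day1.astype(float), day2.astype(float))[0, 1]
        )
        assert res.tp + res.tn + res.fp + res.fn == day1.size

    def test_complementary_masks(self):
        m = np.array([True, False, True])
        assert mcc_reliability(m, ~m).mcc == pytest.approx(-1.0)

    def test_zero_marginal_defined_as_zero(self):
        assert mcc_reliability(np.zeros(4, bool), np.array([1, 0, 0, 0], bool)).mcc == 0.0

    def test_equals_pearson_of_binary_vectors(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 25:
            a = rng.random(12) < 0.4
            b = rng.random(12) < 0.4
            if a.all() or (~a).all() or b.all() or (~b).all():
                continue
            r = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
            assert mcc_reliability(a, b).mcc == pytest.approx(r, rel=1e-10)
            checked += 1


class TestOverlap:
    def test_extremes_and_fractions(self):
        masks = np.array(
            [[1, 0, 1], [1, 0, 1], [1, 0, 0]], dtype=bool
        )
        frac = overlap_percentage(masks)
        assert frac == pytest.approx([1.0, 0.0, 2 / 3])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            overlap_percentage(np.zeros((0, 3)))
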