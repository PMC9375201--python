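"""Weighted statistics: unit-weight reductions and multiplicity-expansion
oracles — the central correctness properties of the module."""

import numpy as np
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_samples

import mcgrain as mg


def expand(values, w):
    """Repeat row/element i of ``values`` w[i] times (frequency expansion)."""
    return np.repeat(np.asarray(values), np.asarray(w, dtype=int), axis=0)


@pytest.fixture()
def mat(rng):
    return np.asarray(rng.normal(size=(12, 6)))


@pytest.fixture()
def int_w(rng):
    return rng.integers(1, 5, size=12).astype(float)


class TestWeightedScale:
    def test_unit_weights_equal_classical_zscore(self, mat):
        got = mg.weighted_scale(mat, np.ones(12))
        exp = (mat - mat.mean(axis=0)) / mat.std(axis=0, ddof=1)
        np.testing.assert_allclose(got, exp, atol=1e-10)

    def test_constant_gene_zeroed(self):
        m = np.column_stack([np.ones(5), np.arange(5.0)])
        got = mg.weighted_scale(m, np.ones(5))
        assert np.all(got[:, 0] == 0)

    def test_expansion_oracle(self, mat, int_w):
        got = mg.weighted_scale(mat, int_w)
        big = expand(mat, int_w)
        exp_big = (big - big.mean(axis=0)) / big.std(axis=0, ddof=1)
        np.testing.assert_allclose(expand(got, int_w), exp_big, atol=1e-10)

    def test_stated_example_weights_211(self):
        got = mg.weighted_scale(np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 1.0, 1.0]))
        big = np.array([1.0, 1.0, 2.0, 3.0])
        exp = (np.array([1.0, 2.0, 3.0]) - big.mean()) / big.std(ddof=1)
        np.testing.assert_allclose(got[:, 0], exp, atol=1e-12)

    def test_reliability_convention_available(self):
        x = np.array([[1.0], [2.0], [3.0]])
        w = np.array([2.0, 1.0, 1.0])
        got = mg.weighted_scale(x, w, convention="reliability")
        # normalized-weight unbiased variance: 11/16 / (1 - 3/8) = 1.1
        np.testing.assert_allclose(
            got[:, 0], (x[:, 0] - 1.75) / np.sqrt(1.1), atol=1e-12
        )


class TestWeightedPca:
    def test_equal_weights_match_standard_pca(self, mat):
        got = mg.weighted_pca(mat, 2 * np.ones(12), n_components=3)
        scaled = mg.weighted_scale(mat, 2 * np.ones(12))
        u, s, vt = np.linalg.svd(scaled, full_matrices=False)
        oracle = scaled @ vt[:3].T
        for j in range(3):
            err = min(np.abs(oracle[:, j] - got.coords[:, j]).max(),
                      np.abs(oracle[:, j] + got.coords[:, j]).max())
            assert err < 1e-8

    def test_rank_one_single_nonzero_eigenvalue(self, rng):
        base = rng.normal(size=6)
        m = np.outer(rng.normal(size=10), base)
        got = mg.weighted_pca(m, np.ones(10), n_components=3, scale=False)
        assert got.explained_variance[0] > 1e-6
        assert np.all(got.explained_variance[1:] < 1e-10)

    def test_expansion_oracle(self, mat, int_w):
        got = mg.weighted_pca(mat, int_w, n_components=4)
        scaled_big = expand(mg.weighted_scale(mat, int_w), int_w)
        u, s, vt = np.linalg.svd(scaled_big, full_matrices=False)
        oracle = (scaled_big @ vt[:4].T)[np.cumsum(int_w.astype(int)) - 1]
        for j in range(4):
            err = min(np.abs(oracle[:, j] - got.coords[:, j]).max(),
                      np.abs(oracle[:, j] + got.coords[:, j]).max())
            assert err < 1e-6

    def test_nonfinite_rejected(self, mat):
        mat = mat.copy()
        mat[0, 0] = np.nan
        with pytest.raises(ValueError):
            mg.weighted_pca(mat, np.ones(12), n_components=2)


class TestWeightedHclust:
    def test_unit_weights_match_scipy_ward(self, rng):
        pts = rng.normal(size=(15, 3))
        got = mg.weighted_hclust(pts, np.ones(15), n_clusters=4)
        ref = fcluster(linkage(pts, method="ward"), 4, criterion="maxclust")
        assert mg.adjusted_rand_index(got, ref) == 1.0

    def test_two_far_groups_recovered(self, rng):
        pts = np.vstack([rng.normal(size=(6, 2)), rng.normal(loc=50, size=(6, 2))])
        got = mg.weighted_hclust(pts, np.ones(12), n_clusters=2)
        assert len(set(got[:6])) == 1 and len(set(got[6:])) == 1 and got[0] != got[-1]

    def test_expansion_oracle(self, rng):
        pts = rng.normal(size=(10, 2))
        w = rng.integers(1, 4, size=10).astype(float)
        got = mg.weighted_hclust(pts, w, n_clusters=3)
        big = expand(pts, w)
        ref_big = fcluster(linkage(big, method="ward"), 3, criterion="maxclust")
        ref = ref_big[np.cumsum(w.astype(int)) - 1]
        assert mg.adjusted_rand_index(got, ref) == 1.0

    def test_n_clusters_out_of_range(self, rng):
        with pytest.raises(ValueError):
            mg.weighted_hclust(rng.normal(size=(4, 2)), np.ones(4), n_clusters=5)


class TestWeightedSilhouette:
    def test_unit_weights_equal_classical(self, rng):
        pts = rng.normal(size=(20, 3))
        labels = rng.integers(0, 3, size=20)
        labels[:3] = [0, 1, 2]
        got = mg.weighted_silhouette(pts, labels, np.ones(20))
        ref = silhouette_samples(pts, labels)
        np.testing.assert_allclose(got.s, ref, atol=1e-10)
        np.testing.assert_allclose(got.overall, ref.mean(), atol=1e-10)

    def test_hand_computed_three_metacells(self):
        # metacells at 0, 1, 5 on a line; weights 2, 1, 1; clusters {0,1} vs {5}
        coords = np.array([[0.0], [1.0], [5.0]])
        w = np.array([2.0, 1.0, 1.0])
        labels = np.array([0, 0, 1])
        got = mg.weighted_silhouette(coords, labels, w)
        # a(0) = d(0,1)*1 / (3-2) = 1 ; b(0) = d(0,2)*1/1 = 5 ; s = 4/5
        # a(1) = d(1,0)*2 / (3-1) = 1 ; b(1) = 4 ; s = 3/4
        # cluster of metacell 2 has a single metacell -> s = 0
        np.testing.assert_allclose(got.s, [0.8, 0.75, 0.0], atol=1e-12)
        np.testing.assert_allclose(got.overall, (0.8 * 2 + 0.75 * 1) / 4, atol=1e-12)

    def test_singleton_cluster_zero(self):
        coords = np.array([[0.0], [1.0], [9.0]])
        got = mg.weighted_silhouette(coords, np.array([0, 0, 1]), np.array([1.0, 1.0, 3.0]))
        assert got.s[2] == 0.0

    def test_overall_in_unit_interval(self, rng):
        pts = rng.normal(size=(25, 4))
        labels = rng.integers(0, 4, size=25)
        labels[:4] = np.arange(4)
        w = rng.integers(1, 6, size=25).astype(float)
        got = mg.weighted_silhouette(pts, labels, w)
        assert -1.0 <= got.overall <= 1.0
        assert np.all(got.s >= -1.0) and np.all(got.s <= 1.0)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="2 clusters"):
            mg.weighted_silhouette(rng.normal(size=(5, 2)), np.zeros(5), np.ones(5))


class TestWeightedTtest:
    def test_identical_groups(self):
        t, df, p, lfc = mg.weighted_ttest([1.0, 2.0], [1.0, 2.0],
                                          [1.0, 1.0], [1.0, 1.0])
        assert t == 0.0 and p == 1.0 and lfc == 0.0

    def test_unit_weights_equal_welch(self, rng):
        x1, x2 = rng.normal(size=8), rng.normal(loc=1, size=10)
        t, df, p, _ = mg.weighted_ttest(x1, x2, np.ones(8), np.ones(10))
        ref = stats.ttest_ind(x1, x2, equal_var=False)
        np.testing.assert_allclose([t, p], [ref.statistic, ref.pvalue], atol=1e-12)

    def test_expansion_oracle(self, rng):
        x1, x2 = rng.normal(size=5), rng.normal(loc=0.5, size=6)
        w1 = rng.integers(1, 5, size=5).astype(float)
        w2 = rng.integers(1, 5, size=6).astype(float)
        t, df, p, lfc = mg.weighted_ttest(x1, x2, w1, w2)
        ref = stats.ttest_ind(expand(x1, w1), expand(x2, w2), equal_var=False)
        np.testing.assert_allclose([t, p], [ref.statistic, ref.pvalue], atol=1e-10)

    def test_zero_variance_flat_groups(self):
        t, df, p, lfc = mg.weighted_ttest([2.0, 2.0], [2.0, 2.0],
                                          [3.0, 1.0], [1.0, 2.0])
        assert t == 0.0 and p == 1.0


class TestWeightedDe:
    def test_exclusive_gene_top_ranked(self):
        x = np.zeros((6, 4))
        x[:3, 0] = 5.0  # gene 0 expressed only in group A metacells
        x[:, 1:] = 1.0 + np.arange(6)[:, None] * 0.01
        labels = np.array(["A"] * 3 + ["B"] * 3)
        table = mg.weighted_de(x, np.ones(6), labels, [f"g{i}" for i in range(4)])
        top_a = table[(table.group == "A")].sort_values("rank").iloc[0]
        assert top_a.gene == "g0"

    def test_unit_weights_match_unweighted_welch(self, rng):
        x = rng.normal(size=(10, 5))
        labels = np.array(["A"] * 4 + ["B"] * 6)
        table = mg.weighted_de(x, np.ones(10), labels)
        for g in range(5):
            ref = stats.ttest_ind(x[:4, g], x[4:, g], equal_var=False)
            row = table[(table.group == "A") & (table.gene == f"gene{g:05d}")].iloc[0]
            np.testing.assert_allclose([row.t, row.p], [ref.statistic, ref.pvalue],
                                       atol=1e-10)

    def test_null_false_positive_rate(self):
        """Permuted labels on null data (no spiked effects): the weighted
        test is calibrated and BH keeps discoveries rare."""
        ds = mg.simulate_counts(n_cells=300, n_genes=150, n_types=2, effect_lfc=0.0,
                                dropout_rate=0.2, seed=4)
        expr = mg.normalize_log(ds.counts, ds.gene_ids, ds.cell_ids)
        rng = np.random.default_rng(4)
        labels = rng.permutation(ds.labels)
        table = mg.weighted_de(expr.dense().T, np.ones(300), labels, expr.gene_ids)
        frac = np.mean(table[table.group == "type0"].p_adj < 0.05)
        assert frac < 0.10

    def test_bh_monotone_in_p(self, rng):
        x = rng.normal(size=(12, 20))
        labels = np.array(["A"] * 6 + ["B"] * 6)
        table = mg.weighted_de(x, np.ones(12), labels)
        sub = table[table.group == "A"].sort_values("p")
        assert np.all(np.diff(sub.p_adj) >= -1e-12)
        assert np.all(sub.p_adj >= sub.p - 1e-12)


class TestWeightedPearson:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=10)
        rho, p = mg.weighted_pearson(x, x, np.ones(10))
        assert rho == pytest.approx(1.0) and p == pytest.approx(0.0)

    def test_unit_weights_classical(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        rho, p = mg.weighted_pearson(x, y, np.ones(15))
        ref = stats.pearsonr(x, y)
        np.testing.assert_allclose([rho, p], [ref.statistic, ref.pvalue], atol=1e-10)

    def test_expansion_oracle(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        w = rng.integers(1, 5, size=8).astype(float)
        rho, p = mg.weighted_pearson(x, y, w)
        ref = stats.pearsonr(expand(x, w), expand(y, w))
        np.testing.assert_allclose([rho, p], [ref.statistic, ref.pvalue], atol=1e-10)


class TestSignatureScore:
    def test_single_gene_max_normalized(self):
        vals = np.array([[1.0, 2.0, 4.0]])
        got = mg.signature_score(vals, ["g0"], ["g0"])
        np.testing.assert_allclose(got, [0.25, 0.5, 1.0])

    def test_five_gene_hand_formula(self, rng):
        vals = np.abs(rng.normal(size=(8, 6)))
        ids = [f"g{i}" for i in range(8)]
        sig = ["g1", "g3", "g4", "g6", "g7"]
        got = mg.signature_score(vals, ids, sig)
        exp = sum(vals[int(s[1:])] / vals[int(s[1:])].max() for s in sig)
        np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_missing_genes_warn_and_skip(self, rng):
        vals = np.abs(rng.normal(size=(3, 4)))
        with pytest.warns(UserWarning, match="absent"):
            got = mg.signature_score(vals, ["a", "b", "c"], ["a", "zz"])
        np.testing.assert_allclose(got, vals[0] / vals[0].max())

    def test_empty_intersection_rejected(self, rng):
        with pytest.raises(ValueError):
            mg.signature_score(np.ones((2, 2)), ["a", "b"], ["x"])


class TestScoreAuc:
    def test_perfect_separation(self):
        assert mg.score_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_reversal_symmetry(self, rng):
        scores = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        a = mg.score_auc(scores, y)
        b = mg.score_auc(-scores, y)
        assert a == pytest.approx(1.0 - b)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=4000)
        y = rng.integers(0, 2, size=4000)
        assert abs(mg.score_auc(scores, y) - 0.5) < 0.05

    def test_weighted_counts_as_multiplicity(self, rng):
        scores = rng.normal(size=10)
        y = rng.integers(0, 2, size=10)
        y[:2] = [0, 1]
        w = rng.integers(1, 4, size=10).astype(float)
        a = mg.score_auc(scores, y, w)
        b = mg.score_auc(expand(scores, w), expand(y, w))
        assert a == pytest.approx(b)


class TestClusterMetacells:
    def test_recovers_blob_types(self, blob_data, blob_partition):
        expr, labels = blob_data
        part, _, _ = blob_partition
        prof = mg.average_expression(expr, part)
        cl = mg.cluster_metacells(prof.dense(), part.sizes.astype(float), 5,
                                  n_hvg=30)
        ari = mg.adjusted_rand_index(np.asarray(cl)[part.membership], labels)
        assert ari >= 0.9

    def test_weighted_hvg_ranks_informative_genes(self, blob_data, blob_partition):
        expr, _ = blob_data
        part, _, _ = blob_partition
        prof = mg.average_expression(expr, part)
        idx = mg.select_variable_genes_weighted(prof.dense(),
                                                part.sizes.astype(float), 20)
        assert set(idx) == set(range(20))  # informative genes occupy indices 0-19
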