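"""Community statistics against independent oracles and invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import ttest_ind

from redsnow import (
    CountTable,
    bray_curtis,
    normalize_log,
    pca,
    per_feature_anova,
    permanova,
    select_top_variable,
    simprof_cluster,
)
from redsnow.community import DistanceMatrix, n_distinct_arrangements
from redsnow.errors import DataError, ParameterError


def _matrix(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=samples)


class TestNormalizeLog:
    def test_equal_depths_scaling_is_identity(self):
        counts = _matrix([[2, 2], [8, 8]])
        table = CountTable(
            counts=counts, groups=pd.Series(["a", "b"], index=counts.columns)
        )
        out = normalize_log(table)
        assert out.iloc[0, 0] == pytest.approx(math.log(3))

    def test_single_sample_closed_form(self):
        counts = _matrix([[2], [0]])
        table = CountTable(counts=counts, groups=pd.Series(["a"], index=["s0"]))
        out = normalize_log(table)
        assert out.iloc[0, 0] == pytest.approx(math.log(3))
        assert out.iloc[1, 0] == 0.0

    def test_depth_rescaling_hand_computation(self):
        # totals 100 and 200; a count of 50 in the deeper sample scales
        # to 25, giving ln 26 (frozen independent arithmetic)
        counts = _matrix([[100, 150], [0, 50]])
        table = CountTable(
            counts=counts, groups=pd.Series(["a", "b"], index=counts.columns)
        )
        out = normalize_log(table)
        assert out.iloc[1, 1] == pytest.approx(3.258096538021482, abs=1e-12)

    def test_zero_total_sample_named_in_error(self):
        counts = _matrix([[5, 0], [1, 0]])
        table = CountTable(
            counts=counts, groups=pd.Series(["a", "b"], index=counts.columns)
        )
        with pytest.raises(DataError, match="s1"):
            normalize_log(table)

    def test_rarefaction_option_hits_min_depth(self):
        counts = _matrix([[100, 150], [0, 50]])
        table = CountTable(
            counts=counts, groups=pd.Series(["a", "b"], index=counts.columns)
        )
        out = normalize_log(table, method="rarefy", seed=0)
        depths = np.expm1(out).sum(axis=0)
        assert depths.iloc[1] == pytest.approx(100.0, abs=1e-6)


class TestSelectTopVariable:
    def test_keeping_all_features_is_identity(self):
        m = _matrix(np.random.default_rng(0).normal(size=(6, 4)))
        assert set(select_top_variable(m, 6).index) == set(m.index)

    def test_constant_feature_dropped_first(self):
        m = _matrix([[1, 1, 1], [0, 5, 9], [2, 4, 8]])
        out = select_top_variable(m, 2)
        assert "f0" not in out.index

    def test_matches_brute_force_variance_sort(self):
        rng = np.random.default_rng(42)
        m = _matrix(rng.normal(size=(20, 8)))
        out = select_top_variable(m, 7)
        oracle = sorted(
            m.index, key=lambda f: (-np.var(m.loc[f], ddof=1), f)
        )[:7]
        assert list(out.index) == oracle

    def test_invalid_k_rejected(self):
        m = _matrix([[1, 2]])
        with pytest.raises(ParameterError):
            select_top_variable(m, 0)
        with pytest.raises(ParameterError):
            select_top_variable(m, 2)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(_matrix([[3, 3], [1, 1]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(_matrix([[3, 0], [0, 7]]))
        assert d.values[0, 1] == 1.0

    def test_hand_case(self):
        d = bray_curtis(_matrix([[1, 0], [1, 1], [0, 1]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_negative_entries_rejected(self):
        with pytest.raises(DataError):
            bray_curtis(_matrix([[-1, 0]]))

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.uniform(0, 10, size=(15, 6)))
        d = bray_curtis(m)
        for i, j in itertools.combinations(range(6), 2):
            expected = scipy_braycurtis(m.iloc[:, i], m.iloc[:, j])
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_metric_properties_and_feature_permutation_invariance(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.uniform(0, 5, size=(12, 5)))
        d = bray_curtis(m)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert d.values.min() >= 0 and d.values.max() <= 1
        shuffled = m.sample(frac=1, random_state=1)
        assert np.allclose(bray_curtis(shuffled).values, d.values)

    def test_all_zero_samples_distance_zero(self):
        d = bray_curtis(_matrix([[0, 0], [0, 0]]))
        assert d.values[0, 1] == 0.0


def _brute_force_permanova_p(dist_values, groups):
    """Independent enumeration oracle: recompute pseudo-F for every
    distinct labeling directly from sums of squared distances."""
    n = len(groups)
    labels = list(groups)
    uniq = sorted(set(labels))
    a = len(uniq)
    d2 = np.asarray(dist_values) ** 2

    def pseudo_f(lab):
        ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in uniq:
            idx = [i for i, l in enumerate(lab) if l == g]
            ss_within += sum(
                d2[i, j] for i in idx for j in idx if i < j
            ) / len(idx)
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return math.inf if ss_between > 0 else 0.0
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if pseudo_f(perm) >= f_obs - 1e-12:
            hits += 1
    return f_obs, hits / total


class TestPermanova:
    def test_separated_clusters_exhaustive_p_matches_brute_force(self):
        # two perfect clusters of 3: within-distance 0, between 1
        values = np.ones((6, 6))
        values[:3, :3] = 0.0
        values[3:, 3:] = 0.0
        np.fill_diagonal(values, 0.0)
        dist = DistanceMatrix(values, [f"s{i}" for i in range(6)])
        groups = ["a"] * 3 + ["b"] * 3
        res = permanova(dist, groups, n_permutations=999, seed=0)
        f_oracle, p_oracle = _brute_force_permanova_p(values, groups)
        assert res.method == "exhaustive"
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(p_oracle, abs=1e-15)
        assert math.isinf(res.statistic) and math.isinf(f_oracle)

    def test_exhaustive_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.uniform(0, 1, size=(6, 4))
            values = np.zeros((6, 6))
            for i, j in itertools.combinations(range(6), 2):
                values[i, j] = values[j, i] = np.abs(x[i] - x[j]).sum() / (
                    x[i] + x[j]
                ).sum()
            dist = DistanceMatrix(values, [f"s{i}" for i in range(6)])
            groups = ["a"] * 3 + ["b"] * 3
            res = permanova(dist, groups, n_permutations=999, seed=1)
            f_oracle, p_oracle = _brute_force_permanova_p(values, groups)
            assert res.statistic == pytest.approx(f_oracle, rel=1e-12)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-15)

    def test_statistic_matches_skbio(self):
        """Cross-check the pseudo-F against an independent implementation."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, size=(9, 5))
        values = np.zeros((9, 9))
        for i, j in itertools.combinations(range(9), 2):
            values[i, j] = values[j, i] = np.abs(x[i] - x[j]).sum() / (
                x[i] + x[j]
            ).sum()
        ids = [f"s{i}" for i in range(9)]
        groups = ["a"] * 4 + ["b"] * 5
        res = permanova(DistanceMatrix(values, ids), groups, seed=0)
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(values, ids), grouping=groups, permutations=0
        )
        assert res.statistic == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=(8, 6))
        values = np.zeros((8, 8))
        for i, j in itertools.combinations(range(8), 2):
            values[i, j] = values[j, i] = np.abs(x[i] - x[j]).mean()
        ids = [f"s{i}" for i in range(8)]
        groups = np.array(["a", "b"] * 4)
        res1 = permanova(DistanceMatrix(values, ids), groups, seed=0)
        order = rng.permutation(8)
        res2 = permanova(
            DistanceMatrix(values[np.ix_(order, order)], [ids[i] for i in order]),
            groups[order],
            seed=0,
        )
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-12)

    def test_monte_carlo_path_close_to_exhaustive(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, size=(6, 4))
        values = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            values[i, j] = values[j, i] = np.abs(x[i] - x[j]).mean()
        dist = DistanceMatrix(values, [f"s{i}" for i in range(6)])
        groups = ["a"] * 3 + ["b"] * 3
        exact = permanova(dist, groups, n_permutations=999, seed=0)
        mc = permanova(dist, groups, n_permutations=19, seed=0)
        assert exact.method == "exhaustive" and mc.method == "monte-carlo"
        assert abs(mc.p_value - exact.p_value) < 0.35

    def test_singleton_group_rejected(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 1.0
        dist = DistanceMatrix(values, ["a", "b", "c"])
        with pytest.raises(DataError):
            permanova(dist, ["g1", "g2", "g2"])

    def test_all_zero_distances_degenerate(self):
        dist = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        with pytest.warns(UserWarning):
            res = permanova(dist, ["g1", "g1", "g2", "g2"])
        assert res.p_value == 1.0

    def test_arrangement_counting(self):
        assert n_distinct_arrangements(np.array([0, 0, 0, 1, 1, 1])) == 20
        assert n_distinct_arrangements(np.array([0, 0, 1, 1, 2, 2])) == 90


class TestSimprof:
    def test_identical_samples_single_cluster(self):
        m = _matrix(np.tile([[1.0], [2.0], [3.0]], (1, 6)))
        res = simprof_cluster(m, seed=0, n_perm_expected=100, n_perm_test=99)
        assert res.n_clusters == 1

    def test_two_separated_groups_recovered(self):
        # two blocks of 4 samples with disjoint feature support and no
        # within-group variation: exactly the two true clusters
        block = np.zeros((10, 8))
        block[:5, :4] = 7.0
        block[5:, 4:] = 7.0
        rng = np.random.default_rng(1)
        block += rng.uniform(0, 0.05, block.shape)  # break exact ties
        m = _matrix(block)
        res = simprof_cluster(m, seed=3, n_perm_expected=200, n_perm_test=199)
        labels = res.labels
        assert res.n_clusters == 2
        assert len(set(labels.iloc[:4])) == 1
        assert len(set(labels.iloc[4:])) == 1
        assert labels.iloc[0] != labels.iloc[7]

    def test_labels_form_partition(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.uniform(0, 5, size=(12, 7)))
        res = simprof_cluster(m, seed=0, n_perm_expected=100, n_perm_test=99)
        assert set(res.labels.index) == set(m.columns)
        assert res.labels.notna().all()

    def test_two_samples_untestable_single_cluster(self):
        m = _matrix([[1, 5], [2, 1]])
        with pytest.warns(UserWarning):
            res = simprof_cluster(m, seed=0)
        assert res.n_clusters == 1
        assert res.newick.endswith(";")

    def test_newick_parses_with_all_leaves(self):
        import io

        from Bio import Phylo

        rng = np.random.default_rng(9)
        m = _matrix(rng.uniform(0, 5, size=(8, 5)))
        res = simprof_cluster(m, seed=0, n_perm_expected=50, n_perm_test=49)
        tree = Phylo.read(io.StringIO(res.newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(m.columns)


class TestPca:
    def test_rank_one_matrix_pc1_explains_everything(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = _matrix(np.outer(base, [1.0, 2.0, 4.0]))
        res = pca(m)
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-9)

    def test_percents_sum_to_100(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.normal(size=(10, 6)))
        res = pca(m)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)

    def test_variances_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(13)
        m = _matrix(rng.normal(size=(10, 6)))  # 6 samples x 10 features
        res = pca(m)
        x = m.to_numpy().T
        cov = np.cov(x - x.mean(axis=0), rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = 100.0 * eigvals / eigvals.sum()
        assert np.allclose(res.percent_variance, expected[: len(res.percent_variance)],
                           atol=1e-9)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(14)
        m = _matrix(rng.normal(size=(5, 8)))
        res = pca(m)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        recon += res.column_means.to_numpy()
        assert np.allclose(recon, m.to_numpy().T, atol=1e-9)

    def test_excessive_components_rejected(self):
        m = _matrix(np.ones((3, 2)))
        with pytest.raises(ParameterError):
            pca(m, n_components=4)


class TestPerFeatureAnova:
    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(21)
        m = _matrix(rng.normal(size=(100, 10)))
        groups = ["a"] * 5 + ["b"] * 5
        res = per_feature_anova(m, groups)
        for feat in m.index:
            t, _ = ttest_ind(m.loc[feat][:5], m.loc[feat][5:], equal_var=True)
            assert res.loc[feat, "F"] == pytest.approx(t**2, rel=1e-9)

    def test_equal_group_means_give_zero_f(self):
        m = _matrix([[1.0, 2.0, 1.0, 2.0]])
        res = per_feature_anova(m, ["a", "a", "b", "b"])
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_feature_f_zero_p_one(self):
        m = _matrix([[3.0, 3.0, 3.0, 3.0]])
        res = per_feature_anova(m, ["a", "a", "b", "b"])
        assert res["F"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_perfect_separation_flagged(self):
        m = _matrix([[1.0, 1.0, 2.0, 2.0]])
        res = per_feature_anova(m, ["a", "a", "b", "b"])
        assert math.isinf(res["F"].iloc[0])
        assert res["degenerate"].iloc[0]
        assert res["p"].iloc[0] > 0

    def test_bh_adjustment_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(22)
        m = _matrix(rng.normal(size=(40, 8)))
        res = per_feature_anova(m, ["a"] * 4 + ["b"] * 4)
        _, q, _, _ = multipletests(res["p"], method="fdr_bh")
        assert np.allclose(res["q"], q)

    def test_singleton_group_rejected(self):
        m = _matrix(np.ones((3, 3)))
        with pytest.raises(DataError):
            per_feature_anova(m, ["a", "b", "b"])
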