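import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd
from skbio import TreeNode

from vertiseq.diversity import (DistanceMatrix, alpha_diversity,
                                alpha_variance_decomposition, beta_distance,
                                coordinate_factor_r2, distance_matrix, pcoa, permanova)
from conftest import make_table, random_bifurcating_tree


def unifrac_oracle(tree: TreeNode, present_a: set, present_b: set) -> float:
    """Branch-by-branch enumeration of unweighted UniFrac."""
    unique = shared = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips()} or {node.name}
        in_a = bool(below & present_a)
        in_b = bool(below & present_b)
        if in_a and in_b:
            shared += node.length
        elif in_a or in_b:
            unique += node.length
    return unique / (unique + shared)


class TestAlpha:
    def test_shannon_uniform_is_log_k(self):
        assert alpha_diversity([10, 10, 10, 10], "shannon") == pytest.approx(np.log(4))

    def test_single_taxon(self):
        assert alpha_diversity([5, 0, 0], "shannon") == 0.0
        assert alpha_diversity([5, 0, 0], "richness") == 1

    def test_faith_pd_path_sums(self):
        tree = TreeNode.read(["(A:1,B:1):0;"])
        assert alpha_diversity([1, 0], "faith_pd", tree=tree, otu_ids=["A", "B"]) == 1.0
        assert alpha_diversity([1, 1], "faith_pd", tree=tree, otu_ids=["A", "B"]) == 2.0

    def test_faith_pd_missing_otu_named(self, toy_tree):
        with pytest.raises(ValueError, match="X"):
            alpha_diversity([1, 1], "faith_pd", tree=toy_tree, otu_ids=["A", "X"])

    def test_faith_pd_monotone_in_observed_taxa(self, toy_tree):
        pd1 = alpha_diversity([1, 0, 0], "faith_pd", tree=toy_tree, otu_ids=["A", "B", "C"])
        pd2 = alpha_diversity([1, 1, 0], "faith_pd", tree=toy_tree, otu_ids=["A", "B", "C"])
        pd3 = alpha_diversity([1, 1, 1], "faith_pd", tree=toy_tree, otu_ids=["A", "B", "C"])
        assert pd1 <= pd2 <= pd3

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.integers(0, 20, size=12)
            if v.sum() == 0:
                continue
            sh = alpha_diversity(v, "shannon")
            rich = alpha_diversity(v, "richness")
            assert sh <= np.log(rich) + 1e-12


class TestBeta:
    @pytest.mark.parametrize("metric", ["jaccard", "bray_curtis", "jsd"])
    def test_identical_vectors_distance_zero(self, metric):
        assert beta_distance([3, 1, 0], [3, 1, 0], metric) == pytest.approx(0.0)

    def test_disjoint_samples_unifrac_one(self):
        tree = TreeNode.read(["(A:1,B:1):0;"])
        d = beta_distance([1, 0], [0, 1], "unweighted_unifrac",
                          tree=tree, otu_ids=["A", "B"])
        assert d == pytest.approx(1.0)

    def test_unifrac_branch_enumeration_example(self):
        tree = TreeNode.read(["((A:1,B:1):1,C:2):0;"])
        d = beta_distance([1, 0, 0], [1, 0, 1], "unweighted_unifrac",
                          tree=tree, otu_ids=["A", "B", "C"])
        assert d == pytest.approx(unifrac_oracle(tree, {"A"}, {"A", "C"}))

    def test_unifrac_matches_enumeration_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            tree = random_bifurcating_tree(8, rng)
            leaves = [t.name for t in tree.tips()]
            a = rng.integers(0, 2, size=8)
            b = rng.integers(0, 2, size=8)
            if a.sum() == 0 or b.sum() == 0:
                continue
            d = beta_distance(a, b, "unweighted_unifrac", tree=tree, otu_ids=leaves)
            pa = {l for l, x in zip(leaves, a) if x}
            pb = {l for l, x in zip(leaves, b) if x}
            assert d == pytest.approx(unifrac_oracle(tree, pa, pb), abs=1e-12)

    def test_metrics_bounded_and_symmetric(self):
        rng = np.random.default_rng(1)
        for metric in ("jaccard", "bray_curtis"):
            for _ in range(10):
                a = rng.integers(0, 10, 6)
                b = rng.integers(0, 10, 6)
                if a.sum() == 0 or b.sum() == 0:
                    continue
                d1 = beta_distance(a, b, metric)
                d2 = beta_distance(b, a, metric)
                assert d1 == pytest.approx(d2)
                assert 0 <= d1 <= 1

    def test_jsd_natural_log_convention(self):
        # disjoint distributions: JSD = ln 2 under natural log
        d = beta_distance([1, 0], [0, 1], "jsd")
        assert d == pytest.approx(np.log(2))

    def test_unifrac_without_tree_errors(self):
        with pytest.raises(ValueError, match="tree"):
            beta_distance([1, 0], [0, 1], "unweighted_unifrac")


class TestDistanceMatrix:
    def _table(self, counts, n):
        return make_table(counts, [f"O{i}" for i in range(len(counts))],
                          [f"s{i}" for i in range(n)],
                          ["vaginal"] * n, ["w24"] * n)

    def test_identical_samples_give_zero_matrix(self):
        t = self._table([[3, 3, 3], [1, 1, 1]], 3)
        dm = distance_matrix(t, "bray_curtis")
        assert np.allclose(dm.values(), 0.0)

    def test_matches_pairwise_beta_distance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 20, size=(5, 4))
        t = self._table(counts, 4)
        for metric in ("jaccard", "bray_curtis", "jsd"):
            dm = distance_matrix(t, metric)
            for i, j in itertools.combinations(range(4), 2):
                expect = beta_distance(counts[:, i], counts[:, j], metric)
                assert dm.values()[i, j] == pytest.approx(expect)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 20, size=(5, 4))
        t = self._table(counts, 4)
        dm = distance_matrix(t, "bray_curtis")
        perm = ["s2", "s0", "s3", "s1"]
        dmp = distance_matrix(t.subset_samples(perm), "bray_curtis")
        pd.testing.assert_frame_equal(dm.data.loc[perm, perm], dmp.data)


class TestPcoa:
    def test_zero_distances_give_zero_coordinates(self):
        ids = ["a", "b", "c"]
        dm = DistanceMatrix(pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids), "test")
        ordn = pcoa(dm)
        assert np.allclose(ordn.coordinates.to_numpy(), 0.0)

    def test_collinear_points_single_axis(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        ordn = pcoa(DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), "test"))
        assert ordn.eigenvalues.size == 1
        pco1 = ordn.coordinates["PCo1"].to_numpy()
        expect = np.array([-1.0, 0.0, 1.0])
        assert np.allclose(pco1, expect) or np.allclose(pco1, -expect)

    def test_euclidean_embedding_reconstructs_distances(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 4))
        d = ssd.squareform(ssd.pdist(pts))
        ids = [f"s{i}" for i in range(12)]
        ordn = pcoa(DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), "euclid"))
        rec = ssd.squareform(ssd.pdist(ordn.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_positive_eigenvalue_sum_equals_gram_trace(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        d = ssd.squareform(ssd.pdist(pts))
        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), "euclid")
        ordn = pcoa(dm)
        n = 8
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ (d ** 2) @ j
        assert ordn.eigenvalues.sum() == pytest.approx(np.trace(g), abs=1e-9)

    def test_matches_skbio_pcoa(self):
        import skbio
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(10, 3))
        d = ssd.squareform(ssd.pdist(pts))
        ids = [f"s{i}" for i in range(10)]
        ours = pcoa(DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), "euclid"))
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids=ids))
        k = min(3, ours.coordinates.shape[1])
        for ax in range(k):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = theirs.samples.iloc[:, ax].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


def brute_force_single_factor(d: np.ndarray, groups: list) -> tuple[float, float, float]:
    """Direct SS decomposition from squared distances for one factor."""
    n = d.shape[0]
    ss_total = (d ** 2)[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in set(groups):
        idx = [i for i, x in enumerate(groups) if x == g]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub ** 2)[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    k = len(set(groups))
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return ss_total, ss_between, f


class TestPermanova:
    def _dm(self, d, ids):
        return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), "test")

    def test_single_level_factor_rejected(self):
        ids = ["a", "b", "c"]
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="single level"):
            permanova(self._dm(d, ids), {"g": pd.Series(["x"] * 3, index=ids)})

    def test_r2_sums_to_one(self):
        rng = np.random.default_rng(12)
        n = 12
        pts = rng.normal(size=(n, 3))
        d = ssd.squareform(ssd.pdist(pts))
        ids = [f"s{i}" for i in range(n)]
        terms = {"g1": pd.Series(rng.choice(["a", "b"], n), index=ids),
                 "g2": pd.Series(rng.choice(["u", "v", "w"], n), index=ids)}
        vd = permanova(self._dm(d, ids), terms, n_perm=49, seed=0)
        r2 = vd.table.drop(index="total")["r2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_six_sample_toy_matches_brute_force(self):
        # two well-separated triplets
        rng = np.random.default_rng(13)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(8, 1, (3, 2))])
        d = ssd.squareform(ssd.pdist(pts))
        ids = [f"s{i}" for i in range(6)]
        groups = ["a", "a", "a", "b", "b", "b"]
        vd = permanova(self._dm(d, ids), {"g": pd.Series(groups, index=ids)},
                       n_perm=99, seed=1)
        ss_total, ss_between, f = brute_force_single_factor(d, groups)
        assert vd.table.loc["g", "ss"] == pytest.approx(ss_between, abs=1e-9)
        assert vd.table.loc["total", "ss"] == pytest.approx(ss_total, abs=1e-9)
        assert vd.table.loc["g", "F"] == pytest.approx(f, abs=1e-9)

    def test_matches_skbio_single_factor(self):
        import skbio
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(10, 3))
        d = ssd.squareform(ssd.pdist(pts))
        ids = [f"s{i}" for i in range(10)]
        groups = list("aabbbababa")
        vd = permanova(self._dm(d, ids), {"g": pd.Series(groups, index=ids)},
                       n_perm=99, seed=2)
        theirs = skbio.stats.distance.permanova(skbio.DistanceMatrix(d, ids=ids),
                                                grouping=groups, permutations=0)
        assert vd.table.loc["g", "F"] == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_numeric_covariate_r2_matches_ols(self):
        # Euclidean distances of 1-D responses: PERMANOVA R^2 on a numeric
        # covariate equals the linear-regression R^2
        rng = np.random.default_rng(16)
        n = 15
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        d = np.abs(y[:, None] - y[None, :])
        ids = [f"s{i}" for i in range(n)]
        vd = permanova(self._dm(d, ids), {"x": pd.Series(x, index=ids)},
                       n_perm=19, seed=0)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        r2_ols = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert vd.table.loc["x", "r2"] == pytest.approx(r2_ols, abs=1e-9)

    def test_null_pvalues_super_uniform(self):
        # random labels on random distances: P(p <= alpha) should not exceed
        # alpha by more than Monte Carlo error
        rng = np.random.default_rng(15)
        pvals = []
        ids = [f"s{i}" for i in range(10)]
        for _ in range(200):
            pts = rng.normal(size=(10, 2))
            d = ssd.squareform(ssd.pdist(pts))
            groups = pd.Series(rng.choice(["a", "b"], 10), index=ids)
            if groups.nunique() < 2:
                continue
            vd = permanova(self._dm(d, ids), {"g": groups}, n_perm=199,
                           seed=int(rng.integers(2**31)))
            pvals.append(vd.table.loc["g", "p"])
        pvals = np.asarray(pvals)
        assert (pvals <= 0.05).mean() < 0.09


class TestAlphaVarianceDecomposition:
    def _balanced(self, subject_effects, time_effects, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for si, se in enumerate(subject_effects):
            for ti, te in enumerate(time_effects):
                rows.append((f"S{si}_t{ti}", f"S{si}", f"tp{ti}",
                             se + te + noise * rng.normal()))
        df = pd.DataFrame(rows, columns=["sample", "subject", "tp", "value"]).set_index("sample")
        return df

    def test_constant_values_flagged_degenerate(self):
        df = self._balanced([0, 0, 0], [0, 0])
        vd = alpha_variance_decomposition(df["value"], df["subject"], df["tp"])
        assert vd.degenerate
        assert vd.table.loc["residual", "r2"] == 1.0

    def test_subject_only_signal_allocates_to_subject(self):
        df = self._balanced([0.0, 5.0, 10.0, 2.0], [0.0, 0.0, 0.0], noise=1e-6, seed=1)
        vd = alpha_variance_decomposition(df["value"], df["subject"], df["tp"])
        assert vd.table.loc["subject", "r2"] > 0.999

    def test_balanced_design_matches_group_mean_arithmetic(self):
        df = self._balanced([0.0, 1.0, 3.0, -1.0, 2.0, 0.5],
                            [0.0, 0.7, 1.5], noise=0.3, seed=2)
        vd = alpha_variance_decomposition(df["value"], df["subject"], df["tp"])
        v = df["value"]
        grand = v.mean()
        ss_subj = sum(len(g) * (g.mean() - grand) ** 2 for _, g in v.groupby(df["subject"]))
        ss_tp = sum(len(g) * (g.mean() - grand) ** 2 for _, g in v.groupby(df["tp"]))
        assert vd.table.loc["subject", "ss"] == pytest.approx(ss_subj, rel=1e-9)
        assert vd.table.loc["timepoint", "ss"] == pytest.approx(ss_tp, rel=1e-9)
        assert vd.table.drop(index="total")["r2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_confounded_factors_error(self):
        df = pd.DataFrame({"value": [1.0, 2, 3, 4],
                           "subject": ["A", "A", "B", "B"],
                           "tp": ["t0", "t0", "t1", "t1"]},
                          index=["s1", "s2", "s3", "s4"])
        with pytest.raises(ValueError, match="confounded"):
            alpha_variance_decomposition(df["value"], df["subject"], df["tp"])


class TestCoordinateFactorR2:
    def _ord(self, scores):
        from vertiseq.diversity import Ordination
        ids = [f"s{i}" for i in range(len(scores))]
        coords = pd.DataFrame({"PCo1": scores}, index=ids)
        return Ordination(coords, np.array([1.0]), np.array([1.0])), ids

    def test_saturated_factor_r2_one(self):
        ordn, ids = self._ord([0.3, 1.2, -0.5])
        r2, p = coordinate_factor_r2(ordn, 1, pd.Series(["a", "b", "c"], index=ids))
        assert r2 == pytest.approx(1.0)

    def test_constant_scores_degenerate(self):
        ordn, ids = self._ord([1.0, 1.0, 1.0, 1.0])
        r2, p = coordinate_factor_r2(ordn, 1, pd.Series(["a", "a", "b", "b"], index=ids))
        assert r2 == 0.0 and np.isnan(p)

    def test_null_mean_r2_matches_expectation(self):
        # independent factor: E[R^2] = (k-1)/(n-1)
        rng = np.random.default_rng(21)
        n, k = 20, 4
        r2s = []
        for _ in range(400):
            ordn, ids = self._ord(rng.normal(size=n))
            factor = pd.Series(rng.choice([f"g{i}" for i in range(k)], n), index=ids)
            if factor.nunique() < k:
                continue
            r2s.append(coordinate_factor_r2(ordn, 1, factor)[0])
        assert np.mean(r2s) == pytest.approx((k - 1) / (n - 1), abs=0.02)
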