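"""Clustering and ANOVA, each checked against independent brute-force
oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msapquant import anova, cluster, round_half_up

from reference_values import DIVERGENT_LINES


def _frame(points, labels=None):
    points = np.asarray(points, dtype=float)
    labels = labels or [f"P{i}" for i in range(len(points))]
    return pd.DataFrame(points, index=labels)


def brute_force_ward(points):
    """Naive Ward agglomeration: at each step merge the pair of clusters
    with the smallest increase of total within-cluster sum of squares.
    Returns the sorted merge costs and the final two-cluster partition."""
    clusters = [[i] for i in range(len(points))]
    points = np.asarray(points, dtype=float)

    def ess(idx):
        sub = points[idx]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    costs = []
    partition_at_two = None
    while len(clusters) > 1:
        best = min(
            itertools.combinations(range(len(clusters)), 2),
            key=lambda ij: ess(clusters[ij[0]] + clusters[ij[1]])
            - ess(clusters[ij[0]]) - ess(clusters[ij[1]]),
        )
        i, j = best
        cost = ess(clusters[i] + clusters[j]) - ess(clusters[i]) - ess(clusters[j])
        costs.append(cost)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        if len(clusters) == 2:
            partition_at_two = [sorted(c) for c in clusters]
    return costs, partition_at_two


class TestCluster:
    def test_heights_match_bruteforce_ward_costs(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pts = rng.normal(size=(7, 3))
            dendro = cluster(_frame(pts))
            costs, _ = brute_force_ward(pts)
            assert np.allclose(sorted(dendro.heights), sorted(costs),
                               atol=1e-10)

    def test_two_cluster_partition_matches_bruteforce(self):
        rng = np.random.default_rng(99)
        pts = rng.normal(size=(8, 2))
        dendro = cluster(_frame(pts))
        _, expected = brute_force_ward(pts)
        # cut the tree at two clusters via the last merge
        from scipy.cluster import hierarchy
        z = dendro.linkage.copy()
        z[:, 2] = np.sqrt(2 * z[:, 2])
        flat = hierarchy.fcluster(z, t=2, criterion="maxclust")
        got = [sorted(np.flatnonzero(flat == k)) for k in (1, 2)]
        assert sorted(map(tuple, got)) == sorted(map(tuple, expected))

    def test_identical_samples_merge_at_zero(self):
        dendro = cluster(_frame([[1.0, 2.0], [1.0, 2.0]]))
        assert dendro.heights[0] == 0.0

    def test_outlier_merges_last(self):
        dendro = cluster(_frame([[0.0], [0.1], [100.0]], ["a", "b", "far"]))
        last = dendro.linkage[-1]
        assert dendro.heights[-1] > dendro.heights[0]
        labels = dendro.truncate()
        assert labels["far"] != labels["a"] == labels["b"]

    def test_heights_are_monotone(self, triticale_characteristics):
        dendro = cluster(triticale_characteristics)
        assert (np.diff(dendro.heights) >= -1e-12).all()

    def test_divergent_lines_separate(self, triticale_characteristics):
        dendro = cluster(triticale_characteristics)
        labels = dendro.truncate()
        assert labels.nunique() == 2
        minor = set(labels.index[labels == labels["NT2"]])
        assert minor == DIVERGENT_LINES

    def test_truncation_robust_to_report_rounding(self,
                                                  triticale_characteristics):
        full = cluster(triticale_characteristics).truncate()
        rounded = cluster(round_half_up(triticale_characteristics)).truncate()
        grouping = lambda s: sorted(
            tuple(sorted(s.index[s == k])) for k in s.unique())
        assert grouping(full) == grouping(rounded)

    def test_requires_two_samples(self, triticale_characteristics):
        with pytest.raises(ValueError, match="at least two"):
            cluster(triticale_characteristics.iloc[:1])

    def test_newick_round_trips_tip_depths(self, triticale_characteristics):
        from skbio.tree import TreeNode
        import io

        dendro = cluster(triticale_characteristics)
        tree = TreeNode.read(io.StringIO(dendro.to_newick()))
        tips = {t.name for t in tree.tips()}
        assert tips == set(triticale_characteristics.index)
        # every leaf sits at the root height => root-to-tip depth equals
        # the final merge height
        for tip in tree.tips():
            depth = sum(n.length for n in tip.ancestors() if n.length) + tip.length
            assert depth == pytest.approx(dendro.heights[-1])


class TestAnova:
    def test_agrees_with_bruteforce_sums_of_squares(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            k = rng.integers(2, 5)
            sizes = rng.integers(2, 7, size=k)
            values = np.concatenate([rng.normal(loc=g, size=s)
                                     for g, s in enumerate(sizes)])
            groups = np.concatenate([[f"g{g}"] * s
                                     for g, s in enumerate(sizes)])
            res = anova(values, groups)
            grand = values.mean()
            ss_total = ((values - grand) ** 2).sum()
            ss_between = sum(
                (values[groups == g].mean() - grand) ** 2
                * (groups == g).sum() for g in np.unique(groups))
            ss_within = ss_total - ss_between
            f = (ss_between / (k - 1)) / (ss_within / (len(values) - k))
            assert res.f_statistic == pytest.approx(f, abs=1e-10)
            assert res.variance_explained == pytest.approx(
                ss_between / ss_total, abs=1e-10)
            assert res.p_value == pytest.approx(
                stats.f.sf(f, k - 1, len(values) - k), abs=1e-12)

    def test_hand_computed_two_by_three_layout(self):
        res = anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == pytest.approx(1.5)
        assert res.variance_explained == pytest.approx(1.5 / 5.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_identical_group_means_give_zero_f(self):
        res = anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == 0.0
        assert res.variance_explained == 0.0

    def test_perfect_separation_explains_everything(self):
        res = anova([0, 0, 0, 1, 1, 1], ["a"] * 3 + ["b"] * 3)
        assert res.variance_explained == pytest.approx(1.0)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            anova([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(ValueError, match="more observations"):
            anova([1, 2], ["a", "b"])
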