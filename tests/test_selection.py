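"""Feature clustering, univariate AUC screening, representative selection
(FDR-gated centralized, weighted-vote distributed) and the overlap metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_site
from fedrad import (
    cluster_features,
    cluster_overlap,
    select_representatives_centralized,
    select_representatives_distributed,
    site_cluster_votes,
    univariate_auc,
    zscore,
)
from fedrad.federation import ClusterVoteMessage
from fedrad.selection import ClusterAssignment


def corr_df(mat, names=None):
    names = names or [f"f{j}" for j in range(len(mat))]
    return pd.DataFrame(np.asarray(mat, dtype=float), index=names, columns=names)


class TestZscore:
    def test_centering(self):
        df = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        out = zscore(df, np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        assert (out["a"] == 0).all()

    def test_global_stats_standardize_concatenation(self):
        rng = np.random.default_rng(0)
        parts = [pd.DataFrame(rng.normal(5, 3, size=(n, 2)), columns=["a", "b"])
                 for n in (30, 70)]
        concat = pd.concat(parts, ignore_index=True)
        mean, sd = concat.mean().to_numpy(), concat.std(ddof=1).to_numpy()
        z = pd.concat([zscore(p, mean, sd) for p in parts], ignore_index=True)
        np.testing.assert_allclose(z.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1, rtol=1e-12)

    def test_constant_feature_removed_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "c": [3.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = zscore(df, df.mean().to_numpy(), df.std(ddof=1).to_numpy())
        assert list(out.columns) == ["a"]

    def test_missing_entries_stay_missing(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        out = zscore(df, np.array([2.0]), np.array([1.0]))
        assert out["a"].isna().sum() == 1


class TestClusterFeatures:
    def test_single_strong_pair(self):
        ca = cluster_features(corr_df([[1, 0.9, 0], [0.9, 1, 0], [0, 0, 1]]))
        assert ca.labels["f0"] == ca.labels["f1"] != ca.labels["f2"]

    def test_identity_matrix_gives_singletons(self):
        ca = cluster_features(corr_df(np.eye(5)))
        assert ca.num_clusters == 5

    def test_two_pairs_by_hand(self):
        mat = np.full((4, 4), 0.1)
        np.fill_diagonal(mat, 1.0)
        mat[0, 1] = mat[1, 0] = 0.7
        mat[2, 3] = mat[3, 2] = 0.7
        ca = cluster_features(corr_df(mat))
        assert ca.labels["f0"] == ca.labels["f1"]
        assert ca.labels["f2"] == ca.labels["f3"]
        assert ca.num_clusters == 2

    def test_negative_correlation_clusters_by_absolute_value(self):
        ca = cluster_features(corr_df([[1, -0.9], [-0.9, 1]]))
        assert ca.num_clusters == 1
        signed = cluster_features(corr_df([[1, -0.9], [-0.9, 1]]), signed=True)
        assert signed.num_clusters == 2

    def test_invariant_to_feature_order(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(300, 6))
        x[:, 1] = x[:, 0] + 0.3 * rng.normal(size=300)
        x[:, 4] = x[:, 3] + 0.3 * rng.normal(size=300)
        df = pd.DataFrame(x, columns=[f"f{j}" for j in range(6)])
        ca = cluster_features(df.corr())
        perm = ["f4", "f0", "f5", "f2", "f3", "f1"]
        ca_p = cluster_features(df[perm].corr())
        for a in df.columns:
            for b in df.columns:
                assert (ca.labels[a] == ca.labels[b]) == (ca_p.labels[a] == ca_p.labels[b])

    def test_rejects_invalid_matrix(self):
        with pytest.raises(ValueError):
            cluster_features(corr_df([[1, 0.5], [0.2, 1]]))
        with pytest.raises(ValueError):
            cluster_features(corr_df([[1, 1.5], [1.5, 1]]))


class TestUnivariateAUC:
    def test_perfect_separator(self):
        auc, p = univariate_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_constant_feature_is_uninformative(self):
        auc, p = univariate_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == 0.5 and p == 1.0

    @pytest.mark.parametrize(
        "outcome,expected", [([0, 0, 1, 1], 1.0), ([0, 1, 0, 1], 0.75)]
    )
    def test_pair_counting(self, outcome, expected):
        auc, _ = univariate_auc([1, 2, 3, 4], outcome)
        assert auc == pytest.approx(expected)

    def test_direction_flip_keeps_auc_above_half(self):
        auc_up, _ = univariate_auc([1, 2, 3, 4], [0, 0, 1, 1])
        auc_dn, _ = univariate_auc([4, 3, 2, 1], [0, 0, 1, 1])
        assert auc_up == auc_dn == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            univariate_auc([1, 2, 3], [1, 1, 1])


def two_cluster_data(n=400, seed=2, informative=True):
    """Two clusters of two correlated features; cluster 1 drives the outcome."""
    rng = np.random.default_rng(seed)
    u1, u2 = rng.normal(size=(2, n))
    x = np.column_stack([
        u1 + 0.4 * rng.normal(size=n), u1 + 0.4 * rng.normal(size=n),
        u2 + 0.4 * rng.normal(size=n), u2 + 0.4 * rng.normal(size=n),
    ])
    lp = 1.5 * x[:, 0] if informative else np.zeros(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    df = pd.DataFrame(x, columns=["a1", "a2", "b1", "b2"])
    clusters = cluster_features(df.corr())
    return df, y, clusters


class TestCentralizedSelection:
    def test_informative_winner_passes_fdr_gate(self):
        df, y, clusters = two_cluster_data()
        res = select_representatives_centralized(clusters, df, y)
        assert "a1" in res.selected or "a2" in res.selected
        # the pure-noise cluster's winner must not pass the gate
        assert not {"b1", "b2"} & set(res.selected)

    def test_null_outcome_selects_nothing(self):
        df, y, clusters = two_cluster_data(informative=False, seed=3)
        res = select_representatives_centralized(clusters, df, y)
        assert res.selected == []

    def test_auc_ties_break_to_smallest_feature_id(self):
        df = pd.DataFrame({"z2": [1.0, 2, 3, 4], "z1": [1.0, 2, 3, 4]})
        y = [0, 0, 1, 1]
        clusters = ClusterAssignment(labels={"z1": 1, "z2": 1}, linkage_record=np.empty((0, 4)))
        res = select_representatives_centralized(clusters, df, y)
        assert res.per_cluster[1]["winner"] == "z1"


class TestDistributedSelection:
    def make_votes(self, sizes, winners, cluster=1):
        return [
            ClusterVoteMessage(site_id=f"s{k}", n=n, best_feature_per_cluster={cluster: (w, 0.8)})
            for k, (n, w) in enumerate(zip(sizes, winners))
        ]

    def clusters_for(self, feats, cluster=1):
        return ClusterAssignment(labels={f: cluster for f in feats}, linkage_record=np.empty((0, 4)))

    def test_cohort_size_weighted_vote(self):
        # three of four cohorts (206+441+100 of 888 patients) vote for f: 84.1%
        votes = self.make_votes([206, 441, 100, 141], ["f", "f", "f", "g"])
        res = select_representatives_distributed(self.clusters_for(["f", "g"]), votes)
        assert res.per_cluster[1]["vote_weight"] == pytest.approx(747 / 888)
        assert res.selected == ["f"]

    def test_unanimous_vote_selected(self):
        votes = self.make_votes([50, 50], ["f", "f"])
        res = select_representatives_distributed(self.clusters_for(["f"]), votes)
        assert res.selected == ["f"]

    def test_split_vote_selects_nothing(self):
        votes = self.make_votes([50, 50], ["f", "g"])
        res = select_representatives_distributed(self.clusters_for(["f", "g"]), votes)
        assert res.selected == []

    def test_monotone_in_vote_threshold(self):
        votes = self.make_votes([206, 441, 100, 141], ["f", "f", "f", "g"])
        clusters = self.clusters_for(["f", "g"])
        prev = None
        for thr in (0.5, 0.7, 0.8, 0.9, 1.0):
            sel = set(select_representatives_distributed(clusters, votes, thr).selected)
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_inconsistent_labelling_rejected(self):
        votes = self.make_votes([50], ["f"], cluster=2)
        with pytest.raises(ValueError, match="inconsistent"):
            select_representatives_distributed(self.clusters_for(["f"], cluster=1), votes)

    def test_single_site_reduces_to_per_cluster_max_auc(self):
        df, y, clusters = two_cluster_data(seed=4)
        site = make_site(df.to_numpy(), outcome=y, columns=list(df.columns))
        votes = [site_cluster_votes(site, clusters)]
        res = select_representatives_distributed(clusters, votes, vote_threshold=0.8)
        # with one site every cluster winner has weight 1: both clusters selected
        assert len(res.selected) == clusters.num_clusters
        for entry in res.per_cluster.values():
            assert entry["vote_weight"] == 1.0


class TestClusterOverlap:
    def assignment(self, labels):
        return ClusterAssignment(labels=labels, linkage_record=np.empty((0, 4)))

    def test_identical_clusterings(self):
        a = self.assignment({"f1": 1, "f2": 1, "f3": 2})
        assert cluster_overlap(a, a) == 1.0

    def test_all_singletons_is_degenerate_one(self):
        a = self.assignment({"f1": 1, "f2": 2, "f3": 3})
        b = self.assignment({"f1": 1, "f2": 1, "f3": 1})
        assert cluster_overlap(a, b) == 1.0

    def test_split_cluster_by_hand(self):
        central = self.assignment({f: 1 for f in "abcd"})
        distributed = self.assignment({"a": 1, "b": 1, "c": 2, "d": 3})
        assert cluster_overlap(central, distributed) == 0.5

    def test_mismatched_features_rejected(self):
        with pytest.raises(ValueError):
            cluster_overlap(self.assignment({"a": 1}), self.assignment({"b": 1}))
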