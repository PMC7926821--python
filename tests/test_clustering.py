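"""K-means, severity ordering, and the ANOVA cluster-validity test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from consafety.clustering import (
    anova_validity,
    cluster_panel,
    kmeans,
    rank_clusters,
)


def brute_force_wss(X: np.ndarray, k: int) -> float:
    """Minimum within-cluster SS over every assignment of points to k clusters."""
    n = len(X)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        groups = set(assign)
        if len(groups) < k:
            continue
        labels = np.array(assign)
        wss = sum(
            ((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum() for c in groups
        )
        best = min(best, wss)
    return best


def test_distinct_points_one_per_cluster():
    X = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    result = kmeans(X, 3, seed=0, restarts=10)
    assert result.within_ss == pytest.approx(0.0)
    assert sorted(result.labels) == [1, 2, 3]


def test_six_points_two_clusters_match_exhaustive_oracle():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(6, 2))
    result = kmeans(X, 2, seed=0, restarts=50)
    assert result.within_ss == pytest.approx(brute_force_wss(X, 2), rel=1e-9)


@pytest.mark.parametrize("n,k,seed", [(5, 2, 1), (7, 3, 2), (8, 3, 3), (8, 2, 4)])
def test_small_instances_reach_global_optimum(n, k, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2)) * 3
    result = kmeans(X, k, seed=0, restarts=50)
    assert result.within_ss == pytest.approx(brute_force_wss(X, k), rel=1e-9)


@given(st.integers(0, 1000))
@settings(derandomize=True, max_examples=20)
def test_lloyd_wss_monotone_nonincreasing(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(20, 2))
    result = kmeans(X, 3, seed=seed, restarts=1)
    hist = result.wss_history
    assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))


def test_k_larger_than_n_rejected():
    with pytest.raises(ValueError):
        kmeans(np.zeros((2, 2)), 3)
    with pytest.raises(ValueError):
        kmeans(np.array([[np.nan, 0.0]]), 1)


def test_labels_ordered_by_centroid_norm():
    """Cluster 1 must be the group with the largest centroid norm."""
    X = np.array([[100.0, 100.0], [101.0, 99.0], [1.0, 1.0], [2.0, 0.0]])
    result = kmeans(X, 2, seed=0, restarts=10)
    assert list(result.labels) == [1, 1, 2, 2]


# ---------------------------------------------------------------------------
# rank_clusters
# ---------------------------------------------------------------------------


def _result_with(centroids, labels):
    from consafety.clustering import ClusterResult

    return ClusterResult(np.asarray(labels), np.asarray(centroids, float), 1, 0.0, True)


def test_rank_clusters_by_severity_feature():
    res = _result_with([[134, 179], [665, 749], [303, 345]], [1, 2, 2, 3, 3, 3])
    ranked = rank_clusters(res, feature=0)
    # centroid (665,749) -> label 1, (303,345) -> 2, (134,179) -> 3
    assert ranked.centroids[0].tolist() == [665, 749]
    assert list(ranked.labels) == [3, 1, 1, 2, 2, 2]


def test_rank_single_cluster_is_label_one():
    res = _result_with([[5.0, 5.0]], [1, 1, 1])
    assert list(rank_clusters(res).labels) == [1, 1, 1]


def test_rank_ties_broken_by_cluster_size():
    res = _result_with([[2.0], [2.0]], [1, 2, 2])
    ranked = rank_clusters(res, feature=0)
    # equal centroids: the larger cluster takes the smaller label
    assert list(ranked.labels) == [2, 1, 1]


# ---------------------------------------------------------------------------
# ANOVA validity
# ---------------------------------------------------------------------------


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(7)
    groups = [rng.normal(loc=m, size=s) for m, s in [(0, 5), (1.5, 8), (-1, 6)]]
    values = np.concatenate(groups)
    labels = np.concatenate([[i + 1] * len(g) for i, g in enumerate(groups)])
    ours = anova_validity(values, labels)
    ref = stats.f_oneway(*groups)
    assert ours.f_statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)
    assert ours.df_between == 2 and ours.df_within == len(values) - 3


def test_anova_ss_decomposition_by_brute_force():
    values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 20.0, 22.0, 24.0])
    labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
    res = anova_validity(values, labels)
    total_ss = ((values - values.mean()) ** 2).sum()
    assert res.between_ss + res.within_ss == pytest.approx(total_ss, rel=1e-12)


@given(st.integers(0, 500))
@settings(derandomize=True, max_examples=30)
def test_anova_conserves_total_ss(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=15)
    labels = rng.integers(1, 4, size=15)
    if len(np.unique(labels)) < 2:
        labels[0], labels[1] = 1, 2
    res = anova_validity(values, labels)
    total_ss = ((values - values.mean()) ** 2).sum()
    assert res.between_ss + res.within_ss == pytest.approx(total_ss, rel=1e-9)


def test_anova_degenerate_cases():
    with pytest.raises(ValueError):
        anova_validity([1.0, 2.0], [1, 1])
    flat = anova_validity([1.0, 1.0, 2.0, 2.0], [1, 1, 2, 2])
    assert flat.within_ss == 0.0
    assert np.isinf(flat.f_statistic) and flat.p_value == 0.0
    same_means = anova_validity([1.0, 3.0, 1.0, 3.0], [1, 1, 2, 2])
    assert same_means.f_statistic == pytest.approx(0.0)


def test_panel_anova_reproduces_reference_f_statistics(panel):
    """All four published validity F statistics, on the printed memberships."""
    expected = {
        ("accidents", "cluster_absolute"): (198922.339, 2896.036, 68.688),
        ("deaths", "cluster_absolute"): (239088.162, 3696.099, 64.687),
        ("rate_production", "cluster_relative"): (62881.544, 461.383, 136.289),
        ("rate_staff", "cluster_relative"): (17834.703, 241.183, 73.947),
    }
    for (feature, col), (bms, wms, f) in expected.items():
        res = anova_validity(panel[feature].to_numpy(float), panel[col].to_numpy())
        assert res.between_ms == pytest.approx(bms, abs=5e-4)
        assert res.within_ms == pytest.approx(wms, abs=5e-4)
        assert res.f_statistic == pytest.approx(f, abs=5e-4)
        assert (res.df_between, res.df_within) == (2, 28)
        assert res.p_value < 0.0005  # "Sig = 0"
        assert res.f_statistic > res.critical_value


def test_f_critical_value_from_distribution():
    """The α=0.05 critical value for a 3-cluster test on 31 regions comes
    from F(2,28) and is 3.34; the 4.196 sometimes quoted for this layout is
    the F(1,28) critical value, i.e. a single-numerator-df slip."""
    rng = np.random.default_rng(0)
    values = rng.normal(size=31)
    labels = np.repeat([1, 2, 3], [10, 10, 11])
    res = anova_validity(values, labels)
    assert (res.df_between, res.df_within) == (2, 28)
    assert res.critical_value == pytest.approx(3.3404, abs=5e-4)
    assert stats.f.ppf(0.95, 1, 28) == pytest.approx(4.196, abs=5e-4)


def test_kmeans_agrees_with_sklearn_reference(panel):
    """Our Lloyd solver and scikit-learn's reach the same optimum on the panel."""
    from sklearn.cluster import KMeans

    for cols in (["accidents", "deaths"], ["rate_production", "rate_staff"]):
        X = panel[cols].to_numpy(float)
        ours = kmeans(X, 3, seed=0, restarts=50)
        ref = KMeans(n_clusters=3, n_init=50, random_state=0).fit(X)
        assert ours.within_ss == pytest.approx(ref.inertia_, rel=1e-9)
        same_partition = {frozenset(np.flatnonzero(ours.labels == c + 1)) for c in range(3)} == {
            frozenset(np.flatnonzero(ref.labels_ == c)) for c in range(3)
        }
        assert same_partition


# ---------------------------------------------------------------------------
# Panel clustering end-to-end
# ---------------------------------------------------------------------------


def test_absolute_factor_clustering_recovers_reference_partition(panel):
    result, labels, anova = cluster_panel(
        panel, ["accidents", "deaths"], 3, seed=0, restarts=50
    )
    assert (labels == panel["cluster_absolute"]).all()
    # Jiangsu alone in the most critical cluster; 8 regions in cluster 2
    assert labels["Jiangsu"] == 1 and (labels == 1).sum() == 1
    assert (labels == 2).sum() == 8
    assert anova["accidents"].f_statistic == pytest.approx(68.688, abs=5e-4)


def test_relative_factor_clustering_top_groups(panel):
    """Hainan and Qinghai always land in the most critical relative cluster.

    Best-of-restarts Lloyd finds a partition at least as good (by WSS) as
    the published one, which is a local optimum; membership of the two
    extreme provinces in cluster 1 is stable either way.
    """
    result, labels, _ = cluster_panel(
        panel, ["rate_production", "rate_staff"], 3, seed=0, restarts=50
    )
    assert labels["Hainan"] == 1 and labels["Qinghai"] == 1
    published = panel["cluster_relative"].to_numpy()
    X = panel[["rate_production", "rate_staff"]].to_numpy(float)
    published_wss = sum(
        ((X[published == c] - X[published == c].mean(axis=0)) ** 2).sum()
        for c in (1, 2, 3)
    )
    assert result.within_ss <= published_wss + 1e-9
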