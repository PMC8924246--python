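import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import DBSCAN as SKDBSCAN

from nucleopol.clustering import (
    ClusterParams,
    DensityClusterer,
    cluster_area,
    dbscan_labels,
    detect_clusters,
    summarize_clusters,
)
from nucleopol.simulate import PatternSpec, simulate_clustered

from _oracles import dbscan_bruteforce


def tight_group(center, n, radius=1.0, seed=0):
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    return np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])


class TestDBSCANLabels:
    def test_two_distant_groups_two_labels(self):
        xy = np.vstack([tight_group((0, 0), 20, seed=1),
                        tight_group((10_000, 10_000), 20, seed=2)])
        labels = dbscan_labels(xy, epsilon=20.0, min_pts=3)
        assert set(labels) == {0, 1}

    def test_two_neighbours_not_core_at_min_pts_three(self):
        # the neighbour count excludes the point itself: a molecule with
        # only 2 others in its search area is not a core point
        xy = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        labels = dbscan_labels(xy, epsilon=20.0, min_pts=3)
        assert np.all(labels == -1)

    def test_three_neighbours_is_core(self):
        xy = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [-5.0, 0.0]])
        labels = dbscan_labels(xy, epsilon=20.0, min_pts=3)
        assert np.all(labels == 0)

    def test_empty_input(self):
        assert len(dbscan_labels(np.empty((0, 2)), 20.0, 3)) == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_region_query(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 200)
        xy = rng.uniform(0, 300, (n, 2))
        eps = rng.uniform(10, 40)
        labels = dbscan_labels(xy, eps, 3)
        expected = dbscan_bruteforce(xy, eps, 3)
        np.testing.assert_array_equal(labels, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_core_points_match_sklearn(self, seed):
        # independent cross-check: sklearn counts the point itself, so
        # min_samples = min_pts + 1; core-point cluster memberships must
        # induce the same partition
        rng = np.random.default_rng(1000 + seed)
        xy = rng.uniform(0, 200, (150, 2))
        eps, min_pts = 15.0, 3
        ours = dbscan_labels(xy, eps, min_pts)
        sk = SKDBSCAN(eps=eps, min_samples=min_pts + 1).fit(xy)
        core = np.zeros(len(xy), bool)
        core[sk.core_sample_indices_] = True
        # same points are core/noise, and core points co-cluster identically
        assert set(map(tuple, _partition(ours[core]))) == set(
            map(tuple, _partition(sk.labels_[core]))
        )

    def test_row_permutation_preserves_memberships(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 500, (120, 2))
        labels = dbscan_labels(xy, 25.0, 3)
        perm = rng.permutation(len(xy))
        labels_p = dbscan_labels(xy[perm], 25.0, 3)
        assert set(map(tuple, _partition(labels))) == set(
            map(tuple, _partition(labels_p[np.argsort(perm)]))
        )


def _partition(labels):
    """Cluster memberships as frozen index-sets, ignoring label numbering."""
    out = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        out.append(tuple(sorted(np.flatnonzero(labels == lab))))
    return out


class TestDetectClusters:
    def test_ten_point_group_is_a_cluster(self, table_factory):
        t = table_factory(tight_group((100, 100), 10, seed=4))
        est = detect_clusters(t, ClusterParams(epsilon=20.0))
        assert est.summary_.n_clusters == 1

    def test_nine_point_group_is_not(self, table_factory):
        t = table_factory(tight_group((100, 100), 9, seed=5))
        est = detect_clusters(t, ClusterParams(epsilon=20.0))
        assert est.summary_.n_clusters == 0
        assert np.all(est.labels_ == -1)

    def test_no_cluster_below_min_size(self, table_factory):
        rng = np.random.default_rng(6)
        t = table_factory(rng.uniform(0, 2000, (400, 2)))
        est = detect_clusters(t, ClusterParams(epsilon=60.0, min_cluster_size=10))
        if len(est.clusters_):
            assert (est.clusters_["n_molecules"] >= 10).all()

    def test_epsilon_defaults_to_mean_precision(self, table_factory):
        t = table_factory(tight_group((0, 0), 30, seed=7), precision=25.0)
        est = DensityClusterer().fit(t)
        assert est.epsilon_ == pytest.approx(25.0)

    def test_epsilon_override_policy(self, table_factory):
        t = table_factory(tight_group((0, 0), 30, seed=8))
        est = DensityClusterer().fit(t, epsilon_override=120.0)
        assert est.epsilon_ == 120.0

    def test_parameter_recovery_on_thomas_pattern(self, square_roi):
        spec = PatternSpec(roi=square_roi, n_clusters=250, molecules_per_cluster=60,
                           cluster_sigma=20.0, background_fraction=0.10,
                           precision_sigma=0.0, seed=9)
        table, _ = simulate_clustered(spec)
        est = detect_clusters(table, ClusterParams(epsilon=20.0))
        assert abs(est.summary_.n_clusters - 250) <= 25
        assert abs(est.summary_.mean_molecules_per_cluster - 60) <= 9


class TestClusterArea:
    def test_rectangle_corners_hull_fallback(self):
        # 30 x 40 nm rectangle: 4 members -> convex hull area 1200 nm²
        pts = [(0, 0), (30, 0), (30, 40), (0, 40)]
        area, degenerate = cluster_area(pts)
        assert not degenerate
        assert area == pytest.approx(1200.0)

    def test_collinear_members_degenerate(self):
        area, degenerate = cluster_area([(0, 0), (10, 10), (20, 20)])
        assert degenerate and area == 0.0

    def test_too_few_members_degenerate(self):
        _, degenerate = cluster_area([(0, 0), (1, 1)])
        assert degenerate

    @pytest.mark.parametrize("seed", range(5))
    def test_kde_contour_within_hull_envelope(self, seed):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 20, (40, 2))
        area, degenerate = cluster_area(pts, smoothing_sigma=7.0)
        hull = ConvexHull(pts).volume
        assert not degenerate
        assert 0.5 * hull <= area <= 4.0 * hull


class TestSummary:
    def test_all_points_in_one_cluster(self, table_factory):
        t = table_factory(tight_group((0, 0), 20, seed=10))
        est = detect_clusters(t, ClusterParams(epsilon=20.0))
        assert summarize_clusters(est).percent_clustered == 100.0

    def test_half_clustered(self, table_factory):
        group = tight_group((0, 0), 20, seed=11)
        # 20 isolated points far apart, each with no neighbours
        lone = np.column_stack([np.linspace(5e4, 9e4, 20), np.full(20, 5e4)])
        t = table_factory(np.vstack([group, lone]))
        est = detect_clusters(t, ClusterParams(epsilon=20.0))
        assert summarize_clusters(est).percent_clustered == pytest.approx(50.0)

    def test_zero_clusters_flagged_with_nan_means(self, table_factory):
        lone = np.column_stack([np.linspace(0, 9e4, 9), np.zeros(9)])
        est = detect_clusters(table_factory(lone), ClusterParams(epsilon=20.0))
        s = summarize_clusters(est)
        assert s.n_clusters == 0
        assert np.isnan(s.mean_molecules_per_cluster)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClusterParams(epsilon=-1).validate()
        with pytest.raises(ValueError):
            ClusterParams(min_pts=5, min_cluster_size=3).validate()
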