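import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from evanomaly.density import (NOISE, OpticsParams, extract_clusters,
                               filter_to_cluster, optics_order,
                               select_primary_cluster, suggest_eps)
from evanomaly.distance import ComparisonSpec
from evanomaly.preprocess import DonorPoint, log_transform

from conftest import make_table


def pts_from(X, condition="ctrl", prefix="P"):
    return [DonorPoint(f"{prefix}{i:04d}", condition, x)
            for i, x in enumerate(np.asarray(X, dtype=float))]


def two_blobs(n=60, sep=10.0, scale=0.3, seed=0):
    rng = np.random.default_rng(seed)
    return np.vstack([rng.normal(0, scale, (n, 3)),
                      rng.normal(sep, scale, (n, 3))])


class TestOpticsOrder:
    def test_too_few_points_advises_smaller_min_pts(self):
        with pytest.raises(ValueError, match="min_pts"):
            optics_order(pts_from(np.zeros((3, 3))), OpticsParams(5, 1.0))

    def test_core_distance_matches_knn_oracle(self):
        """Core distance on a 7-point line equals the brute-force min_pts-th
        nearest-neighbor distance (neighborhood includes the point itself)."""
        X = np.array([[0., 0, 0], [1, 0, 0], [2, 0, 0], [3.5, 0, 0],
                      [5, 0, 0], [7, 0, 0], [9.5, 0, 0]])
        a = optics_order(pts_from(X), OpticsParams(min_pts=3, eps=1.0))
        oracle = np.sort(cdist(X, X), axis=1)[:, 2]
        np.testing.assert_allclose(a.core_distances, oracle)

    def test_two_blobs_give_two_reachability_valleys(self):
        X = two_blobs(n=60)
        a = optics_order(pts_from(X), OpticsParams(min_pts=50, eps=1.0))
        extract_clusters(a, 1.0)
        assert len(a.cluster_sizes()) == 2

    def test_single_blob_no_internal_split_at_permissive_eps(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 0.5, (120, 3))
        a = optics_order(pts_from(X), OpticsParams(min_pts=20, eps=5.0))
        extract_clusters(a, 5.0)
        sizes = a.cluster_sizes()
        assert len(sizes) == 1 and sizes[0] == 120


class TestExtractClusters:
    def test_degenerate_radius_all_noise(self):
        X = two_blobs(n=30)
        a = optics_order(pts_from(X), OpticsParams(min_pts=5, eps=1.0))
        extract_clusters(a, 1e-9)
        assert np.all(a.labels == NOISE)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_dbscan_equivalence(self, seed):
        """eps extraction over the ordering reproduces DBSCAN labels on
        unambiguous points (core points and definite noise; border points
        are order-dependent in both algorithms)."""
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.3, (80, 3)),
                       rng.normal(4, 0.3, (70, 3)),
                       rng.uniform(-3, 8, (40, 3))])
        eps, min_pts = 0.5, 5
        a = optics_order(pts_from(X), OpticsParams(min_pts, eps))
        extract_clusters(a, eps)
        db = DBSCAN(eps=eps, min_samples=min_pts).fit(X).labels_
        n_in_eps = (cdist(X, X) <= eps).sum(axis=1)  # includes self
        core = n_in_eps >= min_pts
        mapping = {}
        for ours, ref in zip(a.labels[core], db[core]):
            assert ours != NOISE and ref != NOISE
            assert mapping.setdefault(ours, ref) == ref
        assert len(set(mapping.values())) == len(mapping)
        near_core = (cdist(X, X[core]) <= eps).any(axis=1)
        definite_noise = ~core & ~near_core
        assert np.all(a.labels[definite_noise] == NOISE)
        assert np.all(db[definite_noise] == NOISE)

    def test_permutation_invariance_up_to_renaming(self):
        X = two_blobs(n=40, seed=5)
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(X))
        p1, p2 = pts_from(X), pts_from(X[perm])
        a1 = optics_order(p1, OpticsParams(10, 1.0))
        a2 = optics_order(p2, OpticsParams(10, 1.0))
        extract_clusters(a1, 1.0)
        extract_clusters(a2, 1.0)
        lab1 = {p.accession[-4:]: l for p, l in zip(p1, a1.labels)}
        # p2's accessions were renumbered; map back through perm.
        lab2 = {f"{perm[i]:04d}": l for i, l in enumerate(a2.labels)}
        mapping = {}
        for key, l1 in lab1.items():
            l2 = lab2[key]
            assert (l1 == NOISE) == (l2 == NOISE)
            if l1 != NOISE:
                assert mapping.setdefault(l1, l2) == l2


class TestPrimaryClusterSelection:
    def _assignment_with_two_clouds(self, nonpositive_in_big=False):
        """40 high-abundance + 25 low-abundance proteins, one condition pair;
        optionally plant a nonpositive raw area in the big cloud."""
        rng = np.random.default_rng(7)
        high = 2.0 ** rng.normal(20, 0.3, (40, 6))
        low = 2.0 ** rng.normal(8, 0.3, (25, 6))
        raw = np.vstack([high, low])
        table = make_table(raw)
        if nonpositive_in_big:
            # zero areas make the whole big cloud fail the all-positive rule;
            # the epsilon floor keeps the points geometrically inside the
            # cloud so only the positivity rule distinguishes the clusters
            for i in range(0, 40, 4):
                table.data.iloc[i, 1] = 0.0
        lt = log_transform(table, nonpositive_policy="epsilon_floor",
                           epsilon=2.0 ** 20)
        pts = []
        from evanomaly.preprocess import donor_points
        for cond in table.conditions:
            pts.extend(donor_points(lt, cond))
        a = optics_order(pts, OpticsParams(min_pts=10, eps=2.0))
        extract_clusters(a, 2.0)
        return a, lt

    def test_all_positive_beats_size(self):
        a, lt = self._assignment_with_two_clouds(nonpositive_in_big=True)
        select_primary_cluster(a, lt, rule="largest_all_positive")
        sel = a.selected_cluster_id
        members = {p.accession for p, l in zip(a.points, a.labels) if l == sel}
        # the smaller, all-positive low cloud wins over the tainted big one
        assert members == {f"P{i:05d}" for i in range(40, 65)}

    def test_both_positive_takes_larger(self):
        a, lt = self._assignment_with_two_clouds()
        select_primary_cluster(a, lt, rule="largest_all_positive")
        sel = a.selected_cluster_id
        sizes = a.cluster_sizes()
        assert sizes[sel] == max(sizes.values())

    def test_all_noise_raises(self):
        rng = np.random.default_rng(0)
        pts = pts_from(rng.uniform(0, 100, (30, 3)))
        a = optics_order(pts, OpticsParams(min_pts=10, eps=0.01))
        extract_clusters(a, 0.01)
        with pytest.raises(ValueError, match="eps"):
            select_primary_cluster(a, None)


class TestFilterToCluster:
    def _toy_assignment(self):
        """Hand-labelled assignment: membership rules only, no clustering."""
        pts = [DonorPoint("A", "ctrl", [0, 0, 0]),
               DonorPoint("A", "doped", [0, 0, 1]),
               DonorPoint("B", "ctrl", [0, 1, 0]),
               DonorPoint("B", "doped", [9, 9, 9]),
               DonorPoint("C", "ctrl", [8, 8, 8]),
               DonorPoint("C", "doped", [0, 1, 1])]
        from evanomaly.density import ClusterAssignment
        a = ClusterAssignment(points=pts, params=OpticsParams(2, 1.0),
                              ordering=np.arange(6),
                              reachability=np.zeros(6),
                              core_distances=np.zeros(6),
                              labels=np.array([0, 0, 0, NOISE, NOISE, 0]),
                              selected_cluster_id=0)
        return a

    def test_both_and_either_rules(self):
        a = self._toy_assignment()
        comp = ComparisonSpec("ctrl", "doped")
        assert filter_to_cluster(a, comp, "both") == {"A"}
        assert filter_to_cluster(a, comp, "either") == {"A", "B", "C"}

    def test_count_equals_set_intersection_oracle(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.3, (60, 3)), rng.normal(6, 0.3, (60, 3))])
        half = len(X) // 2
        pts = (pts_from(X[:half], "ctrl") + pts_from(X[half:], "doped"))
        a = optics_order(pts, OpticsParams(10, 1.0))
        extract_clusters(a, 1.0)
        a.selected_cluster_id = 0
        comp = ComparisonSpec("ctrl", "doped")
        got = filter_to_cluster(a, comp, "both")
        per_cond = {"ctrl": set(), "doped": set()}
        for p, l in zip(a.points, a.labels):
            if l == 0:
                per_cond[p.condition].add(p.accession)
        assert got == per_cond["ctrl"] & per_cond["doped"]


def test_suggest_eps_separates_clouds_not_edges():
    X = two_blobs(n=80, sep=12.0, seed=9)
    pts = pts_from(X)
    eps = suggest_eps(pts, min_pts=20)
    a = optics_order(pts, OpticsParams(20, eps))
    extract_clusters(a, eps)
    sizes = a.cluster_sizes()
    assert sorted(sizes.values()) == [80, 80]
    assert int((a.labels == NOISE).sum()) == 0
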