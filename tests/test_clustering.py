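import math

import numpy as np
import pytest

from goldio.clustering import (
    ClusterConfig,
    cluster_area,
    cluster_particles,
    summarize_clusters,
)
from goldio.data_model import ParticlePointSet
from goldio.errors import InsufficientPointsError


def bfs_components(xy, threshold):
    """Connected components of the <=threshold graph by explicit BFS (oracle)."""
    n = len(xy)
    labels = [-1] * n
    next_label = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        queue = [start]
        labels[start] = next_label
        while queue:
            i = queue.pop()
            for j in range(n):
                if labels[j] == -1 and math.hypot(
                    xy[j][0] - xy[i][0], xy[j][1] - xy[i][1]
                ) <= threshold:
                    labels[j] = next_label
                    queue.append(j)
        next_label += 1
    return labels


def partitions_equal(a, b):
    return {frozenset(np.flatnonzero(np.array(a) == l)) for l in set(a)} == {
        frozenset(np.flatnonzero(np.array(b) == l)) for l in set(b)
    }


class TestClusterParticles:
    def test_chain_transitivity(self):
        pts = ParticlePointSet.from_points([(0, 0), (20, 0), (40, 0)])
        a = cluster_particles(pts, ClusterConfig(threshold=27, compute_area=False))
        assert a.n_clusters == 1
        assert a.clusters[0].size == 3

    def test_distant_points_are_singletons(self):
        pts = ParticlePointSet.from_points([(0, 0), (100, 100)])
        a = cluster_particles(pts, ClusterConfig(threshold=27, compute_area=False))
        assert a.n_clusters == 2
        assert all(c.size == 1 for c in a.clusters)

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientPointsError):
            cluster_particles(ParticlePointSet(xy=np.empty((0, 2))))

    def test_matches_bfs_oracle_on_random_points(self, rng):
        xy = rng.uniform(0, 400, size=(300, 2))
        a = cluster_particles(
            ParticlePointSet(xy=xy), ClusterConfig(threshold=27, compute_area=False)
        )
        assert partitions_equal(a.labels, bfs_components(xy, 27))

    def test_cluster_ids_ordered_by_lowest_member_id(self, rng):
        xy = rng.uniform(0, 600, size=(120, 2))
        a = cluster_particles(
            ParticlePointSet(xy=xy), ClusterConfig(threshold=30, compute_area=False)
        )
        first_member = [c.member_indices.min() for c in a.clusters]
        assert first_member == sorted(first_member)
        assert [c.cluster_id for c in a.clusters] == list(range(a.n_clusters))

    def test_monotonicity_in_threshold(self, rng):
        xy = rng.uniform(0, 300, size=(150, 2))
        pts = ParticlePointSet(xy=xy)
        counts = [
            cluster_particles(pts, ClusterConfig(threshold=t, compute_area=False)).n_clusters
            for t in (5, 10, 20, 40, 80)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_limits(self, rng):
        xy = rng.uniform(0, 300, size=(50, 2))
        pts = ParticlePointSet(xy=xy)
        tiny = cluster_particles(pts, ClusterConfig(threshold=1e-9, compute_area=False))
        assert tiny.n_clusters == 50  # no duplicates at random floats
        diam = np.hypot(*(xy.max(0) - xy.min(0))) + 1
        huge = cluster_particles(pts, ClusterConfig(threshold=diam, compute_area=False))
        assert huge.n_clusters == 1

    def test_partition_conservation(self, rng):
        xy = rng.uniform(0, 300, size=(80, 2))
        a = cluster_particles(
            ParticlePointSet(xy=xy), ClusterConfig(threshold=27, compute_area=False)
        )
        assert sum(c.size for c in a.clusters) == 80
        assert np.all(np.bincount(a.labels) >= 1)


class TestClusterArea:
    def test_single_disk_analytic(self):
        assert cluster_area([(5, 5)], 27) == pytest.approx(math.pi * 27**2, rel=5e-3)

    def test_two_disk_lens_closed_form(self):
        r = d = 27.0
        lens = 2 * r**2 * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(
            4 * r**2 - d**2
        )
        expected = 2 * math.pi * r**2 - lens  # = 3684.96 px²
        got = cluster_area([(0, 0), (d, 0)], r)
        assert got == pytest.approx(expected, rel=5e-3)

    def test_disjoint_disks_add(self):
        got = cluster_area([(0, 0), (500, 0)], 27)
        assert got == pytest.approx(2 * math.pi * 27**2, rel=5e-3)

    def test_matches_monte_carlo_oracle(self, rng):
        r = 27.0
        pts = rng.uniform(0, 60, size=(5, 2))
        got = cluster_area(pts, r)
        lo, hi = pts.min(0) - r, pts.max(0) + r
        samples = rng.uniform(lo, hi, size=(1_000_000, 2))
        inside = np.zeros(len(samples), bool)
        for p in pts:
            inside |= ((samples - p) ** 2).sum(1) <= r * r
        mc = inside.mean() * np.prod(hi - lo)
        assert got == pytest.approx(mc, rel=5e-3)

    def test_matches_shapely_union(self, rng):
        from shapely.geometry import Point
        from shapely.ops import unary_union

        pts = rng.uniform(0, 80, size=(8, 2))
        got = cluster_area(pts, 20.0)
        exact = unary_union([Point(*p).buffer(20.0, quad_segs=256) for p in pts]).area
        assert got == pytest.approx(exact, rel=5e-3)

    def test_area_bounds(self, rng):
        r = 27.0
        tol = 1.005
        for size in (1, 2, 4, 8):
            pts = rng.uniform(0, 100, size=(size, 2))
            area = cluster_area(pts, r)
            assert math.pi * r**2 / tol <= area <= size * math.pi * r**2 * tol


class TestSummarizeClusters:
    def test_two_singletons(self):
        pts = ParticlePointSet.from_points([(0, 0), (500, 500)])
        s = summarize_clusters(cluster_particles(pts, ClusterConfig(threshold=27)))
        assert s["mean_size"] == 1.0
        assert s["mean_area"] == pytest.approx(math.pi * 27**2, rel=5e-3)

    def test_chain_cluster_density(self):
        pts = ParticlePointSet.from_points([(0, 0), (20, 0), (40, 0)])
        a = cluster_particles(pts, ClusterConfig(threshold=27))
        c = a.clusters[0]
        assert c.density == pytest.approx(3 / c.area)
        assert c.area == pytest.approx(cluster_area(pts.xy, 27), rel=1e-9)

    def test_grand_means_are_arithmetic_means(self, rng):
        xy = rng.uniform(0, 400, size=(60, 2))
        a = cluster_particles(ParticlePointSet(xy=xy), ClusterConfig(threshold=27))
        s = summarize_clusters(a)
        assert s["mean_size"] == pytest.approx(
            np.mean([c.size for c in a.clusters])
        )
        assert s["mean_density"] == pytest.approx(
            np.mean([c.density for c in a.clusters])
        )
        assert len(s["membership"]) == 60
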