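"""Cluster separation: nearest-neighbor distances between cluster centroids.

A cluster's centroid is the arithmetic mean of its members' coordinates. Only
clusters meeting a minimum size (default 2 — singletons are not "clusters"
for separation purposes, though the criterion is adjustable) enter the
analysis, which is the same NND computation applied to centroids. No border
correction is applied at the ROI edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .clustering import ClusterAssignment
from .data_model import ParticlePointSet, Point2D
from .distances import NndRecord, particle_nnd
from .errors import InsufficientClustersError


@dataclass
class SeparationConfig:
    min_cluster_size: int = 2

    def __post_init__(self):
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


def cluster_centroid(members: Sequence[Sequence[float]]) -> Point2D:
    """Mean of the members' X values and mean of their Y values."""
    xy = np.atleast_2d(np.asarray(members, dtype=float))
    if len(xy) == 0:
        raise ValueError("centroid of an empty cluster is undefined")
    return Point2D(float(xy[:, 0].mean()), float(xy[:, 1].mean()))


def cluster_separation(
    assignment: ClusterAssignment, cfg: SeparationConfig = SeparationConfig()
) -> List[NndRecord]:
    """Centroid-to-centroid NND over qualifying clusters.

    Records carry cluster ids in place of particle ids. Raises
    :class:`InsufficientClustersError` with fewer than two qualifying
    clusters (reported, not fatal to other workflows).
    """
    qualifying = [c for c in assignment.clusters if c.size >= cfg.min_cluster_size]
    if len(qualifying) < 2:
        raise InsufficientClustersError(
            f"separation needs >=2 clusters of size >= {cfg.min_cluster_size}, "
            f"got {len(qualifying)}"
        )
    centroids = ParticlePointSet(
        xy=np.array([[c.centroid.x, c.centroid.y] for c in qualifying]),
        ids=np.array([c.cluster_id for c in qualifying]),
        label="centroid",
    )
    return particle_nnd(centroids)


def separation_rows(records: List[NndRecord]) -> List[dict]:
    """Rows for the separation result CSV (centroid, nearest cluster, distance)."""
    return [
        {
            "cluster_id": r.id,
            "centroid_x": r.point.x,
            "centroid_y": r.point.y,
            "neighbor_cluster_id": r.neighbor_id,
            "distance": r.distance,
        }
        for r in records
    ]
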