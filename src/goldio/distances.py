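"""Euclidean nearest-neighbor computations.

Two flavours: particle↔particle NND (each particle against every other
particle of the same set) and particle→landmark NND ("Gold Star": each
particle against the landmark set only). Distances are plain Euclidean —
they do not follow the membrane inside the mask, so curved ROIs understate
the true within-membrane distance; neighbor segments are allowed to cross
outside the ROI border.

The search is an exhaustive vectorised all-pairs minimum: ROIs carry
thousands of particles at most, where O(n²) is both fast and trivially
correct. Ties break toward the lowest id. Duplicate coordinates are legal
and yield NND 0 (annotation tools can emit duplicates; filtering is a user
decision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import ParticlePointSet, Point2D
from .errors import InsufficientPointsError, MissingLandmarkError


@dataclass
class NndRecord:
    """One particle, its nearest neighbor, and the distance in px."""

    id: int
    point: Point2D
    neighbor_id: int
    neighbor_point: Point2D
    distance: float

    def as_row(self) -> dict:
        return {
            "id": self.id,
            "x": self.point.x,
            "y": self.point.y,
            "neighbor_id": self.neighbor_id,
            "neighbor_x": self.neighbor_point.x,
            "neighbor_y": self.neighbor_point.y,
            "distance": self.distance,
        }


def euclidean(p1: Sequence[float], p2: Sequence[float]) -> float:
    """d(p1, p2) = sqrt((x2-x1)² + (y2-y1)²)."""
    return math.hypot(p2[0] - p1[0], p2[1] - p1[1])


def particle_nnd(points: ParticlePointSet) -> List[NndRecord]:
    """Nearest-neighbor distance of every particle to any *other* particle.

    Requires at least two points. The neighbor is the distinct point with the
    minimum Euclidean distance; among equidistant candidates the one with the
    lowest id wins.
    """
    n = len(points)
    if n < 2:
        raise InsufficientPointsError(
            f"particle NND needs at least 2 points, got {n}"
        )
    d = cdist(points.xy, points.xy)
    np.fill_diagonal(d, np.inf)
    # argmin returns the first (lowest-index) minimum; input order == id order
    nn = np.argmin(d, axis=1)
    return [
        NndRecord(
            id=int(points.ids[i]),
            point=points.point(i),
            neighbor_id=int(points.ids[j]),
            neighbor_point=points.point(j),
            distance=float(d[i, j]),
        )
        for i, j in enumerate(nn)
    ]


def landmark_nnd(
    points: ParticlePointSet, landmarks: ParticlePointSet
) -> List[NndRecord]:
    """Distance from each particle to its closest landmark (Gold Star).

    The neighbor is drawn from the landmark set only; a particle sitting
    exactly on a landmark has distance 0. Ties break toward the lowest
    landmark id.
    """
    if len(landmarks) == 0:
        raise MissingLandmarkError("landmark NND requires at least one landmark")
    if len(points) == 0:
        raise InsufficientPointsError("landmark NND requires at least one particle")
    d = cdist(points.xy, landmarks.xy)
    nn = np.argmin(d, axis=1)
    return [
        NndRecord(
            id=int(points.ids[i]),
            point=points.point(i),
            neighbor_id=int(landmarks.ids[j]),
            neighbor_point=landmarks.point(j),
            distance=float(d[i, j]),
        )
        for i, j in enumerate(nn)
    ]


def nnd_distances(records: List[NndRecord]) -> np.ndarray:
    return np.array([r.distance for r in records])
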