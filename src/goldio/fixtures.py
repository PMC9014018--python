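"""Programmatic generation of test inputs with known ground truth.

Every workflow is testable with no external data: this module fabricates ROI
masks (rectangle, ellipse, or a sinuous dendrite-like corridor with circular
spine stubs), particle layouts (uniform, planted clusters with known
membership, or Gaussian landmark bias) and landmark points, and writes them
out as an input folder honoring the keyword naming scheme ("image", "mask",
"gold", "landmark") plus a ground-truth JSON sidecar. Generation is
deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import tifffile

from .data_model import ParticlePointSet, RoiMask, contains_many
from .io_formats import InputBundle, write_points_csv


@dataclass
class FixtureSpec:
    """mask_shape: rectangle | ellipse | dendrite; layout: uniform |
    planted_clusters | landmark_bias."""

    mask_shape: str = "rectangle"
    layout: str = "uniform"
    shape: Tuple[int, int] = (512, 512)  # rows, cols
    n_particles: int = 100
    n_landmarks: int = 0
    # planted-cluster parameters
    n_clusters: int = 5
    cluster_size: int = 8
    cluster_spread: float = 10.0  # max radius of intra-cluster scatter
    min_cluster_gap: float = 200.0  # min distance between cluster centers
    # landmark-bias parameters
    bias_sigma: float = 30.0
    seed: int = 0


def make_mask(spec: FixtureSpec) -> RoiMask:
    rows, cols = spec.shape
    if spec.mask_shape == "rectangle":
        grid = np.ones((rows, cols), dtype=bool)
    elif spec.mask_shape == "ellipse":
        r, c = np.mgrid[0:rows, 0:cols]
        cy, cx = (rows - 1) / 2, (cols - 1) / 2
        grid = ((r - cy) / (rows / 2)) ** 2 + ((c - cx) / (cols / 2)) ** 2 <= 1.0
    elif spec.mask_shape == "dendrite":
        grid = _dendrite_mask(rows, cols, spec.seed)
    else:
        raise ValueError(f"unknown mask_shape {spec.mask_shape!r}")
    return RoiMask(grid=grid)


def _dendrite_mask(rows: int, cols: int, seed: int) -> np.ndarray:
    """A sinuous thick corridor with circular spine stubs branching off."""
    rng = np.random.default_rng(seed)
    r, c = np.mgrid[0:rows, 0:cols]
    grid = np.zeros((rows, cols), dtype=bool)
    # sinuous center line across the full width
    xs = np.arange(cols)
    amp = rows * 0.2
    center = rows / 2 + amp * np.sin(2 * np.pi * xs / cols * 1.5)
    half_width = max(6.0, rows * 0.08)
    grid |= np.abs(r - center[None, :]) <= half_width
    # spine stubs: small disks tangent to the corridor
    stub_r = half_width * 0.8
    for x in np.linspace(cols * 0.15, cols * 0.85, 4):
        x = int(x)
        side = 1 if rng.random() < 0.5 else -1
        cy = center[x] + side * (half_width + stub_r * 0.8)
        grid |= (r - cy) ** 2 + (c - x) ** 2 <= stub_r**2
    return grid


@dataclass
class FixtureGroundTruth:
    cluster_centers: Optional[np.ndarray] = None
    cluster_labels: Optional[np.ndarray] = None  # planted membership per particle
    layout: str = "uniform"
    bias_sigma: Optional[float] = None

    def as_json(self) -> dict:
        out = {"layout": self.layout}
        if self.cluster_centers is not None:
            out["cluster_centers"] = self.cluster_centers.tolist()
        if self.cluster_labels is not None:
            out["cluster_labels"] = self.cluster_labels.tolist()
        if self.bias_sigma is not None:
            out["bias_sigma"] = self.bias_sigma
        return out


def make_points(
    spec: FixtureSpec, mask: RoiMask, landmarks: Optional[ParticlePointSet] = None
) -> Tuple[ParticlePointSet, FixtureGroundTruth]:
    """Generate particles per the requested layout; all inside the mask."""
    rng = np.random.default_rng(spec.seed + 1)
    if spec.layout == "uniform":
        xy = _uniform_in_mask(mask, spec.n_particles, rng)
        return ParticlePointSet(xy=xy), FixtureGroundTruth(layout="uniform")
    if spec.layout == "planted_clusters":
        return _planted_clusters(spec, mask, rng)
    if spec.layout == "landmark_bias":
        if landmarks is None or len(landmarks) == 0:
            raise ValueError("landmark_bias layout requires landmarks")
        xy = _biased_points(mask, landmarks, spec.n_particles, spec.bias_sigma, rng)
        gt = FixtureGroundTruth(layout="landmark_bias", bias_sigma=spec.bias_sigma)
        return ParticlePointSet(xy=xy), gt
    raise ValueError(f"unknown layout {spec.layout!r}")


def _uniform_in_mask(mask: RoiMask, n: int, rng) -> np.ndarray:
    interior = mask.interior_coords()
    idx = rng.integers(0, len(interior), size=n)
    # sub-pixel jitter inside the chosen pixel keeps coordinates fractional
    return interior[idx] + rng.uniform(-0.5, 0.5, size=(n, 2))


def _planted_clusters(spec: FixtureSpec, mask: RoiMask, rng):
    """Tight particle groups around well-separated centers.

    Centers are ≥ min_cluster_gap apart and ≥ (spread + gap margin) from the
    mask border, so clustering at any threshold in
    (2·spread, gap − 2·spread) recovers the planted partition exactly.
    """
    interior = mask.interior_coords()
    margin = spec.cluster_spread + 2.0
    centers: List[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.n_clusters:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError(
                "could not place cluster centers; reduce n_clusters or gap"
            )
        cand = interior[rng.integers(0, len(interior))]
        if centers and np.min(
            np.hypot(*(np.array(centers) - cand).T)
        ) < spec.min_cluster_gap:
            continue
        # keep the whole scatter disk inside the mask
        disk = cand + _disk_offsets(margin)
        if not contains_many(mask, disk).all():
            continue
        centers.append(cand)
    centers = np.array(centers, dtype=float)

    pts, labels = [], []
    for k, ctr in enumerate(centers):
        rr = spec.cluster_spread * np.sqrt(rng.uniform(0, 1, spec.cluster_size))
        th = rng.uniform(0, 2 * np.pi, spec.cluster_size)
        pts.append(ctr + np.column_stack([rr * np.cos(th), rr * np.sin(th)]))
        labels.extend([k] * spec.cluster_size)
    xy = np.vstack(pts)
    gt = FixtureGroundTruth(
        cluster_centers=centers,
        cluster_labels=np.array(labels),
        layout="planted_clusters",
    )
    return ParticlePointSet(xy=xy), gt


def _disk_offsets(radius: float, n: int = 16) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th)])


def _biased_points(mask, landmarks, n, sigma, rng) -> np.ndarray:
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = 2 * (n - len(pts)) + 8
        anchors = landmarks.xy[rng.integers(0, len(landmarks), size=m)]
        cand = anchors + rng.normal(0.0, sigma, size=(m, 2))
        pts = np.vstack([pts, cand[contains_many(mask, cand)]])
    return pts[:n]


def make_landmarks(spec: FixtureSpec, mask: RoiMask) -> ParticlePointSet:
    rng = np.random.default_rng(spec.seed + 2)
    xy = _uniform_in_mask(mask, spec.n_landmarks, rng)
    return ParticlePointSet(xy=xy, label="landmark")


def make_fixture(spec: FixtureSpec, folder) -> Tuple[InputBundle, FixtureGroundTruth]:
    """Write a ready-to-run input folder plus ground-truth sidecar.

    Emits ``fixture_mask.tif``, ``fixture_gold.csv``, optionally
    ``fixture_landmark.csv`` and a synthetic ``fixture_image.tif`` (the mask
    rendered as grayscale — a stand-in for a replica image, since only masks
    and coordinates matter for computation), and ``ground_truth.json``.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    mask = make_mask(spec)
    landmarks = make_landmarks(spec, mask) if spec.n_landmarks > 0 else None
    points, gt = make_points(spec, mask, landmarks)

    mask_path = folder / "fixture_mask.tif"
    tifffile.imwrite(mask_path, mask.grid.astype(np.uint8) * 255)
    image_path = folder / "fixture_image.tif"
    tifffile.imwrite(image_path, (mask.grid.astype(np.uint8) * 120 + 40))
    gold_path = folder / "fixture_gold.csv"
    write_points_csv(points, gold_path)
    landmark_path = None
    if landmarks is not None:
        landmark_path = folder / "fixture_landmark.csv"
        write_points_csv(landmarks, landmark_path)
    with open(folder / "ground_truth.json", "w") as fh:
        json.dump(gt.as_json(), fh, indent=2)
    bundle = InputBundle(
        mask_path=mask_path,
        gold_csv_path=gold_path,
        image_path=image_path,
        landmark_csv_path=landmark_path,
    )
    return bundle, gt
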