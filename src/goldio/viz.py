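"""Graphical outputs: point/segment overlays and NND histograms.

Overlays are rendered directly onto the image (or mask) raster so that a
pixel in the output corresponds to a pixel of the input grid; the real
distribution draws in a green/blue family and the random reference in a
yellow/orange family by default, both overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data_model import RoiMask
from .errors import ConfigError

#: default palettes (RGB, 0-255): real = green/blue family, random = yellow/orange
REAL_PALETTE = {"points": (0, 200, 80), "lines": (40, 120, 255)}
RANDOM_PALETTE = {"points": (250, 210, 0), "lines": (255, 140, 0)}


@dataclass
class OverlayLayer:
    """Points and/or line segments to draw in one palette."""

    points: Optional[np.ndarray] = None  # (n, 2) x, y
    segments: Optional[np.ndarray] = None  # (m, 2, 2) [[x1,y1],[x2,y2]]
    palette: dict = field(default_factory=lambda: dict(REAL_PALETTE))
    point_radius: int = 3


def _to_rgb(base: np.ndarray) -> np.ndarray:
    if base.ndim == 2:
        arr = base.astype(float)
        if arr.max() > 0:
            arr = arr / arr.max() * 255
        return np.stack([arr] * 3, axis=-1).astype(np.uint8)
    return base[..., :3].astype(np.uint8)


def _draw_disk(img: np.ndarray, x: float, y: float, radius: int, color) -> None:
    h, w = img.shape[:2]
    r0 = max(0, int(y) - radius)
    r1 = min(h, int(y) + radius + 1)
    c0 = max(0, int(x) - radius)
    c1 = min(w, int(x) + radius + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    sel = (rr - y) ** 2 + (cc - x) ** 2 <= radius**2
    img[r0:r1, c0:c1][sel] = color


def _draw_segment(img: np.ndarray, p1, p2, color) -> None:
    length = max(1, int(np.hypot(p2[0] - p1[0], p2[1] - p1[1]) * 2))
    ts = np.linspace(0.0, 1.0, length + 1)
    xs = np.rint(p1[0] + ts * (p2[0] - p1[0])).astype(int)
    ys = np.rint(p1[1] + ts * (p2[1] - p1[1])).astype(int)
    h, w = img.shape[:2]
    ok = (xs >= 0) & (ys >= 0) & (xs < w) & (ys < h)
    img[ys[ok], xs[ok]] = color


def render_overlay(
    base: np.ndarray | RoiMask,
    layers: Sequence[OverlayLayer],
    out_path=None,
    mask: Optional[RoiMask] = None,
) -> np.ndarray:
    """Rasterize layers onto the base image; optionally save as PNG.

    ``mask``, when given, must share the base's pixel grid (config error
    otherwise). An empty layer list returns the base unchanged (as RGB).
    """
    if isinstance(base, RoiMask):
        base = base.grid.astype(np.uint8) * 255
    img = _to_rgb(np.asarray(base)).copy()
    if mask is not None and mask.grid.shape != img.shape[:2]:
        raise ConfigError(
            f"mask shape {mask.grid.shape} does not match image {img.shape[:2]}"
        )
    for layer in layers:
        if layer.segments is not None:
            for seg in np.asarray(layer.segments, dtype=float):
                _draw_segment(img, seg[0], seg[1], layer.palette["lines"])
        if layer.points is not None:
            for x, y in np.atleast_2d(np.asarray(layer.points, dtype=float)):
                _draw_disk(img, x, y, layer.point_radius, layer.palette["points"])
    if out_path is not None:
        plt.imsave(str(out_path), img)
    return img


def nnd_histogram(
    real: Optional[np.ndarray],
    random: Optional[np.ndarray],
    out_path,
    bin_width: float = 10.0,
    unit: str = "px",
    title: str = "Nearest neighbor distance",
) -> None:
    """Histogram of NNDs, real vs random, with adjustable bin width."""
    series = [(real, "real", "#2878c8"), (random, "random", "#f08c00")]
    upper = max(
        float(np.max(s)) for s, _, _ in series if s is not None and len(s)
    )
    bins = np.arange(0, upper + 2 * bin_width, bin_width)
    fig, ax = plt.subplots(figsize=(6, 4))
    for data, label, color in series:
        if data is None or not len(data):
            continue
        ax.hist(data, bins=bins, alpha=0.55, label=label, color=color)
    ax.set_xlabel(f"distance ({unit})")
    ax.set_ylabel("count")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(out_path), dpi=110)
    plt.close(fig)


def lcpi_plot(curves, out_path, unit: str = "px") -> None:
    """LCPI-vs-radius curves (with S.E.M. bars when available)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        if hasattr(curve, "sem"):
            ax.errorbar(curve.radii, curve.mean, yerr=curve.sem, label=label, capsize=2)
        else:
            ax.plot(curve.radii, curve.lcpi, marker="o", label=label)
    ax.axhline(1.0, ls=":", color="gray")
    ax.set_xlabel(f"ripple radius ({unit})")
    ax.set_ylabel("LCPI")
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(out_path), dpi=110)
    plt.close(fig)
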