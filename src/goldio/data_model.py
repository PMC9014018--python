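"""Core domain types shared by every workflow.

Coordinate convention
---------------------
``x`` is the column index (increasing rightward) and ``y`` the row index
(increasing downward), origin at the top-left pixel — the convention used by
FIJI/Photoshop-style annotation exports, whose CSV ``"X"``/``"Y"`` columns map
directly onto :class:`Point2D`. Coordinates are 0-based and may be fractional:
all distance math runs on the raw floating-point values, and rounding to the
pixel grid happens only for mask membership and area counting.

All internal lengths are in pixels; :class:`ScaleSpec` converts to physical
units at output time only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import InvalidMaskError


class Point2D(NamedTuple):
    """A sub-pixel 2-D location: x = column, y = row."""

    x: float
    y: float


@dataclass
class ParticlePointSet:
    """An ordered set of 2-D points with stable integer ids.

    Houses gold particles, landmarks and random references alike; ``label``
    records which. Ids default to 0..n-1 in input-row order and stay stable
    across every output of one run.
    """

    xy: np.ndarray  # (n, 2) float64, columns (x, y)
    ids: np.ndarray = None  # (n,) int
    label: str = "gold"

    def __post_init__(self):
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.size == 0:
            self.xy = self.xy.reshape(0, 2)
        if self.xy.shape[1] != 2:
            raise ValueError(f"expected (n, 2) coordinates, got {self.xy.shape}")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        if self.ids is None:
            self.ids = np.arange(len(self.xy))
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if len(self.ids) != len(self.xy):
                raise ValueError("ids and coordinates differ in length")
            if len(np.unique(self.ids)) != len(self.ids):
                raise ValueError("ids must be unique")

    @classmethod
    def from_points(
        cls, points: Iterable[Sequence[float]], label: str = "gold"
    ) -> "ParticlePointSet":
        pts = list(points)
        xy = np.asarray(pts, dtype=float).reshape(len(pts), 2)
        return cls(xy=xy, label=label)

    def __len__(self) -> int:
        return len(self.xy)

    def __iter__(self):
        for x, y in self.xy:
            yield Point2D(x, y)

    def point(self, index: int) -> Point2D:
        return Point2D(*self.xy[index])

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]


@dataclass
class RoiMask:
    """Binary raster demarcating the analyzable membrane region.

    Any nonzero source pixel is "inside"; there is no anti-aliased partial
    membership (masks are hand-painted binary images). Each true pixel
    contributes 1 px² of area.
    """

    grid: np.ndarray  # (rows, cols) bool

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise InvalidMaskError(f"mask must be 2-D, got shape {self.grid.shape}")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def interior_coords(self) -> np.ndarray:
        """(k, 2) array of (x, y) pixel-center coordinates of true pixels."""
        rows, cols = np.nonzero(self.grid)
        return np.column_stack([cols, rows]).astype(float)


def total_area(mask: RoiMask) -> int:
    """ROI area in px²: the count of true mask pixels.

    Raises :class:`InvalidMaskError` on an all-false mask — an empty ROI has
    no meaningful area fraction.
    """
    area = int(np.count_nonzero(mask.grid))
    if area == 0:
        raise InvalidMaskError("mask contains no true pixels")
    return area


def contains(mask: RoiMask, p: Sequence[float]) -> bool:
    """Whether point ``p`` falls on a true mask pixel.

    The sub-pixel point is snapped to the nearest pixel center
    (``round(y), round(x)``); points rounding outside the grid are outside.
    """
    x, y = float(p[0]), float(p[1])
    r, c = int(round(y)), int(round(x))
    nrows, ncols = mask.grid.shape
    if r < 0 or c < 0 or r >= nrows or c >= ncols:
        return False
    return bool(mask.grid[r, c])


def contains_many(mask: RoiMask, xy: np.ndarray) -> np.ndarray:
    """Vectorised :func:`contains` for an (n, 2) coordinate array."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if len(xy) == 0:
        return np.zeros(0, dtype=bool)
    c = np.rint(xy[:, 0]).astype(int)
    r = np.rint(xy[:, 1]).astype(int)
    nrows, ncols = mask.grid.shape
    inside = (r >= 0) & (c >= 0) & (r < nrows) & (c < ncols)
    out = np.zeros(len(xy), dtype=bool)
    out[inside] = mask.grid[r[inside], c[inside]]
    return out


_UNIT_ALIASES = {"um": "um", "μm": "um", "µm": "um", "nm": "nm", "px": "px"}


@dataclass(frozen=True)
class ScaleSpec:
    """Pixel → physical-unit conversion, applied at output time only.

    ``nm_per_pixel`` is the physical edge length of one pixel. Lengths scale
    linearly, areas by the square. The shipped calibration example is
    30 nm = 27 px (≈1.111 nm/px).
    """

    nm_per_pixel: float = 1.0
    output_unit: str = "px"

    def __post_init__(self):
        if not (self.nm_per_pixel > 0):
            raise ValueError("nm_per_pixel must be strictly positive")
        unit = _UNIT_ALIASES.get(self.output_unit)
        if unit is None:
            raise ValueError(
                f"output_unit must be one of px/nm/um, got {self.output_unit!r}"
            )
        object.__setattr__(self, "output_unit", unit)

    @property
    def length_factor(self) -> float:
        if self.output_unit == "px":
            return 1.0
        if self.output_unit == "nm":
            return self.nm_per_pixel
        return self.nm_per_pixel / 1000.0  # um

    @property
    def area_factor(self) -> float:
        return self.length_factor**2

    def length(self, value_px):
        """Convert a length (or array of lengths) from px to the output unit."""
        return np.asarray(value_px, dtype=float) * self.length_factor

    def area(self, value_px2):
        """Convert an area (or array of areas) from px² to the output unit²."""
        return np.asarray(value_px2, dtype=float) * self.area_factor

    def length_to_px(self, value_out):
        return np.asarray(value_out, dtype=float) / self.length_factor
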