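"""Pseudo-random reference distributions inside the ROI mask.

Every workflow compares the real particle configuration against a matched
random one: the same number of particles thrown uniformly over the mask, with
a minimum pairwise separation (default 5 px) so generated particles cannot
overlap the way physical gold particles cannot. The separation constraint
applies among the generated points only — the reference must be independent
of the real configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ParticlePointSet, RoiMask, total_area
from .errors import SaturationError


@dataclass
class RandomGenConfig:
    """Dart-throwing parameters.

    n defaults to the real particle count at the call site; min_separation is
    the center-to-center exclusion distance in px; max_attempts caps the
    consecutive rejections tolerated per point before declaring saturation.
    """

    n: int
    min_separation: float = 5.0
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def generate_random(mask: RoiMask, cfg: RandomGenConfig) -> ParticlePointSet:
    """Throw ``cfg.n`` uniform integer-coordinate darts into the mask.

    Proposals are uniform integer pixel coordinates over the mask bounding
    box; a proposal is rejected if its pixel is outside the mask or closer
    than ``min_separation`` to an already-placed point. Identical seed and
    inputs give identical output. Raises :class:`SaturationError` when
    ``max_attempts`` consecutive proposals fail for one point.
    """
    total_area(mask)  # validates non-empty mask
    if cfg.n == 0:
        return ParticlePointSet(xy=np.empty((0, 2)), label="random")

    rows, cols = np.nonzero(mask.grid)
    rmin, rmax = int(rows.min()), int(rows.max())
    cmin, cmax = int(cols.min()), int(cols.max())

    rng = np.random.Generator(np.random.MT19937(cfg.seed))
    placed = np.empty((cfg.n, 2), dtype=float)
    n_placed = 0
    min_sep_sq = cfg.min_separation**2
    while n_placed < cfg.n:
        for attempt in range(cfg.max_attempts):
            x = int(rng.integers(cmin, cmax + 1))
            y = int(rng.integers(rmin, rmax + 1))
            if not mask.grid[y, x]:
                continue
            if n_placed and (
                ((placed[:n_placed, 0] - x) ** 2 + (placed[:n_placed, 1] - y) ** 2).min()
                < min_sep_sq
            ):
                continue
            placed[n_placed] = (x, y)
            n_placed += 1
            break
        else:
            raise SaturationError(n_placed, cfg.n, cfg.max_attempts)
    return ParticlePointSet(xy=placed, label="random")
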