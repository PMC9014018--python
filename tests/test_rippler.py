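import math

import numpy as np
import pytest

from goldio.data_model import ParticlePointSet, RoiMask
from goldio.errors import InsufficientPointsError, MissingLandmarkError
from goldio.rippler import (
    RipplerConfig,
    lcpi_curve,
    particles_in_ripple,
    ripple_area,
)


def _landmarks(*pts):
    return ParticlePointSet.from_points(pts, label="landmark")


class TestRippleArea:
    def test_full_coverage_equals_roi_area(self):
        mask = RoiMask(np.ones((200, 200), bool))
        assert ripple_area(mask, _landmarks((100, 100)), 300) == 40000

    def test_disk_area_within_rasterization_tolerance(self):
        mask = RoiMask(np.ones((1000, 1000), bool))
        area = ripple_area(mask, _landmarks((500, 500)), 50)
        assert area == pytest.approx(math.pi * 50**2, rel=0.01)

    def test_distant_landmarks_add_overlapping_do_not(self):
        mask = RoiMask(np.ones((400, 400), bool))
        r = 40
        far = ripple_area(mask, _landmarks((100, 100), (300, 300)), r)
        one = ripple_area(mask, _landmarks((100, 100)), r)
        assert far == pytest.approx(2 * one, rel=0.01)
        near = ripple_area(mask, _landmarks((100, 100), (130, 100)), r)
        assert near < 2 * one

    def test_union_matches_monte_carlo_oracle(self, blob_mask, rng):
        lms = _landmarks((20, 25), (42, 40))
        r = 12.0
        area = ripple_area(blob_mask, lms, r)
        # MC over pixel-center lattice == exact pixel count; sample points
        samples = rng.uniform(0, 64, size=(200_000, 2))
        inroi = np.zeros(len(samples), bool)
        rr = np.rint(samples[:, 1]).astype(int)
        cc = np.rint(samples[:, 0]).astype(int)
        ok = (rr >= 0) & (cc >= 0) & (rr < 64) & (cc < 64)
        inroi[ok] = blob_mask.grid[rr[ok], cc[ok]]
        near = np.zeros(len(samples), bool)
        for lm in lms.xy:
            near |= ((samples - lm) ** 2).sum(1) <= r * r
        mc = (inroi & near).mean() * 64 * 64
        assert area == pytest.approx(mc, rel=0.05)

    def test_missing_landmarks_rejected(self, full_mask):
        empty = ParticlePointSet(xy=np.empty((0, 2)), label="landmark")
        with pytest.raises(MissingLandmarkError):
            ripple_area(full_mask, empty, 10)


class TestParticlesInRipple:
    def test_particle_at_landmark_counted(self):
        pts = ParticlePointSet.from_points([(50, 50)])
        assert particles_in_ripple(pts, _landmarks((50, 50)), 1) == 1

    def test_all_particles_beyond_radius(self):
        pts = ParticlePointSet.from_points([(500, 500), (600, 600)])
        assert particles_in_ripple(pts, _landmarks((0, 0)), 100) == 0

    def test_matches_brute_force_thresholding(self, rng):
        pts = rng.uniform(0, 500, size=(100, 2))
        lms = rng.uniform(0, 500, size=(5, 2))
        r = 80.0
        expect = sum(
            1
            for p in pts
            if min(math.hypot(*(p - lm)) for lm in lms) <= r
        )
        got = particles_in_ripple(
            ParticlePointSet(xy=pts), ParticlePointSet(xy=lms, label="landmark"), r
        )
        assert got == expect


class TestLcpiCurve:
    def test_full_coverage_final_bin_is_exactly_one(self, rng):
        mask = RoiMask(np.ones((200, 200), bool))
        pts = ParticlePointSet(xy=rng.uniform(0, 199, size=(40, 2)))
        curve = lcpi_curve(
            pts, _landmarks((100, 100)), mask,
            RipplerConfig(initial_radius=50, step=50, n_steps=5),  # last r=250 > diag/2
        )
        assert curve.area_fraction[-1] == 1.0
        assert curve.particle_fraction[-1] == 1.0
        assert curve.lcpi[-1] == 1.0  # exact, not approx
        assert curve.saturated[-1]

    def test_concentrated_particles_hand_computation(self):
        # 10% of the ROI in the first ripple, all particles inside it
        mask = RoiMask(np.ones((100, 100), bool))
        lm = _landmarks((50, 50))
        r0 = math.sqrt(10000 * 0.1 / math.pi)  # disk covering ~10% of ROI
        pts = ParticlePointSet(
            xy=np.full((10, 2), 50.0) + np.arange(10)[:, None] * 0.1
        )
        curve = lcpi_curve(pts, lm, mask, RipplerConfig(initial_radius=r0, step=100, n_steps=2))
        af = curve.area_fraction[0]
        assert af == pytest.approx(0.1, rel=0.02)
        assert curve.lcpi[0] == pytest.approx(1.0 / af, rel=1e-9)

    def test_cumulative_monotonicity(self, blob_mask, rng):
        interior = blob_mask.interior_coords()
        pts = ParticlePointSet(xy=interior[rng.integers(0, len(interior), 50)])
        curve = lcpi_curve(
            pts, _landmarks((25, 22)), blob_mask,
            RipplerConfig(initial_radius=5, step=8, n_steps=8),
        )
        assert np.all(np.diff(curve.particle_fraction) >= 0)
        assert np.all(np.diff(curve.area_fraction) >= 0)

    def test_zero_area_bin_reported_missing(self):
        # landmark far outside the ROI: early ripples never touch the mask
        grid = np.zeros((100, 100), bool)
        grid[:10, :10] = True
        mask = RoiMask(grid)
        pts = ParticlePointSet.from_points([(5, 5)])
        curve = lcpi_curve(
            pts, _landmarks((90, 90)), mask,
            RipplerConfig(initial_radius=10, step=10, n_steps=3),
        )
        assert np.isnan(curve.lcpi[0])

    def test_empty_particles_rejected(self, full_mask):
        empty = ParticlePointSet(xy=np.empty((0, 2)))
        with pytest.raises(InsufficientPointsError):
            lcpi_curve(empty, _landmarks((50, 50)), full_mask)

    def test_rows_schema_and_percent_scale(self, full_mask, rng):
        pts = ParticlePointSet(xy=rng.uniform(0, 99, size=(30, 2)))
        curve = lcpi_curve(pts, _landmarks((50, 50)), full_mask,
                           RipplerConfig(initial_radius=30, step=30, n_steps=3))
        rows = curve.rows()
        assert set(rows[0]) == {"radius", "particle_pct", "area_pct", "lcpi", "n_total"}
        assert rows[0]["particle_pct"] == pytest.approx(
            100 * curve.particle_fraction[0]
        )
        assert all(row["n_total"] == 30 for row in rows)
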