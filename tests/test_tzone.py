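"""Treatment-zone boundary detection, circle fitting and decentration reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from okzone import (
    BaselineParams,
    DifferenceMap,
    FittedCircle,
    NoTreatmentZoneError,
    TreatmentGroundTruth,
    TZBoundary,
    analyze_eye,
    apply_orthok_treatment,
    categorize_decentration,
    compute_decentration,
    detect_tz_boundary,
    fit_circle,
    generate_baseline_surface,
    quadrant_name,
)


@pytest.fixture(scope="module")
def baseline(small_grid):
    p = BaselineParams(noise_sd=0.0)
    return generate_baseline_surface(p, small_grid, seed=0)


class TestDetectBoundary:
    def test_centred_zone_crossings_at_tz_radius(self, baseline):
        truth = TreatmentGroundTruth(0.0, 0.0, tz_radius=1.6)
        post = apply_orthok_treatment(baseline, truth)
        res = analyze_eye(baseline, post)
        b = res.boundary
        assert b.meridians_without_crossing == 0
        radii = np.hypot(b.points[:, 0], b.points[:, 1])
        assert np.all(np.abs(radii - 1.6) < 0.05)

    def test_identical_maps_have_no_zone(self, baseline):
        res = analyze_eye(baseline, baseline.copy())
        assert res.decentration is None
        assert "flattening" in res.no_zone_reason

    def test_decentred_zone_crossing_radii_vary_with_meridian(self, baseline):
        truth = TreatmentGroundTruth(0.5, 0.0, tz_radius=1.8)
        post = apply_orthok_treatment(baseline, truth)
        res = analyze_eye(baseline, post)
        pts = res.boundary.points
        radii = np.hypot(pts[:, 0], pts[:, 1])
        ang = np.arctan2(pts[:, 1], pts[:, 0])
        # crossing radius is max toward the shift (+x) and min away from it
        toward = radii[np.abs(ang) < 0.3]
        away = radii[np.abs(np.abs(ang) - np.pi) < 0.3]
        assert toward.mean() > 2.1 and away.mean() < 1.5

    def test_requires_polar_map(self):
        from okzone.grids import default_cartesian_grid

        g = default_cartesian_grid(n=21)
        d = DifferenceMap(g, np.zeros(g.shape), np.zeros(g.shape, dtype=bool))
        with pytest.raises(ValueError, match="polar"):
            detect_tz_boundary(d)


class TestFitCircle:
    @staticmethod
    def _circle_points(cx, cy, r, n=36, noise=0.0, rng=None):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        if noise:
            pts += rng.normal(0, noise, pts.shape)
        return TZBoundary(pts, 0)

    def test_exact_points_recovered_to_machine_precision(self):
        c = fit_circle(self._circle_points(0.5, -0.3, 1.8))
        assert c.centre_x == pytest.approx(0.5, abs=1e-9)
        assert c.centre_y == pytest.approx(-0.3, abs=1e-9)
        assert c.radius == pytest.approx(1.8, abs=1e-9)
        assert c.fit_rms < 1e-9

    def test_noisy_points_centre_error_monte_carlo(self):
        rng = np.random.default_rng(12)
        errs = []
        for _ in range(100):
            c = fit_circle(self._circle_points(0.5, -0.3, 1.8, noise=0.05, rng=rng))
            errs.append(np.hypot(c.centre_x - 0.5, c.centre_y + 0.3))
        assert np.mean(errs) < 0.05
        assert np.percentile(errs, 95) < 0.05  # sd/sqrt(n) scaling at n=36

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.linspace(0, 1, 8), np.linspace(0, 2, 8)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            fit_circle(TZBoundary(pts, 0))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            fit_circle(self._circle_points(0, 0, 1, n=5))


class TestDecentrationReporting:
    def test_od_temporal_inferior_angle_is_quadrant_3(self):
        # display frame for OD: temporal-inferior is x<0, y<0 (angle ~205.7 deg)
        ang = np.deg2rad(205.7)
        c = FittedCircle(0.6 * np.cos(ang), 0.6 * np.sin(ang), 1.8, 0.0)
        d = compute_decentration(c, "OD")
        assert d.quadrant == 3
        assert d.direction_name == "temporal-inferior"
        assert d.angle == pytest.approx(205.7, abs=1e-9)
        assert d.category == "moderate"

    def test_perfectly_centred_convention(self):
        d = compute_decentration(FittedCircle(0.0, 0.0, 1.8, 0.0), "OD")
        assert d.radius == 0.0
        assert d.category == "small"
        assert d.quadrant == 1
        assert d.on_boundary

    def test_os_mirror_same_direction_different_index(self):
        # mirror of an OD temporal-inferior centre: display x negates
        ang = np.deg2rad(205.7)
        od = compute_decentration(FittedCircle(0.6 * np.cos(ang), 0.6 * np.sin(ang), 1.8, 0.0), "OD")
        os_ = compute_decentration(
            FittedCircle(-0.6 * np.cos(ang), 0.6 * np.sin(ang), 1.8, 0.0), "OS"
        )
        assert od.direction_name == os_.direction_name == "temporal-inferior"
        assert (od.quadrant, os_.quadrant) == (3, 4)
        assert os_.angle == pytest.approx(od.angle, abs=1e-9)

    def test_axis_ties_take_lower_numbered_quarter(self):
        assert compute_decentration(FittedCircle(0.7, 0.0, 1.8, 0.0), "OD").quadrant == 1
        assert compute_decentration(FittedCircle(0.0, 0.7, 1.8, 0.0), "OD").quadrant == 1
        assert compute_decentration(FittedCircle(-0.7, 0.0, 1.8, 0.0), "OD").quadrant == 2
        assert compute_decentration(FittedCircle(0.0, -0.7, 1.8, 0.0), "OD").quadrant == 3

    def test_quarter_tables(self):
        assert quadrant_name(1, "OD") == "nasal-superior"
        assert quadrant_name(3, "OD") == "temporal-inferior"
        assert quadrant_name(1, "OS") == "temporal-superior"
        assert quadrant_name(4, "OS") == "temporal-inferior"


class TestCategories:
    @pytest.mark.parametrize(
        "radius,expected",
        [(0.0, "small"), (0.5, "small"), (0.50001, "moderate"), (1.0, "moderate"), (1.01, "large")],
    )
    def test_boundaries(self, radius, expected):
        assert categorize_decentration(radius) == expected

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            categorize_decentration(-0.1)

    @settings(max_examples=50, derandomize=True)
    @given(r=st.floats(0, 3))
    def test_partition(self, r):
        """Every radius falls in exactly one category, monotone with radius."""
        cat = categorize_decentration(r)
        assert cat in ("small", "moderate", "large")
        order = {"small": 0, "moderate": 1, "large": 2}
        assert order[cat] == (0 if r <= 0.5 else (1 if r <= 1.0 else 2))


class TestRotationEquivariance:
    def test_rotating_difference_map_rotates_recovered_centre(self, small_grid):
        p = BaselineParams(flat_radius=7.8, steep_radius=7.8, q=0.0, noise_sd=0.0)
        base = generate_baseline_surface(p, small_grid, seed=0)
        truth = TreatmentGroundTruth(0.6, 0.2, tz_radius=1.8)
        post = apply_orthok_treatment(base, truth)
        res = analyze_eye(base, post)
        c0 = np.array([res.circle.centre_x, res.circle.centre_y])

        # rotate the smoothed difference map by k meridian steps and re-detect
        k = 10
        step = np.deg2rad(360.0 / small_grid.n_angles * k)
        d = res.delta_smoothed
        rot = DifferenceMap(d.grid, np.roll(d.delta_power, k, axis=0), np.roll(d.mask, k, axis=0))
        circle = fit_circle(detect_tz_boundary(rot))
        rotmat = np.array([[np.cos(step), -np.sin(step)], [np.sin(step), np.cos(step)]])
        expected = rotmat @ c0
        got = np.array([circle.centre_x, circle.centre_y])
        assert np.hypot(*(got - expected)) < 0.05
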