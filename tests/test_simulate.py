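"""Synthetic cornea generator: baselines, ortho-k reshaping, cohorts."""

import numpy as np
import pytest

from okzone import (
    BaselineParams,
    CohortSpec,
    TreatmentGroundTruth,
    analyze_eye,
    apply_orthok_treatment,
    generate_baseline_surface,
    generate_cohort,
    tangential_curvature,
    truth_decentration,
)


class TestBaselineGeneration:
    def test_sphere_curvature_constant(self, small_grid):
        p = BaselineParams(flat_radius=7.5, steep_radius=7.5, q=0.0, noise_sd=0.0)
        s = generate_baseline_surface(p, small_grid, seed=0)
        cm = tangential_curvature(s)
        sel = (s.node_rho() <= 5.0) & ~cm.mask
        assert np.max(np.abs(cm.tangential_curvature[sel] - 1 / 7.5)) < 1e-3

    def test_determinism_under_seed(self, small_grid):
        p = BaselineParams(noise_sd=0.002)
        a = generate_baseline_surface(p, small_grid, seed=9)
        b = generate_baseline_surface(p, small_grid, seed=9)
        c = generate_baseline_surface(p, small_grid, seed=10)
        assert np.array_equal(a.heights, b.heights)
        assert not np.array_equal(a.heights, c.heights)

    def test_zernike_perturbation_enters_surface(self, small_grid):
        p0 = BaselineParams(noise_sd=0.0)
        p1 = BaselineParams(noise_sd=0.0, zernike_perturbations=((1, 1, 0.01),))
        s0 = generate_baseline_surface(p0, small_grid, seed=0)
        s1 = generate_baseline_surface(p1, small_grid, seed=0)
        diff = s1.heights - s0.heights
        x, _ = small_grid.node_xy()
        # tilt term: difference proportional to x (rho cos phi), apex-referenced
        expected = 0.01 * x / small_grid.radii[-1]
        expected = expected - expected[:, 0:1]
        assert np.max(np.abs(diff - expected)) < 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BaselineParams(flat_radius=7.0, steep_radius=7.5)  # steep > flat
        with pytest.raises(ValueError):
            BaselineParams(noise_sd=-1e-3)


class TestTreatment:
    def test_zero_flattening_is_identity_and_undetectable(self, small_grid):
        pre = generate_baseline_surface(BaselineParams(noise_sd=0.0), small_grid, seed=0)
        truth = TreatmentGroundTruth(0.3, 0.0, central_flattening=0.0)
        post = apply_orthok_treatment(pre, truth)
        assert np.array_equal(
            np.nan_to_num(post.heights), np.nan_to_num(pre.heights)
        )
        res = analyze_eye(pre, post)
        assert res.decentration is None

    def test_centred_treatment_recovers_centre(self, small_grid):
        pre = generate_baseline_surface(BaselineParams(noise_sd=0.0), small_grid, seed=0)
        truth = TreatmentGroundTruth(0.0, 0.0, tz_radius=1.6)
        post = apply_orthok_treatment(pre, truth)
        res = analyze_eye(pre, post)
        assert np.hypot(res.circle.centre_x, res.circle.centre_y) < 0.05

    def test_decentred_treatment_pipeline_recovery(self, small_grid):
        pre = generate_baseline_surface(BaselineParams(noise_sd=0.0), small_grid, seed=0)
        truth = TreatmentGroundTruth(0.57, -0.57, tz_radius=1.8)  # 0.8 mm at 315 deg
        post = apply_orthok_treatment(pre, truth)
        res = analyze_eye(pre, post)
        assert res.decentration.radius == pytest.approx(truth.radius, abs=0.1)
        assert res.decentration.angle == pytest.approx(315.0, abs=2.0)
        assert res.circle.radius == pytest.approx(1.8, abs=0.1)

    def test_imposed_power_profile_realised_on_difference_map(self, small_grid):
        """The measured power change at the TZ centre ~ -central_flattening."""
        pre = generate_baseline_surface(BaselineParams(noise_sd=0.0), small_grid, seed=0)
        truth = TreatmentGroundTruth(0.0, 0.0, tz_radius=1.8, central_flattening=5.0,
                                     annulus_gain=3.0)
        post = apply_orthok_treatment(pre, truth)
        res = analyze_eye(pre, post)
        d = res.delta
        near_centre = (pre.node_rho() < 0.3) & ~d.mask
        assert np.nanmean(d.delta_power[near_centre]) == pytest.approx(-5.0, abs=0.15)
        # the whole measured map matches the imposed radial profile
        from okzone.simulate import _power_change_profile

        rho = pre.node_rho()
        sel = (rho <= 4.0) & ~d.mask
        expected = _power_change_profile(truth, rho[sel])
        assert np.nanmax(np.abs(d.delta_power[sel] - expected)) < 0.15
        # positive annulus beyond the boundary
        ann = (np.abs(rho - 2.3) < 0.1) & ~d.mask
        assert np.nanmean(d.delta_power[ann]) > 1.5

    def test_treatment_beyond_measured_area_rejected(self, small_grid):
        pre = generate_baseline_surface(BaselineParams(noise_sd=0.0), small_grid, seed=0)
        truth = TreatmentGroundTruth(2.2, 0.0, tz_radius=3.4, annulus_width=1.0)
        with pytest.raises(ValueError, match="exceeds the measured area"):
            apply_orthok_treatment(pre, truth)

    def test_truth_invariants_enforced(self):
        with pytest.raises(ValueError):
            TreatmentGroundTruth(2.0, 2.0)  # radius > 2.5
        with pytest.raises(ValueError):
            TreatmentGroundTruth(0, 0, tz_radius=0.5)
        with pytest.raises(ValueError):
            TreatmentGroundTruth(0, 0, central_flattening=2.0, annulus_gain=5.0)


class TestCohorts:
    def test_reproducible_ground_truth(self, tiny_grid):
        spec = CohortSpec(n_eyes=10, seed=4)
        a = generate_cohort(spec, tiny_grid)
        b = generate_cohort(spec, tiny_grid)
        for ea, eb in zip(a, b):
            assert ea.laterality == eb.laterality
            assert ea.truth == eb.truth
            assert np.array_equal(ea.pre.heights, eb.pre.heights)
            assert np.array_equal(ea.post.heights, eb.post.heights)

    def test_sample_mean_decentration_within_3_se(self, tiny_grid):
        spec = CohortSpec(n_eyes=250, seed=1, decentration_mean=0.65, decentration_sd=0.35)
        cohort = generate_cohort(spec, tiny_grid)
        radii = np.array([e.truth.radius for e in cohort])
        # |half-normal-ish| sampling plus clipping shifts the mean slightly; the
        # folded-normal mean for mu=0.65, sd=0.35 is ~0.66
        se = 0.35 / np.sqrt(250)
        assert abs(radii.mean() - 0.66) < 3 * se + 0.02

    def test_zero_eyes_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_eyes=0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_eyes=5, decentration_sd=-0.1)

    def test_laterality_ratio(self, tiny_grid):
        cohort = generate_cohort(CohortSpec(n_eyes=60, seed=2, laterality_ratio=1.0), tiny_grid)
        assert all(e.laterality == "OD" for e in cohort)

    def test_truth_decentration_quadrants(self):
        t = TreatmentGroundTruth(-0.5, -0.5)  # temporal-inferior anatomically
        od = truth_decentration(t, "OD")
        os_ = truth_decentration(t, "OS")
        assert od.quadrant == 3 and os_.quadrant == 4
        assert od.angle == pytest.approx(225.0)
        assert os_.angle == pytest.approx(225.0)


class TestDoseResponse:
    def test_induced_astigmatism_monotone_with_decentration(self, small_grid):
        """Mean astigmatism change never decreases as imposed decentration grows."""
        pre = generate_baseline_surface(
            BaselineParams(flat_radius=7.8, steep_radius=7.8, q=0.0, noise_sd=0.0),
            small_grid, seed=0,
        )
        changes = []
        for dec in (0.2, 0.8, 1.4):
            truth = TreatmentGroundTruth(dec / np.sqrt(2), -dec / np.sqrt(2), tz_radius=1.8)
            res = analyze_eye(pre, apply_orthok_treatment(pre, truth))
            changes.append(res.astig_change)
        assert changes[0] <= changes[1] <= changes[2]
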