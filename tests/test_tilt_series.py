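"""Tilt-series geometry: rotations, normals, pre-tilt model fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thonring.synthetic import synth_tilt_series
from thonring.tilt_series import (
    TiltSeriesRecord,
    fit_tilt_model,
    mean_normal,
    pre_tilt_from_normal,
    pre_tilt_per_image,
    rotation_from_tilt,
    tilt_normal,
)

NOMINALS = np.arange(-51.0, 52.0, 3.0)  # 35 images


class TestRotation:
    def test_zero_tilt_is_identity(self):
        np.testing.assert_allclose(rotation_from_tilt(0.0, 77.0), np.eye(3), atol=1e-12)

    def test_phi_zero_action_on_z(self):
        R = rotation_from_tilt(30.0, 0.0)
        expected = np.array([0.0, -np.sin(np.deg2rad(30.0)), np.cos(np.deg2rad(30.0))])
        np.testing.assert_allclose(R @ [0.0, 0.0, 1.0], expected, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(theta=st.floats(-90.0, 90.0), phi=st.floats(0.0, 360.0))
    def test_orthonormal_right_handed(self, theta, phi):
        R = rotation_from_tilt(theta, phi)
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


class TestPreTiltPerImage:
    def test_zero_nominal_angle(self):
        rec = TiltSeriesRecord(0.0, 25.0, 140.0)
        np.testing.assert_allclose(
            pre_tilt_per_image(rec, 178.0), rotation_from_tilt(25.0, 140.0), atol=1e-12
        )

    def test_estimate_equals_stage_rotation(self):
        rec = TiltSeriesRecord(21.0, 21.0, 178.0)
        np.testing.assert_allclose(pre_tilt_per_image(rec, 178.0), np.eye(3), atol=1e-12)

    def test_consistent_series_gives_constant_pre_tilt(self):
        records = synth_tilt_series(20.0, 170.0, 178.0, NOMINALS)
        normals = [
            pre_tilt_per_image(r, 178.0) @ np.array([0.0, 0.0, 1.0]) for r in records
        ]
        spread = np.ptp(np.asarray(normals), axis=0).max()
        assert spread < 1e-9


class TestMeanNormal:
    def test_identical_normals(self):
        rots = np.stack([rotation_from_tilt(20.0, 170.0)] * 6)
        mean, mask = mean_normal(rots)
        np.testing.assert_allclose(mean, tilt_normal(20.0, 170.0), atol=1e-12)
        assert mask.all()

    def test_single_flipped_normal_excluded(self):
        good = [rotation_from_tilt(20.0, 170.0)] * 9
        bad = rotation_from_tilt(-160.0, 170.0)  # antipodal-ish normal
        mean, mask = mean_normal(np.stack(good + [bad]))
        assert not mask[-1] and mask[:-1].all()

    def test_symmetric_perturbations_cancel(self):
        delta = 0.5
        rots = np.stack(
            [rotation_from_tilt(20.0 + s * delta, 170.0) for s in (+1, -1)] * 3
        )
        mean, _ = mean_normal(rots)
        ref = tilt_normal(20.0, 170.0)
        assert np.arccos(np.clip(mean @ ref, -1, 1)) < np.deg2rad(delta) ** 2


class TestPreTiltFromNormal:
    def test_z_axis(self):
        theta0, _ = pre_tilt_from_normal([0.0, 0.0, 1.0])
        assert theta0 == 0.0

    def test_phi_zero_rotation_normal(self):
        v = [0.0, -np.sin(np.deg2rad(20.0)), np.cos(np.deg2rad(20.0))]
        theta0, phi0 = pre_tilt_from_normal(v)
        assert theta0 == pytest.approx(20.0)
        assert phi0 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta,phi", [(10.0, 30.0), (45.0, 170.0), (70.0, 100.0)])
    def test_round_trip_mod_180(self, theta, phi):
        theta0, phi0 = pre_tilt_from_normal(tilt_normal(theta, phi))
        assert abs(theta0) == pytest.approx(theta, abs=1e-9)
        assert phi0 % 180.0 == pytest.approx(phi % 180.0, abs=1e-9)


class TestFitTiltModel:
    def test_noiseless_exact_recovery(self):
        records = synth_tilt_series(20.0, 170.0, 178.0, NOMINALS, noise_deg=0.0)
        model = fit_tilt_model(records)
        assert model.theta0 == pytest.approx(20.0, abs=0.1)
        assert model.phi0 == pytest.approx(170.0, abs=0.1)
        assert model.stage_axis == pytest.approx(178.0, abs=0.1)
        assert np.all(model.residuals_deg < 0.01)

    def test_negative_pre_tilt_recovered(self):
        # a grid inserted the other way round: pre-tilt of about -22 degrees
        records = synth_tilt_series(-21.9, 183.8 % 180.0, 179.8, NOMINALS)
        model = fit_tilt_model(records)
        assert model.theta0 == pytest.approx(-21.9, abs=0.1)

    def test_noisy_recovery_within_one_degree(self):
        records = synth_tilt_series(20.0, 170.0, 178.0, NOMINALS, noise_deg=2.0, seed=1)
        model = fit_tilt_model(records)
        assert model.theta0 == pytest.approx(20.0, abs=1.0)

    def test_low_tilt_images_flagged_axis_unreliable(self):
        records = synth_tilt_series(20.0, 170.0, 178.0, NOMINALS)
        model = fit_tilt_model(records)
        thetas = np.array([r.est_theta for r in records])
        np.testing.assert_array_equal(model.axis_reliable, thetas >= 5.0)

    def test_too_few_records_rejected(self):
        records = synth_tilt_series(20.0, 170.0, 178.0, [-3.0, 0.0, 3.0])
        with pytest.raises(ValueError):
            fit_tilt_model(records)


class TestForwardModelShape:
    def test_v_shape_with_apex_near_minus_pre_tilt(self):
        records = synth_tilt_series(20.0, 170.0, 178.0, NOMINALS)
        thetas = np.array([r.est_theta for r in records])
        apex = NOMINALS[np.argmin(thetas)]
        assert abs(apex + 20.0) <= 3.0  # apex near nominal = -pre-tilt
        # |theta| decreases towards the apex and increases after: V shape
        left = thetas[NOMINALS < apex]
        right = thetas[NOMINALS > apex]
        assert np.all(np.diff(left) < 0) and np.all(np.diff(right) > 0)

    def test_phi_flips_180_across_apex(self):
        # the axis direction reported on the two branches of the V differs by
        # about 180 degrees (high-tilt images far from the apex)
        records = synth_tilt_series(20.0, 170.0, 178.0, NOMINALS)
        phis = np.array([r.est_phi for r in records])
        jump = abs(phis[-1] - phis[0]) % 360.0
        assert 150.0 < jump < 210.0
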