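"""Time-disparity measurement, velocity normalization, depth decoding."""

import numpy as np
import pytest

from saccadeye.depth import (DepthCalibration, DepthError,
                             UndefinedDisparityError, VelocityUndefinedError,
                             DepthOutOfRangeError, time_disparity,
                             velocity_estimate, estimate_depth_closed_form,
                             estimate_depth, run_depth_trial, build_calibration,
                             depth_error_curve, _disparity_channels)
from saccadeye.kinematics import KineticsParams
from saccadeye.phototransduction import adaptive_response
from saccadeye.stimuli import mirror_scene, render_binocular
from saccadeye.depth import _trial_scene


def gaussian_pulse(t0, width=30.0, n=1000):
    t = np.arange(float(n))
    return np.exp(-0.5 * ((t - t0) / width) ** 2)


class TestTimeDisparity:
    def test_known_integer_delay(self):
        a = gaussian_pulse(400.0)
        b = gaussian_pulse(405.0)
        assert time_disparity(a, b, dt_ms=1.0) == pytest.approx(5.0, abs=0.01)

    def test_subsample_recovery_of_458us_lag(self):
        """A 4.58-ms offset is recovered to +/-0.1 ms at 1-ms sampling."""
        a = gaussian_pulse(400.0)
        b = gaussian_pulse(404.58)
        assert time_disparity(a, b, dt_ms=1.0) == pytest.approx(4.58, abs=0.1)

    def test_sign_flips_when_swapped(self):
        a = gaussian_pulse(400.0)
        b = gaussian_pulse(404.58)
        assert time_disparity(b, a, dt_ms=1.0) == pytest.approx(-4.58, abs=0.1)

    def test_flat_input_rejected(self):
        with pytest.raises(UndefinedDisparityError):
            time_disparity(np.zeros(100), gaussian_pulse(50, n=100), dt_ms=1.0)

    def test_mismatched_length_rejected(self):
        with pytest.raises(DepthError):
            time_disparity(np.zeros(100), np.zeros(90), dt_ms=1.0)


class TestVelocity:
    def test_velocity_from_known_lag(self):
        a = gaussian_pulse(300.0)
        b = gaussian_pulse(390.0)
        omega, lag = velocity_estimate(a, b, 4.5, dt_ms=1.0)
        assert lag == pytest.approx(90.0, abs=0.1)
        assert omega == pytest.approx(50.0, rel=0.01)

    def test_near_zero_lag_rejected(self):
        a = gaussian_pulse(300.0)
        with pytest.raises(VelocityUndefinedError):
            velocity_estimate(a, a.copy(), 4.5, dt_ms=1.0)

    def test_static_scene_velocity_undefined(self, eye_pair):
        est = run_depth_trial(eye_pair, 25.0, mode="static", stochastic=False,
                              speed_dps=0.0)
        assert not est.ok


class TestClosedForm:
    def test_inverse_of_trigonometric_disparity(self):
        """k=0.4 mm, omega=50 deg/s, dt=18.33 ms decodes to ~25 mm."""
        z = estimate_depth_closed_form(18.334, 50.0, 0.4)
        assert z == pytest.approx(25.0, rel=1e-3)

    def test_nonpositive_disparity_out_of_range(self):
        with pytest.raises(DepthOutOfRangeError):
            estimate_depth_closed_form(0.0, 50.0, 0.4)
        with pytest.raises(DepthOutOfRangeError):
            estimate_depth_closed_form(-3.0, 50.0, 0.4)


class TestCalibration:
    def test_monotone_and_self_consistent(self, calibration):
        p = calibration.product
        assert np.all(np.diff(p) < 0) or np.all(np.diff(p) > 0)
        # decoding its own table entries recovers the grid depths
        for z, dt, om in zip(calibration.z_mm, calibration.delta_t_ms,
                             calibration.omega_hat_dps):
            z_hat, clamped = calibration.decode(dt, om)
            assert z_hat == pytest.approx(z, rel=1e-6)
            assert not clamped

    def test_monotone_delta_t_over_full_range(self, calibration):
        """Delta-t (velocity-normalized) is strictly monotone in depth.

        The empirical direction in the default closed-loop model: the
        closer the object, the *longer* the inter-eye lag.
        """
        assert calibration.monotone_direction == "decreasing"
        assert np.all(calibration.z_mm[0] <= 2.0 + 1e-9)
        assert calibration.z_mm[-1] >= 200.0

    def test_non_monotone_table_rejected(self):
        with pytest.raises(DepthError):
            DepthCalibration(z_mm=np.array([10.0, 20.0, 30.0]),
                             delta_t_ms=np.array([5.0, 9.0, 7.0]),
                             omega_hat_dps=np.array([50.0, 50.0, 50.0]))

    def test_out_of_range_clamps(self, calibration):
        z_hat, clamped = calibration.decode(1e4, 50.0)
        assert clamped and z_hat == pytest.approx(calibration.z_mm[0], rel=1e-6)


class TestNoiselessPipeline:
    @pytest.mark.parametrize("z", [5.0, 25.0, 100.0, 200.0])
    def test_static_mode_matches_triangulation(self, eye_pair, z):
        """Static-mode lag equals trigonometric disparity / omega within 2%."""
        est = run_depth_trial(eye_pair, z, mode="static", stochastic=False)
        geo = 1000.0 * 2 * np.rad2deg(np.arctan(eye_pair.baseline_mm / (2 * z))) / 50.0
        assert est.ok
        assert est.delta_t_ms == pytest.approx(geo, rel=0.02)
        assert est.omega_hat_dps == pytest.approx(50.0, rel=0.02)

    def test_noiseless_closed_loop_recovery_within_1pct(self, eye_pair, calibration):
        est = run_depth_trial(eye_pair, 25.0, mode="microsaccadic",
                              stochastic=False, calibration=calibration)
        assert est.ok and est.rel_error < 0.01

    def test_reflection_symmetry_of_lag(self, eye_pair):
        """Reversing stimulus direction flips the sign of the lag."""
        members_a, _, _ = _disparity_channels(eye_pair)
        scene = _trial_scene(25.0, eye_pair, 50.0, 3.5, 3.9, 1.0, 1)
        rev = mirror_scene(scene)
        subset = sorted({("left", o) for o, _ in members_a}
                        | {("right", o) for o, _ in members_a})
        kin = KineticsParams()
        rows_l = rows_r = None
        lags = {}
        for name, sc in (("fwd", scene), ("rev", rev)):
            li = render_binocular(sc, eye_pair, kin, "microsaccadic", subset=subset)
            vl = adaptive_response(li.intensity[li.rows(members_a, "left")]).v.mean(axis=0)
            vr = adaptive_response(li.intensity[li.rows(members_a, "right")]).v.mean(axis=0)
            lags[name] = time_disparity(vl, vr, dt_ms=1.0, start_ms=150.0)
        assert lags["rev"] == pytest.approx(-lags["fwd"], abs=1e-6)


class TestStochasticPipeline:
    def test_trial_is_seed_reproducible(self, eye_pair, calibration):
        a = run_depth_trial(eye_pair, 50.0, stochastic=True, seed=77,
                            calibration=calibration)
        b = run_depth_trial(eye_pair, 50.0, stochastic=True, seed=77,
                            calibration=calibration)
        assert a.delta_t_ms == b.delta_t_ms and a.z_hat_mm == b.z_hat_mm

    def test_error_curve_smoke(self, eye_pair, calibration):
        df, summary = depth_error_curve(eye_pair, [25.0], 2, seed=1,
                                        calibration=calibration)
        assert len(df) == 2
        assert set(df.columns) >= {"z_true_mm", "z_hat_mm", "delta_t_ms",
                                   "omega_dps", "rel_error", "trial", "seed"}
        assert 25.0 in summary

    def test_bad_arguments_rejected(self, eye_pair, calibration):
        with pytest.raises(DepthError):
            depth_error_curve(eye_pair, [25.0], 1, seed=0, calibration=calibration)
        with pytest.raises(DepthError):
            depth_error_curve(eye_pair, [-5.0], 2, seed=0, calibration=calibration)
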