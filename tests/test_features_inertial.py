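"""Closed-form oracles and schema contracts for the per-window features."""

import numpy as np
import pytest

from actifuse import simulate_session
from actifuse.features_inertial import (
    PHONE_FEATURE_NAMES,
    WATCH_FEATURE_NAMES,
    activity_counts,
    altitude_features,
    coefficients_of_variation,
    compute_phone_features,
    compute_watch_features,
    estimated_distance,
    mean_device_angle,
    rms_counts,
    sensor_subset_columns,
    spectral_features,
    step_count,
)
from actifuse.pipeline import extract_feature_table

from conftest import N, RATE, make_window, tone


class TestActivityCounts:
    def test_zero_window(self):
        assert np.all(activity_counts(np.zeros((N, 3)), RATE) == 0)

    def test_unit_2hz_tone_closed_form(self):
        """Rectified integral of sin(2pi 2t) over 2 s = 2 s * (2/pi)."""
        x = np.column_stack([tone(2.0)] * 3)
        counts = activity_counts(x, RATE)
        assert counts == pytest.approx(4.0 / np.pi, rel=0.02)

    def test_linear_in_amplitude(self):
        x = np.column_stack([tone(2.0)] * 3)
        assert activity_counts(2 * x, RATE) == pytest.approx(
            2 * activity_counts(x, RATE))


class TestRmsCounts:
    def test_zero(self):
        assert rms_counts(np.zeros((N, 3))) == 0.0

    def test_single_axis_equals_axis_rms(self):
        x = np.zeros((N, 3))
        x[:, 0] = tone(2.0)
        assert rms_counts(x) == pytest.approx(np.sqrt(np.mean(x[:, 0] ** 2)))


class TestDeviceAngle:
    def test_gravity_along_y_is_zero(self):
        v = np.tile([0.0, 9.81, 0.0], (N, 1))
        assert mean_device_angle(v, False, 9.81) == pytest.approx(0.0)
        assert mean_device_angle(v, True, 9.81) == pytest.approx(0.0)

    def test_gravity_along_x_is_ninety(self):
        v = np.tile([9.81, 0.0, 0.0], (N, 1))
        assert mean_device_angle(v, False, 9.81) == pytest.approx(90.0)
        assert mean_device_angle(v, True, 9.81) == pytest.approx(90.0)

    def test_near_zero_vector_flagged_missing(self):
        v = np.full((N, 3), 1e-3)
        assert np.isnan(mean_device_angle(v, True, 9.81))
        assert np.isnan(mean_device_angle(v, False, 9.81))

    def test_configured_posture_angle_recovered(self):
        """Corrected angle of a sitting trace matches the generator's
        gravity-axis angle within 2 degrees."""
        from actifuse.synthgen import DEFAULT_PROFILES

        profile = DEFAULT_PROFILES["sitting"].replace(gravity_axis_angle_deg=40.0)
        session = simulate_session([(profile, 30.0)], seed=2)
        table = extract_feature_table(session.streams["phone"],
                                      session.segments, "phone")
        assert np.all(np.abs(table["acc_angle_corrected_deg"] - 40.0) < 2.0)


class TestCoefficientOfVariation:
    def test_constant_rectified_signal_is_zero(self):
        assert np.all(coefficients_of_variation(np.ones((N, 3))) == 0)

    def test_rectified_sine_closed_form(self):
        """CV of |sin| = sqrt(pi^2/8 - 1) ~ 0.483."""
        x = np.column_stack([tone(2.0)] * 3)
        expected = np.sqrt(np.pi**2 / 8 - 1)
        assert coefficients_of_variation(x) == pytest.approx(expected, rel=0.02)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(N, 3))
        assert coefficients_of_variation(7.3 * x) == pytest.approx(
            coefficients_of_variation(x))


class TestSpectral:
    def test_zero_window_conventions(self):
        out = spectral_features(np.zeros((N, 3)), RATE)
        assert np.all(out["max_power"] == 0)
        assert np.all(out["peak_frequency"] == 0)
        assert out["peak_power"] == 0 and out["primary_frequency"] == 0

    def test_on_bin_tone_exact(self):
        """A 3.0 Hz tone sits exactly on a 0.5 Hz bin: peak frequency is
        exact, and the X axis carries the max power."""
        x = np.zeros((N, 3))
        x[:, 0] = tone(3.0)
        out = spectral_features(x, RATE)
        assert out["peak_frequency"][0] == 3.0
        assert out["primary_frequency"] == 3.0
        assert out["peak_power"] == out["max_power"][0]

    def test_peak_power_is_max_over_axes(self):
        x = np.column_stack([tone(2.0), 2 * tone(3.0), 0.5 * tone(4.0)])
        out = spectral_features(x, RATE)
        assert out["peak_power"] == pytest.approx(out["max_power"][1])


class TestStepCount:
    def test_zero_window(self):
        assert np.all(step_count(np.zeros((N, 3)), RATE) == 0)

    def test_2hz_tone_has_four_peaks(self):
        x = np.column_stack([tone(2.0)] * 3)
        assert np.all(step_count(x, RATE) == 4)

    def test_robust_to_moderate_noise(self):
        rng = np.random.default_rng(0)
        x = tone(2.0)[:, None] + rng.normal(0, 0.1, size=(N, 1))
        count = step_count(np.repeat(x, 3, axis=1), RATE)
        assert np.all(np.abs(count - 4) <= 1)


class TestEstimatedDistance:
    def test_zero_window(self):
        assert estimated_distance(np.zeros((N, 3)), RATE) == 0.0

    def test_constant_acceleration_measures_nothing(self):
        # detrend removes DC: the feature tracks oscillatory displacement
        x = np.zeros((N, 3))
        x[:, 0] = 1.0
        assert estimated_distance(x, RATE) < 1e-9

    @pytest.mark.parametrize("freq,amp", [(2.0, 1.0), (3.0, 2.5)])
    def test_sinusoid_closed_form(self, freq, amp):
        """Displacement amplitude of a.sin(2pi f t) is a/(2pi f)^2."""
        x = np.zeros((N, 3))
        x[:, 1] = amp * np.sin(2 * np.pi * freq * np.arange(N) / RATE)
        expected = amp / (2 * np.pi * freq) ** 2
        assert estimated_distance(x, RATE) == pytest.approx(expected, rel=0.05)


class TestAltitude:
    def test_constant_pressure(self):
        diff, slope = altitude_features(np.full(20, 1013.25), 10.0)
        assert diff == 0.0 and slope == 0.0

    def test_pressure_drop_closed_form(self):
        """A 0.12 hPa linear fall over 2 s near sea level is ~ +1.0 m of
        altitude (international barometric formula oracle)."""
        p = np.linspace(1013.25, 1013.25 - 0.12, 20)
        diff, slope = altitude_features(p, 10.0)
        assert diff == pytest.approx(1.0, rel=0.05)
        assert slope == pytest.approx(diff / 1.9, rel=0.05)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            altitude_features(np.array([1000.0, -1.0]), 10.0)

    def test_elevator_slope_recovered(self):
        """Windows in the cruise phase of a 1 m/s elevator ascent read a
        mean slope of ~ +1 m/s."""
        session = simulate_session([("elevator_ascent", 30.0)], seed=4)
        table = extract_feature_table(session.streams["phone"],
                                      session.segments, "phone")
        cruise = table.iloc[3:-3]  # skip trapezoid ramps
        assert np.median(cruise["alt_slope_mps"]) == pytest.approx(1.0, abs=0.2)


class TestSchemas:
    def test_phone_schema_53(self, mixed_phone_table):
        assert len(PHONE_FEATURE_NAMES) == 53
        feature_cols = [c for c in mixed_phone_table.columns
                        if c in PHONE_FEATURE_NAMES]
        assert feature_cols == list(PHONE_FEATURE_NAMES)
        assert np.isfinite(
            mixed_phone_table[list(PHONE_FEATURE_NAMES)].to_numpy()).all()

    def test_watch_schema_17(self, mixed_watch_table):
        assert len(WATCH_FEATURE_NAMES) == 17
        feature_cols = [c for c in mixed_watch_table.columns
                        if c in WATCH_FEATURE_NAMES]
        assert feature_cols == list(WATCH_FEATURE_NAMES)

    def test_sensor_attribution_counts(self):
        assert len(sensor_subset_columns("accelerometer")) == 21
        assert len(sensor_subset_columns("magnetometer")) == 19
        assert len(sensor_subset_columns("gyro")) == 11
        assert sensor_subset_columns("pressure") == ["alt_diff_m", "alt_slope_mps"]
        assert len(sensor_subset_columns("fused")) == 53

    def test_missing_sensor_slice_rejected(self):
        w = make_window({"accelerometer_gravity": np.zeros((N, 3))})
        with pytest.raises(KeyError):
            compute_phone_features(w)
        with pytest.raises(KeyError):
            compute_watch_features(w)

    def test_zero_window_values(self):
        keys = ("accelerometer_gravity", "accelerometer_dynamic",
                "magnetometer_gravity", "magnetometer_dynamic",
                "gyroscope_dynamic")
        sigs = {k: np.zeros((N, 3)) for k in keys}
        sigs["pressure"] = np.full(20, 1013.25)
        f = compute_phone_features(make_window(sigs))
        angles = [k for k in f if "angle" in k]
        for k, v in f.items():
            if k in angles:
                assert np.isnan(v)
            else:
                assert v == 0.0


def test_intensity_scales_with_amplitude():
    """Doubling the generator's dynamic amplitude doubles the count-type
    features (monotone intensity contract)."""
    from actifuse.synthgen import DEFAULT_PROFILES

    base = DEFAULT_PROFILES["walking"]
    strong = base.replace(dynamic_amplitude_ms2=2 * base.dynamic_amplitude_ms2)
    t1 = extract_feature_table(
        *_session_parts(simulate_session([(base, 30.0)], seed=6)), "phone")
    t2 = extract_feature_table(
        *_session_parts(simulate_session([(strong, 30.0)], seed=6)), "phone")
    for col in ("acc_count_y", "acc_rms_count"):
        assert t2[col].mean() == pytest.approx(2 * t1[col].mean(), rel=0.1)
    assert t2["acc_peak_power"].mean() > 2 * t1["acc_peak_power"].mean()


def test_watch_separates_walking_from_sitting(mixed_watch_table):
    walk = mixed_watch_table[mixed_watch_table.label == "walking"]["acc_count_y"]
    sit = mixed_watch_table[mixed_watch_table.label == "sitting"]["acc_count_y"]
    assert walk.min() > sit.max()


def _session_parts(session):
    return session.streams["phone"], session.segments
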