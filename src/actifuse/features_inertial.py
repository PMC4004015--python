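"""Per-window inertial and barometric features.

The phone schema has exactly 53 attributes drawn from accelerometer (A),
magnetometer (M), gyroscope (G) and pressure (P); the watch schema is the
17-attribute accelerometer subset. Intensity features (activity counts, RMS
counts, coefficients of variation) operate on the band-passed dynamic
component; orientation features on the low-passed gravity/field component;
altitude features on raw pressure converted through the international
barometric formula.

An *activity count* is the classical actigraphy epoch measure: the
rectified integral of the band-passed signal, sum(|x|) x dt, per axis.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate as spi
from scipy import signal as sps

from .synthgen import GRAVITY_MS2, EARTH_FIELD_UT, altitude_from_pressure
from .windowing import Window

STEP_MIN_SEPARATION_S = 0.25  # max credible cadence 4 Hz
STEP_THRESHOLD_RMS_FRACTION = 0.5
ANGLE_MIN_MAGNITUDE_FRACTION = 0.1  # below this, angle is meaningless


# ---------------------------------------------------------------------------
# feature primitives (each takes an (n, axes) array plus rate where needed)
# ---------------------------------------------------------------------------

def activity_counts(banded: np.ndarray, rate_hz: float) -> np.ndarray:
    """Rectified integral per axis: sum(|x|) * dt. Linear in amplitude."""
    return np.sum(np.abs(banded), axis=0) / rate_hz


def rms_counts(banded: np.ndarray) -> float:
    """RMS of the per-sample vector magnitude over the window."""
    return float(np.sqrt(np.mean(np.sum(np.asarray(banded) ** 2, axis=1))))


def mean_device_angle(
    lowpassed: np.ndarray,
    corrected: bool,
    expected_magnitude: float | None = None,
) -> float:
    """Angle (deg, in [0, 180]) between the sensed static vector and +Y.

    Uncorrected: mean over samples of the instantaneous angle. Corrected:
    angle of the window's mean vector (accelerometer gravity vector).
    Near-zero vectors (< 0.1 of the expected field) make the angle
    meaningless; the value is flagged missing (NaN).
    """
    v = np.asarray(lowpassed, float)
    mags = np.linalg.norm(v, axis=1)
    floor = (
        ANGLE_MIN_MAGNITUDE_FRACTION * expected_magnitude
        if expected_magnitude
        else 1e-9
    )
    if corrected:
        mean_v = v.mean(axis=0)
        m = np.linalg.norm(mean_v)
        if m < floor:
            return float("nan")
        return float(np.degrees(np.arccos(np.clip(mean_v[1] / m, -1.0, 1.0))))
    ok = mags >= floor
    if not np.any(ok):
        return float("nan")
    cos = np.clip(v[ok, 1] / mags[ok], -1.0, 1.0)
    return float(np.mean(np.degrees(np.arccos(cos))))


def coefficients_of_variation(banded: np.ndarray) -> np.ndarray:
    """SD / mean of the rectified signal per axis.

    The band-passed signal is zero-mean by construction, so the CV is taken
    on |x|; a rectified mean at machine zero returns 0 by convention.
    """
    r = np.abs(np.asarray(banded, float))
    mean = r.mean(axis=0)
    sd = r.std(axis=0)
    out = np.zeros(r.shape[1])
    nz = mean > 1e-12
    out[nz] = sd[nz] / mean[nz]
    return out


def spectral_features(banded: np.ndarray, rate_hz: float) -> dict:
    """Periodogram summary per axis.

    Returns max_power and peak_frequency per axis, peak_power (max over
    axes) and primary_frequency (bin maximizing power summed across axes).
    A 2-s window at 100 Hz gives 0.5 Hz bins, so an on-bin tone is exact.
    All-zero input returns zero powers and, by convention, zero frequencies.
    """
    x = np.asarray(banded, float)
    freqs, pxx = sps.periodogram(x, fs=rate_hz, window="boxcar",
                                 detrend=False, axis=0)
    max_power = pxx.max(axis=0)
    peak_idx = pxx.argmax(axis=0)
    peak_freq = freqs[peak_idx].astype(float)
    peak_freq[max_power <= 0.0] = 0.0
    total = pxx.sum(axis=1)
    primary = float(freqs[int(total.argmax())]) if total.max() > 0 else 0.0
    return {
        "max_power": max_power,
        "peak_frequency": peak_freq,
        "peak_power": float(max_power.max(initial=0.0)),
        "primary_frequency": primary,
    }


def step_count(banded: np.ndarray, rate_hz: float) -> np.ndarray:
    """Cyclical peaks per axis: local maxima above 0.5 x window RMS with a
    minimum separation of 0.25 s."""
    x = np.asarray(banded, float)
    out = np.zeros(x.shape[1], dtype=int)
    dist = max(1, int(round(STEP_MIN_SEPARATION_S * rate_hz)))
    for c in range(x.shape[1]):
        rms = np.sqrt(np.mean(x[:, c] ** 2))
        if rms <= 0:
            continue
        peaks, _ = sps.find_peaks(
            x[:, c], height=STEP_THRESHOLD_RMS_FRACTION * rms, distance=dist
        )
        out[c] = len(peaks)
    return out


def estimated_distance(banded: np.ndarray, rate_hz: float) -> float:
    """Oscillatory-displacement proxy from double integration.

    Each axis of the band-passed acceleration is detrended (mean removed),
    integrated twice trapezoidally (detrending again between stages), and
    summarized by its peak displacement; the three per-axis displacements
    combine as a Euclidean norm. For a·sin(2πft) this recovers the
    closed-form displacement amplitude a/(2πf)²; a constant offset yields 0
    — the feature measures movement, not transport.
    """
    x = np.asarray(banded, float)
    dt = 1.0 / rate_hz
    disp = np.zeros(x.shape[1])
    for c in range(x.shape[1]):
        a = x[:, c] - x[:, c].mean()
        v = spi.cumulative_trapezoid(a, dx=dt, initial=0.0)
        v -= v.mean()
        p = spi.cumulative_trapezoid(v, dx=dt, initial=0.0)
        p -= p.mean()
        disp[c] = np.max(np.abs(p))
    return float(np.linalg.norm(disp))


def altitude_features(raw_pressure: np.ndarray, rate_hz: float) -> tuple[float, float]:
    """(altitude_difference_m, mean_slope_m_per_s) from raw pressure.

    Pressure converts to altitude by the international barometric formula;
    the difference is last minus first altitude in the window, the slope a
    least-squares fit of altitude against time.
    """
    p = np.asarray(raw_pressure, float).ravel()
    if np.any(p <= 0):
        raise ValueError("non-positive pressure")
    h = altitude_from_pressure(p)
    t = np.arange(p.size) / rate_hz
    slope = float(np.polyfit(t, h, 1)[0]) if p.size > 1 else 0.0
    return float(h[-1] - h[0]), slope


# ---------------------------------------------------------------------------
# schemas
# ---------------------------------------------------------------------------

def _axis_names(prefix: str) -> list[str]:
    return [f"{prefix}_{ax}" for ax in ("x", "y", "z")]


def _schema_phone() -> list[str]:
    names: list[str] = []
    names += _axis_names("acc_count") + _axis_names("mag_count")  # 6
    names += ["acc_rms_count", "mag_rms_count"]  # 2
    names += ["acc_angle_mean_deg", "mag_angle_mean_deg"]  # 2
    names += ["acc_angle_corrected_deg"]  # 1
    names += _axis_names("acc_cv") + _axis_names("mag_cv")  # 6
    for s in ("acc", "mag", "gyro"):  # 9 + 9
        names += _axis_names(f"{s}_max_power")
    for s in ("acc", "mag", "gyro"):
        names += _axis_names(f"{s}_peak_freq")
    names += [f"{s}_peak_power" for s in ("acc", "mag", "gyro")]  # 3
    names += [f"{s}_primary_freq" for s in ("acc", "mag", "gyro")]  # 3
    for s in ("acc", "mag", "gyro"):  # 9
        names += _axis_names(f"{s}_step_count")
    names += ["acc_distance_m", "alt_diff_m", "alt_slope_mps"]  # 3
    return names


def _schema_watch() -> list[str]:
    names: list[str] = []
    names += _axis_names("acc_count")  # 3
    names += ["acc_rms_count"]  # 1
    names += _axis_names("acc_peak_freq")  # 3
    names += _axis_names("acc_max_power")  # 3
    names += ["acc_peak_power", "acc_primary_freq"]  # 2
    names += _axis_names("acc_step_count")  # 3
    names += ["acc_angle_mean_deg", "acc_angle_corrected_deg"]  # 2
    return names


PHONE_FEATURE_NAMES: tuple[str, ...] = tuple(_schema_phone())
WATCH_FEATURE_NAMES: tuple[str, ...] = tuple(_schema_watch())
assert len(PHONE_FEATURE_NAMES) == 53
assert len(WATCH_FEATURE_NAMES) == 17

#: Table-of-features sensor attribution, used to build single-sensor datasets
SENSOR_PREFIXES = {
    "accelerometer": ("acc_",),
    "magnetometer": ("mag_",),
    "gyro": ("gyro_",),
    "pressure": ("alt_",),
}


def sensor_subset_columns(subset: str, schema=PHONE_FEATURE_NAMES) -> list[str]:
    """Feature names attributed to one sensor (or 'fused' for all)."""
    if subset == "fused":
        return list(schema)
    if subset not in SENSOR_PREFIXES:
        raise ValueError(f"unknown sensor subset {subset!r}")
    prefixes = SENSOR_PREFIXES[subset]
    return [n for n in schema if n.startswith(prefixes)]


# ---------------------------------------------------------------------------
# per-window assembly
# ---------------------------------------------------------------------------

def compute_phone_features(window: Window) -> dict:
    """The 53-attribute phone feature vector for one 2-s window.

    Requires ``accelerometer_gravity``, ``accelerometer_dynamic``,
    ``magnetometer_gravity``, ``magnetometer_dynamic``,
    ``gyroscope_dynamic`` and ``pressure`` slices; a missing sensor slice
    rejects the window.
    """
    acc_g = window.get("accelerometer_gravity")
    acc_d = window.get("accelerometer_dynamic")
    mag_g = window.get("magnetometer_gravity")
    mag_d = window.get("magnetometer_dynamic")
    gyr_d = window.get("gyroscope_dynamic")
    press = window.get("pressure")
    r_in = window.rates["accelerometer_dynamic"]
    r_p = window.rates["pressure"]

    f: dict[str, float] = {}
    for ax, v in zip("xyz", activity_counts(acc_d, r_in)):
        f[f"acc_count_{ax}"] = float(v)
    for ax, v in zip("xyz", activity_counts(mag_d, r_in)):
        f[f"mag_count_{ax}"] = float(v)
    f["acc_rms_count"] = rms_counts(acc_d)
    f["mag_rms_count"] = rms_counts(mag_d)
    f["acc_angle_mean_deg"] = mean_device_angle(acc_g, False, GRAVITY_MS2)
    f["mag_angle_mean_deg"] = mean_device_angle(mag_g, False, EARTH_FIELD_UT)
    f["acc_angle_corrected_deg"] = mean_device_angle(acc_g, True, GRAVITY_MS2)
    for ax, v in zip("xyz", coefficients_of_variation(acc_d)):
        f[f"acc_cv_{ax}"] = float(v)
    for ax, v in zip("xyz", coefficients_of_variation(mag_d)):
        f[f"mag_cv_{ax}"] = float(v)
    for name, band in (("acc", acc_d), ("mag", mag_d), ("gyro", gyr_d)):
        spec = spectral_features(band, r_in)
        for ax, v in zip("xyz", spec["max_power"]):
            f[f"{name}_max_power_{ax}"] = float(v)
        for ax, v in zip("xyz", spec["peak_frequency"]):
            f[f"{name}_peak_freq_{ax}"] = float(v)
        f[f"{name}_peak_power"] = spec["peak_power"]
        f[f"{name}_primary_freq"] = spec["primary_frequency"]
        for ax, v in zip("xyz", step_count(band, r_in)):
            f[f"{name}_step_count_{ax}"] = float(v)
    f["acc_distance_m"] = estimated_distance(acc_d, r_in)
    diff, slope = altitude_features(press, r_p)
    f["alt_diff_m"] = diff
    f["alt_slope_mps"] = slope

    out = {name: f[name] for name in PHONE_FEATURE_NAMES}
    assert len(out) == 53
    return out


def compute_watch_features(window: Window) -> dict:
    """The 17-attribute watch accelerometry feature vector."""
    acc_g = window.get("accelerometer_gravity")
    acc_d = window.get("accelerometer_dynamic")
    r_in = window.rates["accelerometer_dynamic"]

    f: dict[str, float] = {}
    for ax, v in zip("xyz", activity_counts(acc_d, r_in)):
        f[f"acc_count_{ax}"] = float(v)
    f["acc_rms_count"] = rms_counts(acc_d)
    spec = spectral_features(acc_d, r_in)
    for ax, v in zip("xyz", spec["peak_frequency"]):
        f[f"acc_peak_freq_{ax}"] = float(v)
    for ax, v in zip("xyz", spec["max_power"]):
        f[f"acc_max_power_{ax}"] = float(v)
    f["acc_peak_power"] = spec["peak_power"]
    f["acc_primary_freq"] = spec["primary_frequency"]
    for ax, v in zip("xyz", step_count(acc_d, r_in)):
        f[f"acc_step_count_{ax}"] = float(v)
    f["acc_angle_mean_deg"] = mean_device_angle(acc_g, False, GRAVITY_MS2)
    f["acc_angle_corrected_deg"] = mean_device_angle(acc_g, True, GRAVITY_MS2)

    out = {name: f[name] for name in WATCH_FEATURE_NAMES}
    assert len(out) == 17
    return out
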