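"""Zero-phase Butterworth filter bank separating the static (gravity)
component from the dynamic gait band, and detrending barometric pressure.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``): flat passband, no group delay, so filtered samples stay
aligned with the raw timeline and 2-s windows cut on either agree.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .signal_io import UniformSignal

_DEFAULT = PipelineConfig()


def _sos(order: int, cutoff, btype: str, rate_hz: float) -> np.ndarray:
    nyq = rate_hz / 2.0
    edges = np.atleast_1d(cutoff).astype(float)
    if np.any(edges <= 0) or np.any(edges >= nyq):
        raise ValueError(f"cutoff {cutoff} outside (0, Nyquist={nyq} Hz)")
    return sps.butter(order, cutoff, btype=btype, fs=rate_hz, output="sos")


def _filtfilt(samples: np.ndarray, sos: np.ndarray) -> np.ndarray:
    # reflect padding keeps short annotated segments usable; transient at
    # order 4 is negligible past a pad length
    padlen = min(samples.shape[0] - 1, 3 * (2 * sos.shape[0] + 1) * 3)
    return sps.sosfiltfilt(sos, samples, axis=0, padlen=padlen)


def _apply(sig: UniformSignal, sos: np.ndarray, variant: str) -> UniformSignal:
    return sig.replace(samples=_filtfilt(sig.samples, sos), variant=variant)


def gravity_lowpass(
    sig: UniformSignal,
    cutoff_hz: float = _DEFAULT.gravity_lowpass_cutoff_hz,
    order: int = _DEFAULT.filter_order,
) -> UniformSignal:
    """Static (gravity/field) component: low-pass below the gait band.

    DC passes with unit gain; typical gait (>= 2 Hz) is attenuated below
    0.1 of its amplitude, so the window-mean vector tracks orientation.
    """
    return _apply(sig, _sos(order, cutoff_hz, "lowpass", sig.rate_hz), "gravity")


def dynamic_bandpass(
    sig: UniformSignal,
    band_hz: tuple[float, float] = _DEFAULT.bandpass_hz,
    order: int = _DEFAULT.filter_order,
) -> UniformSignal:
    """Dynamic component: band-pass retaining human gait periodicity.

    Rejects DC (gravity / static field) and high-frequency noise; applied to
    accelerometer, magnetometer and gyroscope alike.
    """
    return _apply(sig, _sos(order, list(band_hz), "bandpass", sig.rate_hz), "dynamic")


def pressure_highpass(
    sig: UniformSignal,
    cutoff_hz: float = _DEFAULT.pressure_highpass_cutoff_hz,
    order: int = _DEFAULT.filter_order,
) -> UniformSignal:
    """Remove slow atmospheric drift from barometric pressure.

    Weather-scale fluctuations (hours) are orders of magnitude below the
    cutoff and are suppressed; elevator/stair transients pass. Diagnostic
    only — altitude features are computed from raw pressure.
    """
    return _apply(sig, _sos(order, cutoff_hz, "highpass", sig.rate_hz), "detrended")


def light_lowpass(
    sig: UniformSignal,
    cutoff_hz: float = _DEFAULT.light_lowpass_cutoff_hz,
    order: int = _DEFAULT.filter_order,
) -> UniformSignal:
    """Smooth ambient light for the low-passed lux mean feature."""
    return _apply(sig, _sos(order, cutoff_hz, "lowpass", sig.rate_hz), "lowpass")


def measure_gain(
    make_filter, rate_hz: float, freq_hz: float, duration_s: float = 60.0
) -> float:
    """Empirical amplitude gain of a filter at one frequency.

    Runs a unit tone (or DC for freq 0) through ``make_filter`` applied to a
    UniformSignal and compares RMS amplitudes over the central half of the
    trace (edges excluded). Used by the filter-contract checks.
    """
    n = int(duration_s * rate_hz)
    t = np.arange(n) / rate_hz
    x = np.ones(n) if freq_hz == 0 else np.sin(2 * np.pi * freq_hz * t)
    sig = UniformSignal(device="phone", kind="accelerometer", rate_hz=rate_hz,
                        start_ms=0.0, samples=np.column_stack([x, x, x]))
    y = make_filter(sig).samples[:, 0]
    lo, hi = n // 4, 3 * n // 4
    if freq_hz == 0:
        return float(np.mean(y[lo:hi]))
    ref = np.sqrt(np.mean(x[lo:hi] ** 2))
    return float(np.sqrt(np.mean(y[lo:hi] ** 2)) / ref)
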