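"""Pipeline configuration: every numeric constant used by resampling,
filtering, windowing and modeling lives here so a run is fully described
by one object (and one YAML file via the CLI)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    """Numeric constants of the processing pipeline.

    Rates and cutoffs follow standard practice for human-gait signals:
    inertial sensors are linearly interpolated to a common 100 Hz, the slow
    sensors (pressure, light) to 10 Hz; the static (gravity) component is
    isolated below 0.6 Hz, the dynamic gait band is 0.6-7.5 Hz, and
    barometric drift below 0.1 Hz is removed before pressure diagnostics.
    """

    inertial_rate_hz: float = 100.0
    slow_rate_hz: float = 10.0  # pressure and light
    gravity_lowpass_cutoff_hz: float = 0.6
    bandpass_hz: tuple[float, float] = (0.6, 7.5)
    pressure_highpass_cutoff_hz: float = 0.1
    light_lowpass_cutoff_hz: float = 0.5
    filter_order: int = 4
    window_s: float = 2.0
    max_gap_ms: float = 2000.0  # hold-last-value threshold (one window)
    pca_variance: float = 0.95
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.bandpass_hz
        nyq = self.inertial_rate_hz / 2.0
        if not (0.0 < low < high < nyq):
            raise ValueError(
                f"band-pass edges ({low}, {high}) must satisfy 0 < low < high "
                f"< Nyquist ({nyq} Hz)"
            )
        if not (0.0 < self.gravity_lowpass_cutoff_hz < nyq):
            raise ValueError("gravity low-pass cutoff outside (0, Nyquist)")
        if not (0.0 < self.pressure_highpass_cutoff_hz < self.slow_rate_hz / 2.0):
            raise ValueError("pressure high-pass cutoff outside (0, Nyquist)")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "bandpass_hz" in d:
            d["bandpass_hz"] = tuple(d["bandpass_hz"])
        return cls(**d)
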