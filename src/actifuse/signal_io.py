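"""Raw sensor streams, annotations, CSV round-trip, gap filling and
resampling to the pipeline's fixed rates.

A recording directory holds one CSV per sensor
(``<device>_<kind>.csv`` with header ``t_ms,<channel names>``) and a
``segments.csv`` (``label,start_ms,end_ms,device,accepted``). Timestamps are
milliseconds since session start and must be strictly increasing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: the nine everyday activities plus the environment labels used by the
#: indoor/outdoor experiment
ACTIVITIES = (
    "walking",
    "running",
    "cycling",
    "standing",
    "sitting",
    "elevator_ascent",
    "elevator_descent",
    "stair_ascent",
    "stair_descent",
)
ENVIRONMENTS = ("indoor", "outdoor")

SENSOR_CHANNELS: dict[str, tuple[str, ...]] = {
    "accelerometer": ("x", "y", "z"),
    "magnetometer": ("x", "y", "z"),
    "gyroscope": ("x", "y", "z"),
    "pressure": ("hpa",),
    "light": ("lux",),
    "gps": ("bearing_deg", "speed_mps", "altitude_m", "satellite_count", "mean_snr"),
}

SENSOR_UNITS: dict[str, str] = {
    "accelerometer": "m/s^2",
    "magnetometer": "uT",
    "gyroscope": "rad/s",
    "pressure": "hPa",
    "light": "lux",
    "gps": "mixed",
}


@dataclass
class SensorStream:
    """One raw sensor's irregularly sampled, timestamped record.

    ``values`` is (n, channels); ``synthetic`` flags samples inserted by
    hold-last-value gap filling (all False for samples a device emitted).
    """

    device: str
    kind: str
    timestamps: np.ndarray  # ms since session start, strictly increasing
    values: np.ndarray  # (n, channels)
    synthetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in SENSOR_CHANNELS:
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            self.values = self.values.T
        n_chan = len(SENSOR_CHANNELS[self.kind])
        if self.values.shape != (self.timestamps.shape[0], n_chan):
            raise ValueError(
                f"{self.kind} stream expects {n_chan} channels, got shape "
                f"{self.values.shape}"
            )
        diffs = np.diff(self.timestamps)
        if diffs.size and not np.all(diffs > 0):
            bad = int(np.argmin(diffs > 0)) + 1
            raise ValueError(
                f"timestamps not strictly increasing at row {bad} "
                f"(t={self.timestamps[bad]:.3f} ms)"
            )
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.timestamps), dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def units(self) -> str:
        return SENSOR_UNITS[self.kind]

    @property
    def channel_names(self) -> tuple[str, ...]:
        return SENSOR_CHANNELS[self.kind]


@dataclass
class UniformSignal:
    """Fixed-rate multi-channel signal on a regular grid.

    Sample i sits at ``start_ms + i * 1000 / rate_hz``. ``variant`` tags a
    filtered derivative ("gravity", "dynamic", ...); "raw" is unfiltered.
    """

    device: str
    kind: str
    rate_hz: float
    start_ms: float
    samples: np.ndarray  # (n, channels)
    variant: str = "raw"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] < self.samples.shape[1] and self.samples.shape[0] == len(
            SENSOR_CHANNELS.get(self.kind, ())
        ):
            self.samples = self.samples.T

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(len(self)) * (1000.0 / self.rate_hz)

    @property
    def end_ms(self) -> float:
        return self.start_ms + (len(self) - 1) * (1000.0 / self.rate_hz)

    def key(self) -> str:
        return self.kind if self.variant == "raw" else f"{self.kind}_{self.variant}"

    def window(self, start_ms: float, duration_ms: float) -> np.ndarray | None:
        """Samples of the half-open interval [start_ms, start_ms+duration);
        None if the signal does not fully cover it."""
        step = 1000.0 / self.rate_hz
        i0 = int(round((start_ms - self.start_ms) / step))
        n = int(round(duration_ms / step))
        if i0 < 0 or i0 + n > len(self):
            return None
        return self.samples[i0 : i0 + n]

    def replace(self, **kw) -> "UniformSignal":
        return dataclasses.replace(self, **kw)


@dataclass
class ActivitySegment:
    """Labeled half-open interval [start_ms, end_ms) for one device."""

    label: str
    start_ms: float
    end_ms: float
    device: str
    accepted: bool = True

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("segment must have end_ms > start_ms")
        if self.label not in ACTIVITIES and self.label not in ENVIRONMENTS:
            raise ValueError(f"unknown activity label {self.label!r}")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_recording(
    directory: str | Path,
    streams: list[SensorStream],
    segments: list[ActivitySegment],
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in streams:
        df = pd.DataFrame(s.values, columns=list(s.channel_names))
        df.insert(0, "t_ms", s.timestamps)
        df.to_csv(directory / f"{s.device}_{s.kind}.csv", index=False)
    seg = pd.DataFrame(
        [
            {
                "label": g.label,
                "start_ms": g.start_ms,
                "end_ms": g.end_ms,
                "device": g.device,
                "accepted": g.accepted,
            }
            for g in segments
        ],
        columns=["label", "start_ms", "end_ms", "device", "accepted"],
    )
    seg.to_csv(directory / "segments.csv", index=False)


def read_recording(
    directory: str | Path,
) -> tuple[list[SensorStream], list[ActivitySegment]]:
    """Load every ``<device>_<kind>.csv`` plus ``segments.csv``.

    Streams are validated (monotone timestamps, channel counts); segments are
    returned sorted by start time. An empty segments file yields no segments.
    """
    directory = Path(directory)
    streams: list[SensorStream] = []
    for path in sorted(directory.glob("*_*.csv")):
        device, _, kind = path.stem.partition("_")
        if kind not in SENSOR_CHANNELS:
            raise ValueError(f"unknown sensor kind {kind!r} in {path.name}")
        df = pd.read_csv(path)
        streams.append(
            SensorStream(
                device=device,
                kind=kind,
                timestamps=df["t_ms"].to_numpy(float),
                values=df[list(SENSOR_CHANNELS[kind])].to_numpy(float),
            )
        )
    segments: list[ActivitySegment] = []
    seg_path = directory / "segments.csv"
    if seg_path.exists():
        seg = pd.read_csv(seg_path)
        for _, row in seg.iterrows():
            segments.append(
                ActivitySegment(
                    label=str(row["label"]),
                    start_ms=float(row["start_ms"]),
                    end_ms=float(row["end_ms"]),
                    device=str(row["device"]),
                    accepted=bool(row["accepted"]),
                )
            )
    segments.sort(key=lambda g: (g.device, g.start_ms))
    return streams, segments


# ---------------------------------------------------------------------------
# Gap filling and resampling
# ---------------------------------------------------------------------------

def fill_hold_last(
    stream: SensorStream,
    max_gap_ms: float,
    nominal_rate_hz: float | None = None,
    end_ms: float | None = None,
) -> SensorStream:
    """Fill gaps longer than ``max_gap_ms`` by repeating the last sample.

    Emulates a watch whose accelerometer powers down during sedentary bouts:
    the last known good value is held, at the nominal rate, until the next
    observed sample (or ``end_ms`` for a trailing power-down). Inserted
    samples carry ``synthetic=True``. Gaps shorter than the threshold are
    left to linear interpolation downstream.
    """
    if len(stream) == 0:
        raise ValueError("cannot gap-fill an empty stream")
    t = stream.timestamps
    if nominal_rate_hz is None:
        if len(t) < 2:
            raise ValueError("need nominal_rate_hz for a single-sample stream")
        nominal_rate_hz = 1000.0 / float(np.median(np.diff(t)))
    step = 1000.0 / nominal_rate_hz

    new_t = [t]
    new_v = [stream.values]
    new_s = [stream.synthetic]
    gaps = list(zip(t[:-1], t[1:]))
    if end_ms is not None and end_ms > t[-1]:
        gaps.append((t[-1], end_ms + step))  # trailing gap, fill through end
    for left, right in gaps:
        if right - left <= max_gap_ms:
            continue
        fill_t = np.arange(left + step, right - step / 2, step)
        if fill_t.size == 0:
            continue
        idx = int(np.searchsorted(t, left, side="right")) - 1
        new_t.append(fill_t)
        new_v.append(np.repeat(stream.values[idx : idx + 1], fill_t.size, axis=0))
        new_s.append(np.ones(fill_t.size, dtype=bool))
    order = np.argsort(np.concatenate(new_t), kind="stable")
    return SensorStream(
        device=stream.device,
        kind=stream.kind,
        timestamps=np.concatenate(new_t)[order],
        values=np.concatenate(new_v)[order],
        synthetic=np.concatenate(new_s)[order],
    )


def resample_linear(stream: SensorStream, target_rate_hz: float) -> UniformSignal:
    """Linearly interpolate an irregular stream onto a fixed-rate grid.

    The grid starts at the first raw timestamp and extends to the last; no
    extrapolation beyond the raw span. Exact on affine signals.
    """
    if target_rate_hz <= 0:
        raise ValueError("target rate must be positive")
    if len(stream) < 2:
        raise ValueError("need at least 2 samples to resample")
    step = 1000.0 / target_rate_hz
    t = stream.timestamps
    n = int(np.floor((t[-1] - t[0]) / step)) + 1
    grid = t[0] + np.arange(n) * step
    out = np.empty((n, stream.values.shape[1]))
    for c in range(stream.values.shape[1]):
        out[:, c] = np.interp(grid, t, stream.values[:, c])
    return UniformSignal(
        device=stream.device,
        kind=stream.kind,
        rate_hz=target_rate_hz,
        start_ms=float(t[0]),
        samples=out,
    )
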