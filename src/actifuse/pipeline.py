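"""End-to-end orchestration: raw streams to per-window feature tables.

Processing order per device:

1. hold-last-value gap filling (watch accelerometer power-downs);
2. linear resampling to the fixed rates (inertial 100 Hz, slow 10 Hz);
3. per accepted segment: slice, zero-phase filtering into gravity/dynamic
   (and raw pressure) variants, 2-s non-overlapping windowing;
4. feature computation per window into the device schema.

GPS is never resampled; it feeds the geo feature table separately.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import PipelineConfig
from .features_inertial import compute_phone_features, compute_watch_features
from .filters import dynamic_bandpass, gravity_lowpass
from .signal_io import SensorStream, UniformSignal, fill_hold_last, resample_linear
from .synthgen import Session
from .windowing import extract_windows

log = logging.getLogger(__name__)

PHONE_REQUIRED = (
    "accelerometer_gravity",
    "accelerometer_dynamic",
    "magnetometer_gravity",
    "magnetometer_dynamic",
    "gyroscope_dynamic",
    "pressure",
)
WATCH_REQUIRED = ("accelerometer_gravity", "accelerometer_dynamic")


def prepare_signals(
    streams: list[SensorStream],
    config: PipelineConfig,
    session_end_ms: float | None = None,
) -> dict[str, UniformSignal]:
    """Gap-fill and resample raw streams to the pipeline's fixed rates."""
    out: dict[str, UniformSignal] = {}
    for stream in streams:
        if stream.kind == "gps":
            continue  # aggregated per window, never interpolated
        filled = fill_hold_last(stream, config.max_gap_ms, end_ms=session_end_ms)
        rate = (
            config.inertial_rate_hz
            if stream.kind in ("accelerometer", "magnetometer", "gyroscope")
            else config.slow_rate_hz
        )
        out[stream.kind] = resample_linear(filled, rate)
    return out


def _segment_variants(
    raw: dict[str, UniformSignal],
    segment,
    config: PipelineConfig,
) -> list[UniformSignal]:
    """Slice each uniform signal to the segment and build filter variants.

    Filtering per segment (with reflect padding) keeps posture transitions
    from bleeding across annotation boundaries.
    """
    variants: list[UniformSignal] = []
    for kind, sig in raw.items():
        step = 1000.0 / sig.rate_hz
        i0 = max(0, int(round((segment.start_ms - sig.start_ms) / step)))
        # exclusive end: the sample at end_ms belongs to the next segment
        i1 = min(len(sig), int(round((segment.end_ms - sig.start_ms) / step)))
        if i1 - i0 < 2:
            continue
        piece = sig.replace(
            samples=sig.samples[i0:i1], start_ms=sig.start_ms + i0 * step
        )
        if kind in ("accelerometer", "magnetometer"):
            variants.append(gravity_lowpass(
                piece, config.gravity_lowpass_cutoff_hz, config.filter_order))
            variants.append(dynamic_bandpass(
                piece, config.bandpass_hz, config.filter_order))
        elif kind == "gyroscope":
            variants.append(dynamic_bandpass(
                piece, config.bandpass_hz, config.filter_order))
        else:  # pressure, light: raw slices (altitude needs absolute pressure)
            variants.append(piece)
    return variants


def extract_feature_table(
    streams: list[SensorStream],
    segments,
    device: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-window feature table for one device's streams and segments."""
    config = config or PipelineConfig()
    segments = [s for s in segments if s.device == device]
    if not segments:
        return pd.DataFrame()
    session_end = max(s.end_ms for s in segments)
    raw = prepare_signals(streams, config, session_end_ms=session_end)
    compute = compute_phone_features if device == "phone" else compute_watch_features
    required = PHONE_REQUIRED if device == "phone" else WATCH_REQUIRED
    rows = []
    n_rejected = 0
    for seg_id, seg in enumerate(sorted(segments, key=lambda s: s.start_ms)):
        if not seg.accepted:
            n_rejected += 1
            continue
        variants = _segment_variants(raw, seg, config)
        if not variants:
            # e.g. a leading watch power-down: no last value to hold yet
            log.info("%s: no signal coverage for segment %d (%s)",
                     device, seg_id, seg.label)
            continue
        windows = extract_windows(
            seg, variants, config.window_s, segment_id=seg_id, required=required
        )
        for w in windows:
            row = {
                "label": w.label,
                "device": w.device,
                "segment_id": w.segment_id,
                "window_index": w.index,
            }
            row.update(compute(w))
            rows.append(row)
    if n_rejected:
        log.info("%s: skipped %d rejected segments", device, n_rejected)
    return pd.DataFrame(rows)


def cohort_feature_tables(
    sessions: list[Session],
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Concatenated phone and watch feature tables over a cohort.

    Segment ids are offset per subject so (segment_id, window_index) stays
    a unique, deterministic row key.
    """
    config = config or PipelineConfig()
    tables: dict[str, list[pd.DataFrame]] = {"phone": [], "watch": []}
    offset = {"phone": 0, "watch": 0}
    for session in sessions:
        for device in tables:
            if device not in session.streams:
                continue
            df = extract_feature_table(
                session.streams[device], session.segments, device, config
            )
            if df.empty:
                continue
            df = df.copy()
            df["segment_id"] += offset[device]
            offset[device] = int(df["segment_id"].max()) + 1
            tables[device].append(df)
    return {
        device: (pd.concat(parts, ignore_index=True) if parts else pd.DataFrame())
        for device, parts in tables.items()
    }
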