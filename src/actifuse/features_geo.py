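"""GPS and ambient-light features per window, and the indoor/outdoor
detection experiment.

GPS fixes are never interpolated; they are aggregated per window. Indoors
the receiver loses lock, so an empty fix window is encoded as satellite
count 0 and SNR 0 — absence is itself the discriminative cue — while the
remaining fix fields are flagged missing. Bearings average circularly
(the arithmetic mean is wrong across the 0/360 wrap).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .filters import light_lowpass
from .signal_io import SensorStream, UniformSignal, resample_linear
from .windowing import Window  # noqa: F401  (same windowing grid)

GPS_FEATURES = (
    "mean_bearing_deg",
    "mean_speed_mps",
    "mean_altitude_m",
    "mean_sat_count",
    "mean_sat_snr",
)
LIGHT_FEATURES = ("raw_mean_lux", "lowpass_mean_lux", "mean_diff_lux")
GEO_FEATURES = GPS_FEATURES + LIGHT_FEATURES


def circular_mean_deg(bearings_deg: np.ndarray) -> float:
    """Vector mean of angles in degrees, result in [0, 360)."""
    b = np.radians(np.asarray(bearings_deg, float))
    ang = float(np.degrees(np.arctan2(np.mean(np.sin(b)), np.mean(np.cos(b)))) % 360.0)
    return 0.0 if ang >= 360.0 else ang


def gps_features(
    gps: SensorStream | None, start_ms: float, end_ms: float
) -> dict:
    """Aggregate the GPS fixes falling in [start_ms, end_ms).

    With no fixes (indoors / no lock): satellite count and SNR are 0, the
    other fields NaN (missing).
    """
    if gps is not None:
        m = (gps.timestamps >= start_ms) & (gps.timestamps < end_ms)
        fixes = gps.values[m]
    else:
        fixes = np.empty((0, 5))
    if fixes.shape[0] == 0:
        return {
            "mean_bearing_deg": float("nan"),
            "mean_speed_mps": float("nan"),
            "mean_altitude_m": float("nan"),
            "mean_sat_count": 0.0,
            "mean_sat_snr": 0.0,
        }
    return {
        "mean_bearing_deg": circular_mean_deg(fixes[:, 0]),
        "mean_speed_mps": float(np.mean(fixes[:, 1])),
        "mean_altitude_m": float(np.mean(fixes[:, 2])),
        "mean_sat_count": float(np.mean(fixes[:, 3])),
        "mean_sat_snr": float(np.mean(fixes[:, 4])),
    }


def light_features(
    raw: np.ndarray, lowpassed: np.ndarray
) -> dict:
    """Raw mean, low-passed mean and mean first difference of window lux."""
    raw = np.asarray(raw, float).ravel()
    lp = np.asarray(lowpassed, float).ravel()
    diff = float(np.mean(np.diff(raw))) if raw.size > 1 else 0.0
    return {
        "raw_mean_lux": float(np.mean(raw)),
        "lowpass_mean_lux": float(np.mean(lp)),
        "mean_diff_lux": diff,
    }


def build_geo_table(
    light_stream: SensorStream,
    gps_stream: SensorStream | None,
    segments,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-window geo feature table over labeled (indoor/outdoor) segments.

    Light is resampled to the slow rate and low-passed once; windows follow
    the same fixed non-overlapping grid as the activity pipeline.
    """
    config = config or PipelineConfig()
    light_raw = resample_linear(light_stream, config.slow_rate_hz)
    window_ms = config.window_s * 1000.0
    rows = []
    for seg_id, seg in enumerate(segments):
        if not seg.accepted:
            continue
        # low-pass per segment so an indoor/outdoor step at the boundary
        # does not smear into neighbouring windows
        step = 1000.0 / light_raw.rate_hz
        i0 = max(0, int(round((seg.start_ms - light_raw.start_ms) / step)))
        i1 = min(len(light_raw),
                 int(round((seg.end_ms - light_raw.start_ms) / step)))
        if i1 - i0 < 2:
            continue
        piece = light_raw.replace(samples=light_raw.samples[i0:i1],
                                  start_ms=light_raw.start_ms + i0 * step)
        light_lp = light_lowpass(piece, config.light_lowpass_cutoff_hz,
                                 config.filter_order)
        n = int(np.floor(seg.duration_ms / window_ms))
        for k in range(n):
            ws = seg.start_ms + k * window_ms
            raw = piece.window(ws, window_ms)
            lp = light_lp.window(ws, window_ms)
            if raw is None or lp is None:
                continue
            row = {"label": seg.label, "segment_id": seg_id, "window_index": k}
            row.update(gps_features(gps_stream, ws, ws + window_ms))
            row.update(light_features(raw, lp))
            rows.append(row)
    cols = ["label", "segment_id", "window_index", *GEO_FEATURES]
    return pd.DataFrame(rows, columns=cols)


ENVIRONMENT_SUBSETS = {
    "gps": list(GPS_FEATURES),
    "light": list(LIGHT_FEATURES),
    "fused": list(GEO_FEATURES),
}


def detect_environment(
    table: pd.DataFrame,
    classifier: str = "nb",
    config: PipelineConfig | None = None,
) -> dict:
    """Indoor/outdoor window classification with GPS-only, light-only and
    fused feature subsets.

    Returns ``{subset: EvalReport}`` under the modeling module's stratified
    CV protocol. Missing fix fields are imputed as 0 (no lock reads as
    "zero signal", which is the physical truth indoors).
    """
    from .modeling import train_eval

    config = config or PipelineConfig()
    classes = table["label"].value_counts()
    if len(classes) < 2:
        raise ValueError("need both indoor and outdoor windows")
    if classes.min() < 2:
        raise ValueError("need at least 2 windows per class")
    folds = int(min(config.cv_folds, classes.min()))
    out = {}
    for name, cols in ENVIRONMENT_SUBSETS.items():
        sub = table[["label", *cols]].copy()
        sub[cols] = sub[cols].fillna(0.0)  # no lock reads as zero signal
        out[name] = train_eval(
            sub, classifier, folds=folds, seed=config.seed,
            feature_columns=cols,
        )
    return out
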