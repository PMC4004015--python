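"""Cut accepted annotated segments into fixed-length, non-overlapping
windows across all synchronized signals."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .signal_io import ActivitySegment, UniformSignal

log = logging.getLogger(__name__)


@dataclass
class Window:
    """One fixed-length slice of every signal, labeled by its segment.

    ``signals`` maps a signal key (``kind`` or ``kind_variant``, e.g.
    ``accelerometer_dynamic``) to an (n, channels) array; ``rates`` gives the
    sampling rate of each key.
    """

    label: str
    device: str
    segment_id: int
    index: int
    start_ms: float
    duration_ms: float
    signals: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)

    def get(self, key: str) -> np.ndarray:
        if key not in self.signals:
            raise KeyError(f"window lacks signal {key!r}")
        return self.signals[key]


def extract_windows(
    segment: ActivitySegment,
    signals: list[UniformSignal],
    window_s: float = 2.0,
    segment_id: int = 0,
    required: tuple[str, ...] | None = None,
) -> list[Window]:
    """Non-overlapping contiguous windows of ``window_s`` seconds.

    The trailing remainder shorter than one window is discarded; a segment
    shorter than one window yields an empty list. Rejected segments yield no
    windows. Every window carries a slice of every signal; if ``required``
    keys are missing from a window (sensor outage at the segment edge) the
    window is dropped with a logged count. Signals that do not cover the
    segment at all are an error.
    """
    if not segment.accepted:
        return []
    if not signals:
        raise ValueError("no signals supplied")
    window_ms = window_s * 1000.0
    n_windows = int(np.floor(segment.duration_ms / window_ms))
    if n_windows == 0:
        return []
    for sig in signals:
        if sig.start_ms > segment.start_ms + window_ms or sig.end_ms < segment.start_ms:
            raise ValueError(
                f"signal {sig.key()!r} does not cover segment "
                f"[{segment.start_ms}, {segment.end_ms}) ms"
            )
    windows: list[Window] = []
    dropped = 0
    for k in range(n_windows):
        ws = segment.start_ms + k * window_ms
        slices, rates = {}, {}
        ok = True
        for sig in signals:
            arr = sig.window(ws, window_ms)
            if arr is None:
                ok = False
                break
            slices[sig.key()] = arr
            rates[sig.key()] = sig.rate_hz
        if not ok or (required and any(r not in slices for r in required)):
            dropped += 1
            continue
        windows.append(
            Window(
                label=segment.label,
                device=segment.device,
                segment_id=segment_id,
                index=k,
                start_ms=ws,
                duration_ms=window_ms,
                signals=slices,
                rates=rates,
            )
        )
    if dropped:
        log.info(
            "segment %d (%s): dropped %d/%d windows with incomplete coverage",
            segment_id, segment.label, dropped, n_windows,
        )
    return windows
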