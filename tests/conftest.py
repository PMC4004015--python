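import numpy as np
import pytest

from actifuse import PipelineConfig, simulate_session
from actifuse.pipeline import extract_feature_table
from actifuse.synthgen import DEFAULT_PROFILES
from actifuse.windowing import Window

RATE = 100.0
N = 200  # one 2-s window at 100 Hz


def tone(freq_hz, amp=1.0, n=N, rate=RATE, phase=0.0):
    t = np.arange(n) / rate
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


def make_window(signals: dict, rates: dict | None = None, label="walking") -> Window:
    """Assemble a Window from named (n, channels) arrays for feature tests."""
    rates = rates or {}
    sig2, r2 = {}, {}
    for key, arr in signals.items():
        arr = np.asarray(arr, float)
        if arr.ndim == 1:
            arr = arr[:, None] if key == "pressure" else np.column_stack([arr] * 3)
        sig2[key] = arr
        r2[key] = rates.get(key, RATE if key != "pressure" else 10.0)
    return Window(label=label, device="phone", segment_id=0, index=0,
                  start_ms=0.0, duration_ms=2000.0, signals=sig2, rates=r2)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def walking_session():
    return simulate_session([("walking", 60.0)], seed=7)


@pytest.fixture(scope="session")
def mixed_session():
    protocol = [
        ("walking", 30.0),
        ("sitting", 30.0),
        ("running", 20.0),
        ("standing", 20.0),
        ("elevator_ascent", 20.0),
        ("stair_descent", 20.0),
    ]
    return simulate_session(protocol, seed=11)


@pytest.fixture(scope="session")
def mixed_phone_table(mixed_session, config):
    return extract_feature_table(
        mixed_session.streams["phone"], mixed_session.segments, "phone", config
    )


@pytest.fixture(scope="session")
def mixed_watch_table(mixed_session, config):
    return extract_feature_table(
        mixed_session.streams["watch"], mixed_session.segments, "watch", config
    )


@pytest.fixture(scope="session")
def nine_class_table(config):
    """A small balanced-ready table covering all nine activities."""
    protocol = [(label, 24.0) for label in DEFAULT_PROFILES]
    session = simulate_session(protocol, seed=5)
    return extract_feature_table(
        session.streams["phone"], session.segments, "phone", config
    )
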