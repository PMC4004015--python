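"""Generator contracts: determinism, spectral and rate fidelity, posture
physics, watch dropout, and indoor/outdoor contrast."""

import numpy as np
import pytest
from scipy import signal as sps

from actifuse import simulate_session, simulate_transition_walk
from actifuse.filters import dynamic_bandpass
from actifuse.signal_io import resample_linear
from actifuse.synthgen import (
    DEFAULT_PROFILES,
    PHONE_SPEC,
    WATCH_SPEC,
    ActivityProfile,
    altitude_from_pressure,
    pressure_from_altitude,
)


def test_empty_protocol_rejected():
    with pytest.raises(ValueError):
        simulate_session([], seed=0)


def test_unknown_label_rejected():
    with pytest.raises(ValueError):
        simulate_session([("moonwalking", 10.0)], seed=0)
    with pytest.raises(ValueError):
        ActivityProfile("moonwalking")


def test_nonpositive_duration_rejected():
    with pytest.raises(ValueError):
        simulate_session([("walking", 0.0)], seed=0)
    with pytest.raises(ValueError):
        simulate_transition_walk(-1.0, 60.0, seed=0)


def test_same_seed_bit_identical(mixed_session):
    protocol = [(p, d) for p, d in mixed_session.protocol]
    again = simulate_session(protocol, seed=mixed_session.seed)
    for device, streams in mixed_session.streams.items():
        other = {s.kind: s for s in again.streams[device]}
        assert set(other) == {s.kind for s in streams}
        for s in streams:
            assert np.array_equal(s.timestamps, other[s.kind].timestamps)
            assert np.array_equal(s.values, other[s.kind].values)


def test_different_seed_differs(walking_session):
    other = simulate_session([("walking", 60.0)], seed=8)
    acc_a = next(s for s in walking_session.streams["phone"]
                 if s.kind == "accelerometer")
    acc_b = next(s for s in other.streams["phone"] if s.kind == "accelerometer")
    assert not np.array_equal(acc_a.values, acc_b.values)


@pytest.mark.parametrize("device_spec", [PHONE_SPEC, WATCH_SPEC],
                         ids=["phone", "watch"])
def test_sampling_rate_fidelity(walking_session, device_spec):
    """Empirical median sampling interval within 10% of nominal."""
    for stream in walking_session.streams[device_spec.device]:
        if stream.kind == "gps":
            continue
        nominal_ms = 1000.0 / device_spec.rates_hz[stream.kind]
        median = np.median(np.diff(stream.timestamps))
        assert abs(median - nominal_ms) < 0.1 * nominal_ms, stream.kind


def test_segments_partition_protocol(mixed_session):
    for device in ("phone", "watch"):
        segs = sorted(
            (s for s in mixed_session.segments if s.device == device),
            key=lambda s: s.start_ms,
        )
        assert [s.label for s in segs] == [p.label for p, _ in mixed_session.protocol]
        assert segs[0].start_ms == 0.0
        for a, b in zip(segs, segs[1:]):
            assert a.end_ms == b.start_ms


def test_static_posture_has_no_gait_band_power():
    """Band-passed accelerometer power while sitting stays at the noise
    floor (< 3x the band-passed noise variance)."""
    session = simulate_session([("sitting", 60.0)], seed=7)
    acc = next(s for s in session.streams["phone"] if s.kind == "accelerometer")
    uni = resample_linear(acc, 100.0)
    band = dynamic_bandpass(uni)
    power = np.mean(band.samples**2)
    sd = PHONE_SPEC.noise_sd["accelerometer"]
    assert power < 3 * sd**2


def test_walking_fundamental_recoverable(walking_session):
    """Periodogram of the band-passed Y axis peaks within one bin of the
    configured 2.0 Hz cadence (oracle: direct periodogram of the trace)."""
    acc = next(s for s in walking_session.streams["phone"]
               if s.kind == "accelerometer")
    band = dynamic_bandpass(resample_linear(acc, 100.0))
    freqs, pxx = sps.periodogram(band.samples[:, 1], fs=100.0)
    peak = freqs[np.argmax(pxx)]
    assert abs(peak - 2.0) <= freqs[1] - freqs[0] + 1e-9


def test_watch_dropout_contract(mixed_session):
    """Sedentary bouts emit zero watch samples; dynamic bouts never gap by
    more than twice the nominal interval."""
    acc = next(s for s in mixed_session.streams["watch"]
               if s.kind == "accelerometer")
    t_s = acc.timestamps / 1000.0
    t0 = 0.0
    for prof, dur in mixed_session.protocol:
        inside = (t_s >= t0) & (t_s < t0 + dur)
        if prof.sedentary:
            assert inside.sum() == 0, prof.label
        else:
            tt = np.concatenate([[t0], t_s[inside], [t0 + dur]])
            assert np.max(np.diff(tt)) <= 2.0 / WATCH_SPEC.rates_hz["accelerometer"]
        t0 += dur


def test_barometric_formula_round_trip():
    assert pressure_from_altitude(0.0) == pytest.approx(1013.25)
    h = np.array([0.0, 10.0, 100.0, 500.0])
    assert altitude_from_pressure(pressure_from_altitude(h)) == pytest.approx(h)
    with pytest.raises(ValueError):
        altitude_from_pressure(-5.0)


def test_elevator_pressure_tracks_altitude():
    session = simulate_session([("standing", 10.0), ("elevator_ascent", 30.0)],
                               seed=3)
    press = next(s for s in session.streams["phone"] if s.kind == "pressure")
    h = altitude_from_pressure(press.values[:, 0])
    start = h[press.timestamps < 10_000].mean()
    end = h[press.timestamps > 38_000].mean()
    profile = DEFAULT_PROFILES["elevator_ascent"]
    expected = profile.altitude_rate_m_per_s * (30.0 - 3.0)  # trapezoid ramps
    assert end - start == pytest.approx(expected, rel=0.1)


def test_transition_walk_contrast():
    walk = simulate_transition_walk(300.0, 300.0, seed=1)
    lux = walk.light.values[:, 0]
    indoor = walk.light.timestamps < walk.transition_ms
    assert lux[~indoor].mean() > lux[indoor].mean()
    assert walk.gps is not None
    # no fixes indoors: satellite visibility exists only outdoors
    assert np.all(walk.gps.timestamps >= walk.transition_ms)
    assert walk.gps.values[:, 3].mean() > 5
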