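"""Toss/snore detectors against brute-force scans, CO2 bands, heart-rate
runs and temperature artifact masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import somnokit as sk
from somnokit.events import Co2Band

from _oracles import (naive_snore_scan, naive_toss_scan,
                      random_pressure_stream, random_sound_stream)


# ---------------------------------------------------------------------------
# frame delta (the movement statistic)

def test_frame_delta_hand_values():
    zero = np.zeros(8)
    burst = np.array([1, 2, 3, 0, 0, 0, 0, 0], dtype=float)
    assert sk.frame_delta(burst, burst) == 0.0
    assert sk.frame_delta(burst, zero) == 6.0
    assert sk.frame_delta(zero, burst) == 6.0  # symmetric in its arguments


def test_frame_delta_accepts_frames():
    a = sk.PressureFrame(t=1, p=(1, 0, 0, 0, 0, 0, 0, 0))
    b = sk.PressureFrame(t=0, p=(0, 0, 0, 0, 0, 0, 0, 2))
    assert sk.frame_delta(a, b) == 3.0


# ---------------------------------------------------------------------------
# toss-and-turn

def _flat(n=60, level=20.0):
    return np.full((n, 8), level)


def test_flat_stream_no_events():
    assert sk.detect_toss_turn(_flat(), sk.TossTurnParams(threshold=5.0)) == []


def test_single_burst_matches_closing_rule():
    p = _flat(60)
    p[10:13] += 100.0  # movement during seconds 10..12
    events = sk.detect_toss_turn(p, sk.TossTurnParams(threshold=50.0))
    naive = naive_toss_scan(p, 50.0, 5)
    assert [(e.start, e.end) for e in events] == naive == [(10, 14)]
    assert events[0].attrs["peak_delta"] == pytest.approx(800.0)


def test_burst_merging_depends_on_gap():
    near = _flat(80)
    near[10:12] += 100.0
    near[14:16] += 100.0   # 2 s quiet gap < quiescence: one event
    far = _flat(80)
    far[10:12] += 100.0
    far[26:28] += 100.0    # 14 s gap: two events
    p1 = sk.detect_toss_turn(near, sk.TossTurnParams(threshold=50.0))
    p2 = sk.detect_toss_turn(far, sk.TossTurnParams(threshold=50.0))
    assert len(p1) == 1 and len(p2) == 2
    assert [(e.start, e.end) for e in p1] == naive_toss_scan(near, 50.0, 5)
    assert [(e.start, e.end) for e in p2] == naive_toss_scan(far, 50.0, 5)


def test_sub_threshold_movement_never_opens():
    p = _flat(60)
    p[20:25] += 1.0
    assert sk.detect_toss_turn(p, sk.TossTurnParams(threshold=50.0)) == []


def test_events_invariant_under_quiet_padding():
    rng = np.random.default_rng(0)
    p = random_pressure_stream(rng, n=300)
    thr = 200.0
    base = [e.start for e in
            sk.detect_toss_turn(p, sk.TossTurnParams(threshold=thr))]
    pad = np.tile(p[:1], (30, 1))
    padded = np.vstack([pad, p, np.tile(p[-1:], (30, 1))])
    shifted = [e.start - 30 for e in
               sk.detect_toss_turn(padded, sk.TossTurnParams(threshold=thr))]
    assert base == shifted


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_toss_oracle_equivalence_random_streams(seed):
    """Detector output equals an independent brute-force per-second scan."""
    rng = np.random.default_rng(seed)
    p = random_pressure_stream(rng, n=240)
    thr = float(rng.uniform(100, 300))
    q = int(rng.integers(1, 8))
    events = sk.detect_toss_turn(
        p, sk.TossTurnParams(threshold=thr, quiescence=q,
                             merge_within_posture=False))
    assert [(e.start, e.end) for e in events] == naive_toss_scan(p, thr, q)
    assert sk.validate_events(events) == []


# ---------------------------------------------------------------------------
# snoring

def test_below_threshold_sound_no_events():
    assert sk.detect_snore_events(np.full(60, 25.0)) == []


def test_three_bursts_record_intervals():
    s = np.full(20, 25.0)
    for t0 in (0, 5, 10):
        s[t0:t0 + 2] = 40.0
    events = sk.detect_snore_events(s)
    assert [(e.start, e.end) for e in events] == [(0, 2), (5, 7), (10, 12)]
    assert "interval_s" not in events[0].attrs
    assert [e.attrs["interval_s"] for e in events[1:]] == [5.0, 5.0]
    assert all(e.attrs["peak_db"] == 40.0 for e in events)


def test_continuous_sound_truncated_at_capture_and_rearmed():
    s = np.full(20, 40.0)
    events = sk.detect_snore_events(s)
    assert [(e.start, e.end) for e in events] == [(0, 15), (17, 20)]


def test_rearm_delay_suppresses_immediate_retrigger():
    s = np.full(10, 25.0)
    s[0:2] = 40.0
    s[3] = 40.0   # within the 2 s re-arm window after close at t=2
    events = sk.detect_snore_events(s)
    assert [(e.start, e.end) for e in events] == [(0, 2)]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_snore_oracle_equivalence_random_streams(seed):
    rng = np.random.default_rng(seed)
    s = random_sound_stream(rng, n=240)
    params = sk.SnoreParams(db_threshold=30.0,
                            max_capture=int(rng.integers(2, 20)),
                            rearm_delay=int(rng.integers(0, 5)))
    events = sk.detect_snore_events(s, params)
    naive = naive_snore_scan(s, 30.0, params.max_capture, params.rearm_delay)
    assert [(e.start, e.end) for e in events] == naive
    assert sk.validate_events(events) == []


# ---------------------------------------------------------------------------
# snore regularity

def _snores_at(onsets):
    return [sk.Event(sk.EventKind.SNORE, t, t + 1) for t in onsets]


def test_perfectly_regular_intervals_cv_zero():
    events = _snores_at(np.arange(0, 30, 3))
    cv, flags = sk.snore_regularity(events)
    assert cv[5] == 0.0 and flags[5] is True


def test_irregular_intervals_hand_cv():
    # intervals 2, 8, 3, 12, 5: mean 6, population std sqrt(66/5)
    events = _snores_at(np.cumsum([0, 2, 8, 3, 12, 5]))
    cv, flags = sk.snore_regularity(events)
    assert cv[5] == pytest.approx(np.sqrt(66 / 5) / 6)
    assert flags[5] is False


def test_too_few_events_flag_undefined():
    events = _snores_at([0, 3, 6])
    cv, flags = sk.snore_regularity(events)
    assert all(f is None for f in flags)
    assert np.isnan(cv).all()


# ---------------------------------------------------------------------------
# CO2 banding

@pytest.mark.parametrize("ppm, band", [
    (0, Co2Band.GOOD), (350, Co2Band.GOOD), (399.9, Co2Band.GOOD),
    (400, Co2Band.AVERAGE), (699.9, Co2Band.AVERAGE),
    (700, Co2Band.POOR), (999.9, Co2Band.POOR),
    (1000, Co2Band.VERY_POOR), (1200, Co2Band.VERY_POOR),
])
def test_co2_band_boundaries_left_closed(ppm, band):
    assert sk.classify_co2(ppm) == band


def test_co2_negative_rejected():
    with pytest.raises(sk.ValidationError):
        sk.classify_co2(-1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=0, max_value=5000), st.floats(min_value=0, max_value=5000))
def test_co2_total_monotone_step(a, b):
    order = [Co2Band.GOOD, Co2Band.AVERAGE, Co2Band.POOR, Co2Band.VERY_POOR]
    lo, hi = sorted((a, b))
    assert order.index(sk.classify_co2(lo)) <= order.index(sk.classify_co2(hi))


# ---------------------------------------------------------------------------
# heart rate

def test_normal_heart_rate_no_events():
    assert sk.annotate_heart_rate(np.full(120, 70.0)) == []


def test_bradycardia_run_detected():
    hr = np.full(120, 70.0)
    hr[30:90] = 59.0
    events = sk.annotate_heart_rate(hr)
    assert len(events) == 1
    e = events[0]
    assert (e.kind, e.start, e.end) == (sk.EventKind.BRADYCARDIA, 30, 90)


def test_strict_boundaries_60_and_100():
    hr = np.full(60, 60.0)   # not < 60
    hr[30:] = 100.0          # not > 100
    assert sk.annotate_heart_rate(hr) == []


def test_short_flicker_suppressed():
    hr = np.full(60, 70.0)
    hr[10:13] = 55.0  # 3 s < min_duration 5 s
    assert sk.annotate_heart_rate(hr) == []
    hr2 = np.full(60, 70.0)
    hr2[10:16] = 110.0
    assert [e.kind for e in sk.annotate_heart_rate(hr2)] == \
        [sk.EventKind.TACHYCARDIA]


def test_absent_channel_errors():
    with pytest.raises(sk.ValidationError, match="absent"):
        sk.annotate_heart_rate(None)


# ---------------------------------------------------------------------------
# temperature artifact masking

def test_no_posture_changes_no_flags():
    temp = np.full(200, 36.5)
    masked, flags = sk.mask_temp_artifacts(temp, [])
    assert not flags.any() and np.array_equal(masked, temp)


def test_flag_window_interval_arithmetic():
    temp = np.full(200, 36.5)
    change = [sk.Event(sk.EventKind.POSTURE_CHANGE, 100, 101)]
    _, flags = sk.mask_temp_artifacts(temp, change, pad=30)
    assert set(np.nonzero(flags)[0]) == set(range(70, 131))


def test_simulated_dips_inside_flagged_regions(default_night):
    session, truth = default_night
    changes = truth.events(sk.EventKind.POSTURE_CHANGE)
    masked, flags = sk.mask_temp_artifacts(session.body_temp, changes)
    dip = session.body_temp < 35.0
    assert not dip[~flags].any()   # every injected dip is masked
    valid = masked[np.isfinite(masked)]
    assert valid.min() > 35.0
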