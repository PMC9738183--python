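"""Synthetic full-night sleep sessions with ground truth.

Generates 1 Hz multi-channel recordings whose signal structure mirrors
what the pillow/sound/temperature/CO2/heart-rate sensor suite observes
over a night:

* a hypnogram of alternating NREM/REM blocks per ~90 min cycle, with the
  REM fraction growing across the night and a terminal wake tail;
* posture-dependent pressure profiles over the 8 sensors, with movement
  transients at posture changes and light toss-and-turn bursts placed in
  REM/wake;
* snore bursts above a quiet-room floor — onset intervals ~3 s with small
  jitter during NREM (regular) and longer, heavily jittered intervals
  during REM (irregular);
* stage-conditioned heart rate (slow and stable in NREM, elevated and
  variable in REM) with injected bradycardia/tachycardia episodes;
* CO2 drifting upward overnight with small bumps during snoring;
* contactless body temperature with spurious dips (33.5-34.0 °C) at
  posture changes; a 22-23 °C room, humidity and illuminance.

Every injected event is recorded in the returned ground truth, so each
detector in the pipeline can be scored against what was actually put in.
All randomness flows from one seed through named substreams (one per
channel), so adding a channel never perturbs another channel's draws and
a fixed (params, seed) pair reproduces the session bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .posture import PostureSegment, extract_features
from .streams import (Event, EventKind, Hypnogram, Posture, SessionRecord,
                      Stage, ValidationError)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_hypnogram",
    "simulate_session",
    "simulate_night",
    "make_posture_training_set",
    "POSTURE_PROFILES",
]

#: mean pressure profile over the 8 sensors for each lying posture
#: (arbitrary force units; supine mass is centered, left/right shifted)
POSTURE_PROFILES: dict[Posture, tuple[float, ...]] = {
    Posture.SUPINE: (2, 10, 40, 85, 85, 40, 10, 2),
    Posture.LEFT: (60, 95, 55, 18, 5, 1, 0, 0),
    Posture.RIGHT: (0, 0, 1, 5, 18, 55, 95, 60),
}


@dataclass
class SimulationParams:
    """Generative parameters; the defaults define the study conditions."""

    duration_s: int = 21600           # 6 h night
    epoch_len: int = 60
    cycle_len_s: int = 5400           # ~90 min sleep cycle
    rem_frac_start: float = 0.15      # REM fraction of the first cycle
    rem_frac_end: float = 0.35        # ... and of the last
    wake_epochs: int = 2              # terminal wake tail

    # posture / movement
    posture_change_rate_per_rem_h: float = 2.0
    light_movement_rate_per_rem_h: float = 90.0
    pressure_noise_sd: float = 5.0
    head_shift_sd: float = 1.0        # head-position jitter, sensor units (~4.4 cm pitch)
    amp_jitter_sd: float = 0.1        # lognormal sd of per-window contact pressure
    transient_s: int = 4              # posture-change transient length
    transient_amp: float = 120.0      # movement fluctuation amplitude
    movement_min_gap_s: int = 10      # onset separation so bursts stay distinct
    movement_burst_max_s: int = 3     # light-movement burst length (1..max)

    # snoring
    snore_nrem_interval_s: float = 3.0
    snore_nrem_jitter_sd: float = 0.3
    snore_rem_interval_s: float = 6.0
    snore_rem_jitter_sd: float = 4.0
    snore_min_interval_s: float = 3.0  # keeps bursts separable under re-arm
    snore_burst_db_mean: float = 40.0
    snore_burst_db_sd: float = 3.0
    snore_max_burst_s: int = 3
    sound_floor_db: float = 25.0
    sound_floor_noise_sd: float = 1.0

    # heart rate
    hr_nrem_mean: float = 58.0
    hr_nrem_sd: float = 2.0
    hr_rem_mean: float = 75.0
    hr_rem_sd: float = 8.0
    hr_wake_mean: float = 80.0
    hr_wake_sd: float = 6.0
    brady_episodes_per_night: float = 2.0
    tachy_episodes_per_night: float = 1.0
    episode_duration_s: int = 60

    # environment
    co2_start_ppm: float = 450.0
    co2_drift_ppm_per_h: float = 60.0
    co2_snore_bump_ppm: float = 10.0
    co2_noise_sd: float = 5.0
    body_temp_c: float = 36.5
    body_temp_noise_sd: float = 0.08
    dip_low_c: float = 33.5
    dip_high_c: float = 34.0
    dip_len_s: int = 10
    room_temp_start_c: float = 23.0
    room_temp_end_c: float = 22.0
    room_temp_noise_sd: float = 0.05
    humidity_pct: float = 45.0
    humidity_noise_sd: float = 1.0
    lux_mean: float = 10.0
    lux_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("pressure_noise_sd", "head_shift_sd", "amp_jitter_sd",
                     "snore_nrem_jitter_sd", "snore_rem_jitter_sd",
                     "snore_burst_db_sd", "sound_floor_noise_sd",
                     "hr_nrem_sd", "hr_rem_sd", "hr_wake_sd",
                     "co2_noise_sd", "body_temp_noise_sd",
                     "room_temp_noise_sd", "humidity_noise_sd",
                     "lux_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("rem_frac_start", "rem_frac_end"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")

    def noise_free(self) -> "SimulationParams":
        """Copy with every noise sd, drift and event rate zeroed."""
        return replace(
            self, pressure_noise_sd=0.0, head_shift_sd=0.0, amp_jitter_sd=0.0,
            snore_nrem_jitter_sd=0.0, snore_rem_jitter_sd=0.0,
            snore_burst_db_sd=0.0, sound_floor_noise_sd=0.0,
            hr_nrem_sd=0.0, hr_rem_sd=0.0, hr_wake_sd=0.0,
            co2_noise_sd=0.0, co2_drift_ppm_per_h=0.0,
            body_temp_noise_sd=0.0, room_temp_noise_sd=0.0,
            room_temp_start_c=self.room_temp_end_c,
            humidity_noise_sd=0.0, lux_noise_sd=0.0,
            posture_change_rate_per_rem_h=0.0,
            light_movement_rate_per_rem_h=0.0,
            brady_episodes_per_night=0.0, tachy_episodes_per_night=0.0)


@dataclass
class GroundTruth:
    """Everything the simulator injected, for scoring the detectors."""

    hypnogram: Hypnogram
    posture_schedule: list[PostureSegment]
    injected_events: dict[str, list[Event]]
    params: SimulationParams

    def events(self, kind: EventKind) -> list[Event]:
        return self.injected_events.get(kind.value, [])


#: fixed substream order; append-only so existing channels keep their draws
_SUBSTREAMS = ("posture", "movement", "pressure", "snore", "hr", "co2",
               "body_temp", "room_temp", "humidity", "lux")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_SUBSTREAMS, children)}


def simulate_hypnogram(params: SimulationParams | None = None,
                       seed: int = 0) -> Hypnogram:
    """Build the ground-truth hypnogram: NREM then REM per cycle, REM
    fraction interpolating across cycles, terminal wake epochs.

    The block layout is a deterministic function of the parameters; the
    seed is accepted for interface symmetry with the other generators.
    """
    params = params or SimulationParams()
    if params.duration_s < params.cycle_len_s:
        raise ValidationError("duration must cover at least one cycle")
    n_epochs = params.duration_s // params.epoch_len
    epc = params.cycle_len_s // params.epoch_len
    n_cycles = max(1, n_epochs // epc)
    labels: list[Stage] = []
    for c in range(n_cycles):
        cycle_epochs = epc if c < n_cycles - 1 else n_epochs - epc * (n_cycles - 1)
        frac = (params.rem_frac_start if n_cycles == 1 else
                params.rem_frac_start
                + (params.rem_frac_end - params.rem_frac_start) * c / (n_cycles - 1))
        rem = int(np.round(frac * cycle_epochs))
        labels.extend([Stage.NREM] * (cycle_epochs - rem) + [Stage.REM] * rem)
    for k in range(1, min(params.wake_epochs, len(labels)) + 1):
        labels[-k] = Stage.WAKE
    return Hypnogram(labels=labels, epoch_len=params.epoch_len)


def _stage_per_second(hyp: Hypnogram, n: int) -> np.ndarray:
    return np.array([s.value for s in hyp.stage_per_second(n)])


def _shifted_profile(base: np.ndarray, shift: float) -> np.ndarray:
    idx = np.arange(base.size, dtype=float)
    return np.interp(idx - shift, idx, base, left=0.0, right=0.0)


def _poisson_times(rng: np.random.Generator, candidate_secs: np.ndarray,
                   rate_per_h: float, min_gap: int,
                   forbidden: Sequence[int] = ()) -> list[int]:
    """Place events at the given rate on candidate seconds, thinned to a
    minimum onset separation (also from `forbidden` onsets)."""
    if candidate_secs.size == 0 or rate_per_h <= 0:
        return []
    n_events = rng.poisson(rate_per_h * candidate_secs.size / 3600.0)
    if n_events == 0:
        return []
    picks = np.sort(rng.choice(candidate_secs,
                               size=min(n_events, candidate_secs.size),
                               replace=False))
    out: list[int] = []
    taken = sorted(forbidden)
    for t in picks:
        t = int(t)
        if out and t - out[-1] < min_gap:
            continue
        if any(abs(t - f) < min_gap for f in taken):
            continue
        out.append(t)
    return out


def simulate_session(
    truth_hypnogram: Hypnogram | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> tuple[SessionRecord, GroundTruth]:
    """Render a full SessionRecord from a hypnogram, with ground truth."""
    params = params or SimulationParams()
    hyp = truth_hypnogram or simulate_hypnogram(params, seed)
    n = min(params.duration_s, hyp.n_epochs * hyp.epoch_len)
    stage = _stage_per_second(hyp, n)
    rngs = _rngs(seed)

    rem_wake = np.nonzero((stage == Stage.REM.value)
                          | (stage == Stage.WAKE.value))[0]
    sleep_mask = stage != Stage.WAKE.value

    # --- posture schedule -------------------------------------------------
    rng = rngs["posture"]
    # keep changes clear of the session edges and of each other so the
    # discrimination cycle can recover every segment
    min_sep = max(120, 3 * params.transient_s)
    candidates = rem_wake[(rem_wake > min_sep) & (rem_wake < n - min_sep)]
    change_times = _poisson_times(rng, candidates,
                                  params.posture_change_rate_per_rem_h,
                                  min_gap=min_sep)
    lying = [Posture.SUPINE, Posture.LEFT, Posture.RIGHT]
    schedule: list[PostureSegment] = []
    posture_changes: list[Event] = []
    current = Posture.SUPINE
    prev_t = 0
    for c in change_times:
        schedule.append(PostureSegment(current, prev_t, c))
        nxt = lying[rng.integers(0, 3)]
        while nxt == current:
            nxt = lying[rng.integers(0, 3)]
        posture_changes.append(Event(EventKind.POSTURE_CHANGE, c, c + 1,
                                     attrs={"from": current.value,
                                            "to": nxt.value}))
        current, prev_t = nxt, c
    schedule.append(PostureSegment(current, prev_t, n))

    # --- movement bursts --------------------------------------------------
    rng = rngs["movement"]
    burst_starts = _poisson_times(
        rng, rem_wake[(rem_wake > 1) & (rem_wake < n - params.transient_s - 1)],
        params.light_movement_rate_per_rem_h,
        min_gap=params.movement_min_gap_s,
        forbidden=change_times)
    toss_events: list[Event] = []
    movement_secs = np.zeros(n, dtype=bool)
    for c in change_times:  # posture-change transients are movements too
        end = min(c + params.transient_s, n)
        movement_secs[c:end] = True
        toss_events.append(Event(EventKind.TOSS_TURN, c, end,
                                 attrs={"cause": "posture_change"}))
    for b in burst_starts:
        dur = int(rng.integers(1, params.movement_burst_max_s + 1))
        end = min(b + dur, n)
        movement_secs[b:end] = True
        toss_events.append(Event(EventKind.TOSS_TURN, b, end,
                                 attrs={"cause": "light_movement"}))
    toss_events.sort(key=lambda e: e.start)

    # --- pressure ---------------------------------------------------------
    rng = rngs["pressure"]
    pressure = np.zeros((n, 8))
    for seg in schedule:
        base = np.asarray(POSTURE_PROFILES[seg.posture], dtype=float)
        shift = rng.normal(0.0, params.head_shift_sd) \
            if params.head_shift_sd > 0 else 0.0
        amp = float(np.exp(rng.normal(0.0, params.amp_jitter_sd))) \
            if params.amp_jitter_sd > 0 else 1.0
        pressure[seg.start:seg.end] = amp * _shifted_profile(base, shift)
    if params.pressure_noise_sd > 0:
        pressure += rng.normal(0.0, params.pressure_noise_sd, size=pressure.shape)
    m = int(movement_secs.sum())
    if m:
        pressure[movement_secs] += rng.uniform(0.0, params.transient_amp,
                                               size=(m, 8))
    np.clip(pressure, 0.0, None, out=pressure)

    # --- snoring ----------------------------------------------------------
    rng = rngs["snore"]
    sound = np.full(n, params.sound_floor_db)
    if params.sound_floor_noise_sd > 0:
        sound += rng.normal(0.0, params.sound_floor_noise_sd, size=n)
    snore_events: list[Event] = []
    snore_active = np.zeros(n, dtype=bool)
    # one point process per contiguous sleep block, stage-conditioned
    block_start = 0
    for t in range(1, n + 1):
        if t == n or stage[t] != stage[block_start]:
            blk_stage = stage[block_start]
            if blk_stage in (Stage.NREM.value, Stage.REM.value):
                if blk_stage == Stage.NREM.value:
                    mean, sd = (params.snore_nrem_interval_s,
                                params.snore_nrem_jitter_sd)
                else:
                    mean, sd = (params.snore_rem_interval_s,
                                params.snore_rem_jitter_sd)
                pos = float(block_start) + 1.0
                onsets: list[int] = []
                while True:
                    gap = max(params.snore_min_interval_s,
                              rng.normal(mean, sd) if sd > 0 else mean)
                    pos += gap
                    if pos >= t - 1:
                        break
                    onsets.append(int(np.floor(pos)))
                for i, onset in enumerate(onsets):
                    gap_next = (onsets[i + 1] - onset if i + 1 < len(onsets)
                                else params.snore_max_burst_s + 3)
                    dur = int(min(rng.integers(1, params.snore_max_burst_s + 1),
                                  max(1, gap_next - 3)))
                    end = min(onset + dur, t)
                    db = float(rng.normal(params.snore_burst_db_mean,
                                          params.snore_burst_db_sd)) \
                        if params.snore_burst_db_sd > 0 \
                        else params.snore_burst_db_mean
                    sound[onset:end] = db
                    snore_active[onset:end] = True
                    attrs = {"peak_db": db, "stage": blk_stage}
                    if snore_events:
                        attrs["interval_s"] = float(onset - snore_events[-1].start)
                    snore_events.append(Event(EventKind.SNORE, onset, end,
                                              attrs=attrs))
            if t < n:
                block_start = t

    # --- heart rate -------------------------------------------------------
    rng = rngs["hr"]
    means = {Stage.NREM.value: params.hr_nrem_mean,
             Stage.REM.value: params.hr_rem_mean,
             Stage.WAKE.value: params.hr_wake_mean}
    sds = {Stage.NREM.value: params.hr_nrem_sd,
           Stage.REM.value: params.hr_rem_sd,
           Stage.WAKE.value: params.hr_wake_sd}
    hr = np.array([means[s] for s in stage], dtype=float)
    noise_sd = np.array([sds[s] for s in stage], dtype=float)
    if noise_sd.any():
        hr += rng.normal(0.0, 1.0, size=n) * noise_sd
    hr_events: list[Event] = []
    rem_secs = np.nonzero(stage == Stage.REM.value)[0]
    for kind, rate, lo, hi in (
            (EventKind.BRADYCARDIA, params.brady_episodes_per_night, 48.0, 58.0),
            (EventKind.TACHYCARDIA, params.tachy_episodes_per_night, 103.0, 118.0)):
        nights = rate  # rate is already per night
        n_ep = rng.poisson(nights) if nights > 0 else 0
        cands = rem_secs[rem_secs < n - params.episode_duration_s]
        placed: list[int] = []
        for _ in range(n_ep):
            if cands.size == 0:
                break
            s = int(rng.choice(cands))
            if any(abs(s - p) < 2 * params.episode_duration_s for p in placed):
                continue
            placed.append(s)
            e = s + params.episode_duration_s
            hr[s:e] = np.clip(rng.normal((lo + hi) / 2, 1.5, size=e - s), lo, hi)
            hr_events.append(Event(kind, s, e,
                                   attrs={"mean_bpm": float(hr[s:e].mean())}))
    hr = np.clip(hr, 30.0, 200.0)
    hr_events.sort(key=lambda e: e.start)

    # --- environment ------------------------------------------------------
    t_axis = np.arange(n, dtype=float)
    rng = rngs["co2"]
    co2 = (params.co2_start_ppm
           + params.co2_drift_ppm_per_h * t_axis / 3600.0
           + params.co2_snore_bump_ppm * snore_active)
    if params.co2_noise_sd > 0:
        co2 += rng.normal(0.0, params.co2_noise_sd, size=n)
    co2 = np.clip(co2, 0.0, None)

    rng = rngs["body_temp"]
    body = np.full(n, params.body_temp_c)
    if params.body_temp_noise_sd > 0:
        body += rng.normal(0.0, params.body_temp_noise_sd, size=n)
    for e in posture_changes:
        end = min(e.start + params.dip_len_s, n)
        body[e.start:end] = rng.uniform(params.dip_low_c, params.dip_high_c,
                                        size=end - e.start)

    rng = rngs["room_temp"]
    room = np.linspace(params.room_temp_start_c, params.room_temp_end_c, num=n)
    if params.room_temp_noise_sd > 0:
        room += rng.normal(0.0, params.room_temp_noise_sd, size=n)

    rng = rngs["humidity"]
    humidity = np.full(n, params.humidity_pct)
    if params.humidity_noise_sd > 0:
        humidity += rng.normal(0.0, params.humidity_noise_sd, size=n)

    rng = rngs["lux"]
    lux = np.full(n, params.lux_mean)
    if params.lux_noise_sd > 0:
        lux += rng.normal(0.0, params.lux_noise_sd, size=n)
    lux = np.clip(lux, 0.0, None)

    session = SessionRecord(
        pressure=pressure, sound_db=sound, body_temp=body, room_temp=room,
        humidity=humidity, co2=co2, lux=lux, heart_rate=hr)
    truth = GroundTruth(
        hypnogram=hyp,
        posture_schedule=schedule,
        injected_events={
            EventKind.TOSS_TURN.value: toss_events,
            EventKind.SNORE.value: snore_events,
            EventKind.POSTURE_CHANGE.value: posture_changes,
            EventKind.BRADYCARDIA.value: [e for e in hr_events
                                          if e.kind == EventKind.BRADYCARDIA],
            EventKind.TACHYCARDIA.value: [e for e in hr_events
                                          if e.kind == EventKind.TACHYCARDIA],
        },
        params=params)
    return session, truth


def simulate_night(params: SimulationParams | None = None,
                   seed: int = 0) -> tuple[SessionRecord, GroundTruth]:
    """Convenience: hypnogram + session in one call."""
    params = params or SimulationParams()
    hyp = simulate_hypnogram(params, seed)
    return simulate_session(hyp, params, seed)


def make_posture_training_set(
    n_windows_per_class: int,
    seed: int = 0,
    window_s: int = 60,
    noise_sd: float | None = None,
    shift_sd: float | None = None,
    amp_jitter_sd: float | None = None,
    params: SimulationParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labelled posture benchmark: per-class feature windows.

    Each window is ``window_s`` seconds of one posture's pressure
    profile with a per-window head-position shift (in sensor units) and
    contact-pressure scale, plus per-second sensor noise (defaults from
    SimulationParams), summarized by
    :func:`somnokit.posture.extract_features`.  Returns ``(X, y)`` with
    ``X`` of shape ``(3 * n, 18)`` and posture-name labels.
    """
    if n_windows_per_class < 1:
        raise ValidationError("need at least one window per class")
    params = params or SimulationParams()
    noise_sd = params.pressure_noise_sd if noise_sd is None else noise_sd
    shift_sd = params.head_shift_sd if shift_sd is None else shift_sd
    amp_jitter_sd = (params.amp_jitter_sd if amp_jitter_sd is None
                     else amp_jitter_sd)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    X, y = [], []
    for posture in (Posture.SUPINE, Posture.LEFT, Posture.RIGHT):
        base = np.asarray(POSTURE_PROFILES[posture], dtype=float)
        for _ in range(n_windows_per_class):
            shift = rng.normal(0.0, shift_sd) if shift_sd > 0 else 0.0
            amp = (float(np.exp(rng.normal(0.0, amp_jitter_sd)))
                   if amp_jitter_sd > 0 else 1.0)
            window = np.tile(amp * _shifted_profile(base, shift),
                             (window_s, 1))
            if noise_sd > 0:
                window = window + rng.normal(0.0, noise_sd, size=window.shape)
            np.clip(window, 0.0, None, out=window)
            X.append(extract_features(window))
            y.append(posture.value)
    return np.asarray(X), np.asarray(y)
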