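"""Event detection on the aligned 1 Hz channels.

Covers body-movement (toss-and-turn) detection from the pillow pressure
array, snore-burst segmentation from the sound-pressure-level channel,
snore-interval regularity, CO2 air-quality banding, bradycardia /
tachycardia annotation from the heart-rate channel, and masking of the
contactless body-temperature artifacts caused by posture changes.

Movement is measured by the inter-frame delta statistic

    delta(t) = sum_i |p_i(t) - p_i(t-1)|

over the 8 pressure sensors, compared against a configurable threshold
(default: 4x the median nightly delta, which is robust to the arbitrary
sensor scale).  A movement event ends when the delta stays at or below
the threshold for a full quiescence period (default 5 s): "no change in
the pressure for 5 s" means the movement has stopped.

Snore capture mimics a sound recorder armed on a 30 dB threshold: the
capture closes when the level falls back to the threshold or after 15 s,
whichever comes first, and the detector re-arms ~2 s after closing.
Regularity of the onset-to-onset intervals (coefficient of variation over
a sliding window) separates the regular ~3 s snoring seen in NREM sleep
from the irregular snoring seen in REM sleep.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .streams import Event, EventKind, PressureFrame, ValidationError

__all__ = [
    "TossTurnParams",
    "SnoreParams",
    "Co2Band",
    "frame_delta",
    "channel_deltas",
    "default_toss_threshold",
    "detect_toss_turn",
    "detect_snore_events",
    "snore_regularity",
    "classify_co2",
    "annotate_heart_rate",
    "mask_temp_artifacts",
]


@dataclass
class TossTurnParams:
    """Movement-detector parameters.

    ``threshold`` is in the same (arbitrary) units as the summed pressure
    delta; ``None`` selects the data-driven default at detection time.
    ``quiescence`` is the number of consecutive at-or-below-threshold
    seconds that closes an event.
    """

    threshold: float | None = None
    quiescence: int = 5
    merge_within_posture: bool = True

    def __post_init__(self) -> None:
        if self.threshold is not None and self.threshold <= 0:
            raise ValidationError("toss threshold must be > 0")
        if self.quiescence < 1:
            raise ValidationError("quiescence must be >= 1 s")


@dataclass
class SnoreParams:
    db_threshold: float = 30.0   # sound level that triggers a capture
    max_capture: int = 15        # s, maximum single-capture length
    rearm_delay: int = 2         # s until the detector re-arms after a close
    regularity_window: int = 5   # onset-to-onset intervals per CV window
    cv_regular_max: float = 0.25

    def __post_init__(self) -> None:
        if self.db_threshold <= 0:
            raise ValidationError("db_threshold must be > 0")
        if self.max_capture < 1:
            raise ValidationError("max_capture must be >= 1 s")
        if self.rearm_delay < 0:
            raise ValidationError("rearm_delay must be >= 0")
        if self.regularity_window < 2:
            raise ValidationError("regularity_window must be >= 2")


class Co2Band(str, Enum):
    GOOD = "good"
    AVERAGE = "average"
    POOR = "poor"
    VERY_POOR = "very_poor"


# ---------------------------------------------------------------------------
# movement

def frame_delta(curr, prev) -> float:
    """Summed absolute pressure change between two frames.

    Accepts :class:`PressureFrame` objects or length-8 arrays; symmetric
    in its arguments.
    """
    a = np.asarray(curr.p if isinstance(curr, PressureFrame) else curr, float)
    b = np.asarray(prev.p if isinstance(prev, PressureFrame) else prev, float)
    if a.shape != b.shape:
        raise ValidationError("frames must have equal sensor count")
    return float(np.abs(a - b).sum())


def channel_deltas(pressure: np.ndarray) -> np.ndarray:
    """Per-second delta track for an (n, 8) pressure stream; deltas[0] = 0."""
    pressure = np.asarray(pressure, dtype=float)
    d = np.zeros(pressure.shape[0])
    if pressure.shape[0] > 1:
        d[1:] = np.abs(np.diff(pressure, axis=0)).sum(axis=1)
    return d


def default_toss_threshold(pressure: np.ndarray, factor: float = 4.0) -> float:
    """Data-driven movement threshold: ``factor`` x median nightly delta.

    The median delta reflects the sensor-noise floor, so the threshold
    adapts to the arbitrary force units of the FSR readings.
    """
    d = channel_deltas(pressure)[1:]
    if d.size == 0:
        raise ValidationError("need at least 2 frames for a delta threshold")
    med = float(np.median(d))
    if med <= 0:
        # noise-free stream: any strictly positive delta is movement
        positive = d[d > 0]
        return float(positive.min()) / 2.0 if positive.size else 1e-9
    return factor * med


def detect_toss_turn(
    pressure: np.ndarray,
    params: TossTurnParams | None = None,
    segments: Sequence | None = None,
) -> list[Event]:
    """Detect toss-and-turn events on an (n, 8) pressure stream.

    An event opens at the first second whose delta exceeds the threshold
    and closes at the start of the first run of ``quiescence`` consecutive
    at-or-below-threshold seconds (or at stream end).  Sub-threshold
    movement never opens an event.  When ``merge_within_posture`` is set,
    events separated by less than ``quiescence`` seconds that fall in the
    same posture segment (all events, when ``segments`` is None) are
    merged.  Each event records ``peak_delta`` and its duration is a
    first-class output: for sleep-state scoring the duration of movement
    matters more than its count.
    """
    params = params or TossTurnParams()
    pressure = np.asarray(pressure, dtype=float)
    n = pressure.shape[0]
    if n < 2:
        raise ValidationError("stream must have at least 2 frames")
    thr = params.threshold if params.threshold is not None \
        else default_toss_threshold(pressure)
    d = channel_deltas(pressure)
    q = params.quiescence

    events: list[Event] = []
    t = 1
    while t < n:
        if d[t] > thr:
            start = t
            # close at the start of the first full quiescent run
            end = n
            run = 0
            for u in range(t + 1, n):
                if d[u] <= thr:
                    run += 1
                    if run == q:
                        end = u - q + 1
                        break
                else:
                    run = 0
            peak = float(np.max(d[start:end]))
            events.append(Event(EventKind.TOSS_TURN, start, end,
                                attrs={"peak_delta": peak}))
            t = end + q if end < n else n
        else:
            t += 1

    if params.merge_within_posture and len(events) > 1:
        events = _merge_close_events(events, gap=q, segments=segments)
    return events


def _segment_index(segments, t: int) -> int:
    for i, seg in enumerate(segments):
        if seg.start <= t < seg.end:
            return i
    return -1


def _merge_close_events(events: list[Event], gap: int,
                        segments: Sequence | None) -> list[Event]:
    merged = [events[0]]
    for e in events[1:]:
        prev = merged[-1]
        close = e.start - prev.end < gap
        same_seg = True
        if segments is not None:
            same_seg = (_segment_index(segments, prev.start)
                        == _segment_index(segments, e.start))
        if close and same_seg:
            merged[-1] = Event(
                EventKind.TOSS_TURN, prev.start, e.end,
                attrs={"peak_delta": max(prev.attrs["peak_delta"],
                                         e.attrs["peak_delta"])})
        else:
            merged.append(e)
    return merged


# ---------------------------------------------------------------------------
# snoring

def detect_snore_events(sound_db: np.ndarray,
                        params: SnoreParams | None = None) -> list[Event]:
    """Segment supra-threshold sound bursts into snore events.

    A capture opens at the first sample strictly above ``db_threshold``,
    closes when the level falls to or below the threshold or after
    ``max_capture`` seconds, whichever comes first, and the detector
    re-arms ``rearm_delay`` seconds after the close.  Each event records
    the peak level (``peak_db``) and the onset-to-onset gap to the
    previous event (``interval_s``; absent on the first event).
    """
    params = params or SnoreParams()
    s = np.asarray(sound_db, dtype=float)
    n = s.size
    events: list[Event] = []
    armed_at = 0
    t = 0
    while t < n:
        if t >= armed_at and s[t] > params.db_threshold:
            start = t
            end = min(start + params.max_capture, n)
            for u in range(start + 1, end):
                if s[u] <= params.db_threshold:
                    end = u
                    break
            attrs = {"peak_db": float(np.max(s[start:end]))}
            if events:
                attrs["interval_s"] = float(start - events[-1].start)
            events.append(Event(EventKind.SNORE, start, end, attrs=attrs))
            armed_at = end + params.rearm_delay
            t = max(end, armed_at)
        else:
            t += 1
    return events


def snore_regularity(
    events: Sequence[Event],
    params: SnoreParams | None = None,
) -> tuple[np.ndarray, list[bool | None]]:
    """Per-event regularity flag and interval CV.

    For event ``i`` the CV (population std / mean) is computed over the
    trailing window of ``regularity_window`` onset-to-onset intervals
    ending at event ``i``; the event is regular iff CV <= ``cv_regular_max``.
    Events without a full trailing window get CV ``nan`` and flag ``None``.
    Returns ``(cv, flags)`` aligned with ``events``.
    """
    params = params or SnoreParams()
    w = params.regularity_window
    onsets = np.array([e.start for e in events], dtype=float)
    m = onsets.size
    cv = np.full(m, np.nan)
    flags: list[bool | None] = [None] * m
    if m < 2:
        return cv, flags
    intervals = np.diff(onsets)  # intervals[j] leads into event j+1
    for i in range(m):
        if i < w:
            continue
        win = intervals[i - w:i]
        mean = float(win.mean())
        if mean <= 0:
            continue
        c = float(win.std()) / mean  # population std (ddof=0)
        cv[i] = c
        flags[i] = bool(c <= params.cv_regular_max)
    return cv, flags


# ---------------------------------------------------------------------------
# CO2, heart rate, temperature

def classify_co2(ppm: float) -> Co2Band:
    """Band a CO2 concentration: good < 400 <= average < 700 <= poor < 1000
    <= very poor (left-closed, right-open bands)."""
    if ppm < 0:
        raise ValidationError("CO2 concentration must be >= 0 ppm")
    if ppm < 400:
        return Co2Band.GOOD
    if ppm < 700:
        return Co2Band.AVERAGE
    if ppm < 1000:
        return Co2Band.POOR
    return Co2Band.VERY_POOR


BRADYCARDIA_BPM = 60.0   # strictly below
TACHYCARDIA_BPM = 100.0  # strictly above


def annotate_heart_rate(hr: np.ndarray | None,
                        min_duration: int = 5) -> list[Event]:
    """Flag maximal bradycardia (<60 bpm) / tachycardia (>100 bpm) runs.

    Runs shorter than ``min_duration`` seconds are suppressed as
    single-sample flicker.  Raises when the channel is absent.
    """
    if hr is None:
        raise ValidationError("heart-rate channel is absent")
    hr = np.asarray(hr, dtype=float)
    events: list[Event] = []
    for kind, mask in ((EventKind.BRADYCARDIA, hr < BRADYCARDIA_BPM),
                       (EventKind.TACHYCARDIA, hr > TACHYCARDIA_BPM)):
        t = 0
        n = hr.size
        while t < n:
            if mask[t]:
                start = t
                while t < n and mask[t]:
                    t += 1
                if t - start >= min_duration:
                    events.append(Event(kind, start, t,
                                        attrs={"mean_bpm": float(hr[start:t].mean())}))
            else:
                t += 1
    events.sort(key=lambda e: e.start)
    return events


def mask_temp_artifacts(
    body_temp: np.ndarray,
    posture_changes: Sequence[Event],
    pad: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag body-temperature samples near posture changes as artifacts.

    The contactless sensor reads the head, so a posture change produces a
    spurious dip (down to ~33.5-34.0 °C); samples within ``pad`` seconds
    (inclusive) of any posture-change boundary are flagged and set to NaN
    in the returned masked copy so they drop out of downstream statistics.
    Returns ``(masked, flags)``.
    """
    temp = np.asarray(body_temp, dtype=float)
    flags = np.zeros(temp.size, dtype=bool)
    for e in posture_changes:
        lo = max(0, e.start - pad)
        hi = min(temp.size, e.start + pad + 1)
        flags[lo:hi] = True
    masked = temp.copy()
    masked[flags] = np.nan
    return masked, flags
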