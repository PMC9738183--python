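"""Posture discrimination from pillow pressure windows.

The eight force sensors lie in a straight line under the head (index 0
leftmost, 7 rightmost), so the pressure distribution across the array
carries the lying posture: mass centered on the middle sensors for the
supine posture, shifted toward low indices when lying to the left and
high indices when lying to the right.  (Which body side maps to low
indices is a convention; it is configurable on the heuristic model.)

Two classifiers are provided: a transparent centroid heuristic and a
margin classifier (support-vector machine) trained on per-window
summary features.  Night segmentation uses a variable discrimination
cycle: posture is normally judged on one-minute windows of accumulated
pressure, but when a rapid pressure change is detected the cycle
shortens to a minimum of 10 s until the movement subsides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import joblib
import numpy as np
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .events import channel_deltas, default_toss_threshold
from .streams import (Event, EventKind, N_PRESSURE_SENSORS, Posture,
                      PressureFrame, ValidationError)

__all__ = [
    "FEATURE_NAMES",
    "PostureSegment",
    "HeuristicPostureModel",
    "SvmPostureModel",
    "pressure_centroid",
    "classify_posture_heuristic",
    "extract_features",
    "train_posture_classifier",
    "posture_segments",
    "save_posture_model",
    "load_posture_model",
]

#: ordered feature vector produced by extract_features
FEATURE_NAMES: tuple[str, ...] = (
    *(f"mean_p{i}" for i in range(N_PRESSURE_SENSORS)),
    *(f"std_p{i}" for i in range(N_PRESSURE_SENSORS)),
    "centroid",
    "total_mean",
)

#: default presence threshold in arbitrary force units; a calibrated value
#: is 5% of the head-on mean total pressure (presence_threshold_from_calibration)
DEFAULT_PRESENCE_THRESHOLD = 10.0


def presence_threshold_from_calibration(head_on_mean_total: float) -> float:
    """Presence threshold as 5% of the calibration head-on mean total."""
    return 0.05 * float(head_on_mean_total)


@dataclass
class PostureSegment:
    """A maximal run of one posture; ``[start, end)`` in seconds."""

    posture: Posture
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("segment duration must be > 0")

    @property
    def duration(self) -> int:
        return self.end - self.start


def _window_array(window) -> np.ndarray:
    if isinstance(window, np.ndarray):
        arr = np.asarray(window, dtype=float)
    else:
        arr = np.asarray(
            [w.p if isinstance(w, PressureFrame) else w for w in window],
            dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != N_PRESSURE_SENSORS:
        raise ValidationError(
            f"window must be (n, {N_PRESSURE_SENSORS}) pressure readings")
    if arr.shape[0] == 0:
        raise ValidationError("window must be non-empty")
    return arr


def pressure_centroid(frame) -> float:
    """Pressure-weighted mean sensor index, in [0, 7].

    Scale-free: multiplying all readings by a constant leaves the
    centroid unchanged.  Raises for an all-zero frame.
    """
    p = np.asarray(frame.p if isinstance(frame, PressureFrame) else frame,
                   dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValidationError("centroid undefined for all-zero frame")
    return float(np.dot(np.arange(p.size), p) / total)


class PostureClassifier(Protocol):
    def classify(self, window) -> Posture: ...


@dataclass
class HeuristicPostureModel:
    """Centroid-threshold posture model.

    OFF_PILLOW when the mean total pressure falls below the presence
    threshold; otherwise the mean centroid is cut at ``c_lo`` / ``c_hi``
    (defaults 3.0 / 4.0, so the symmetric center 3.5 maps to SUPINE).
    ``left_is_low_index`` flips the side convention.
    """

    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    c_lo: float = 3.0
    c_hi: float = 4.0
    left_is_low_index: bool = True

    kind = "centroid_heuristic"

    def classify(self, window) -> Posture:
        arr = _window_array(window)
        means = arr.mean(axis=0)
        if means.sum() < self.presence_threshold:
            return Posture.OFF_PILLOW
        c = pressure_centroid(means)
        if c <= self.c_lo:
            return Posture.LEFT if self.left_is_low_index else Posture.RIGHT
        if c >= self.c_hi:
            return Posture.RIGHT if self.left_is_low_index else Posture.LEFT
        return Posture.SUPINE


def classify_posture_heuristic(window, model: HeuristicPostureModel | None = None
                               ) -> Posture:
    """Classify a pressure window with the centroid heuristic."""
    return (model or HeuristicPostureModel()).classify(window)


def extract_features(window) -> np.ndarray:
    """Per-window summary features (see FEATURE_NAMES; 18 values).

    Eight per-sensor means, eight per-sensor standard deviations
    (population, ddof=0), the centroid of the mean profile, and the mean
    total pressure.  For an all-zero window the centroid is reported as
    the array center 3.5 (it is undefined; the presence threshold handles
    such windows before classification).
    """
    arr = _window_array(window)
    means = arr.mean(axis=0)
    stds = arr.std(axis=0)
    total = means.sum()
    centroid = pressure_centroid(means) if total > 0 else (N_PRESSURE_SENSORS - 1) / 2
    return np.concatenate([means, stds, [centroid, total]])


@dataclass
class SvmPostureModel:
    """Margin classifier over extract_features windows."""

    estimator: Pipeline
    feature_spec: tuple[str, ...] = FEATURE_NAMES
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    classes: tuple[str, ...] = field(default_factory=tuple)

    kind = "margin_classifier"

    def classify(self, window) -> Posture:
        arr = _window_array(window)
        if arr.mean(axis=0).sum() < self.presence_threshold:
            return Posture.OFF_PILLOW
        x = extract_features(arr)[None, :]
        return Posture(self.estimator.predict(x)[0])

    def predict_features(self, features: np.ndarray) -> np.ndarray:
        """Predict posture labels for precomputed feature rows."""
        return self.estimator.predict(np.asarray(features, dtype=float))


def train_posture_classifier(
    features: np.ndarray,
    labels: Sequence,
    *,
    C: float = 10.0,
    gamma: str | float = "scale",
    kernel: str = "rbf",
    seed: int = 0,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> SvmPostureModel:
    """Train the margin classifier on labelled feature vectors.

    Requires at least two classes and at least 10 samples per class.
    Training is deterministic under a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray([l.value if isinstance(l, Posture) else str(l)
                    for l in labels])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("training needs at least 2 posture classes")
    if counts.min() < 10:
        raise ValidationError(
            f"training needs >= 10 samples per class; class "
            f"{classes[int(np.argmin(counts))]!r} has {int(counts.min())}")
    est = make_pipeline(
        StandardScaler(),
        SVC(C=C, gamma=gamma, kernel=kernel, random_state=seed))
    est.fit(X, y)
    return SvmPostureModel(estimator=est,
                           presence_threshold=presence_threshold,
                           classes=tuple(classes))


def posture_segments(
    pressure: np.ndarray,
    model: PostureClassifier | None = None,
    base_cycle: int = 60,
    min_cycle: int = 10,
    toss_threshold: float | None = None,
) -> tuple[list[PostureSegment], list[Event]]:
    """Segment a night into posture intervals with a variable cycle.

    Posture is normally judged on ``base_cycle`` windows; when a rapid
    pressure change (inter-frame delta above the movement threshold) lies
    ahead within the prospective base window, the cycle shortens to
    ``min_cycle`` windows until the deltas subside, so posture boundaries
    resolve to within one minimum cycle.  Movement frames carry no
    posture, so a window containing movement is judged on its quiet
    frames before the movement starts (or, when the movement opens the
    window, on the quiet frames after it ends); a window of pure
    movement inherits the previous label.  This keeps every judged
    window on one side of a transition.  Adjacent equal-posture windows
    are merged and a
    POSTURE_CHANGE event is emitted at each boundary between distinct
    postures.  Returns ``(segments, posture_change_events)``; segments
    tile the session exactly.
    """
    model = model or HeuristicPostureModel()
    pressure = np.asarray(pressure, dtype=float)
    n = pressure.shape[0]
    if n < min_cycle:
        raise ValidationError(f"stream shorter than min_cycle ({min_cycle} s)")
    thr = toss_threshold if toss_threshold is not None \
        else default_toss_threshold(pressure)
    d = channel_deltas(pressure)

    raw: list[tuple[int, int, Posture]] = []
    t = 0
    while t < n:
        rapid = bool(np.any(d[t + 1:t + base_cycle] > thr))
        win = min_cycle if rapid else base_cycle
        end = min(t + win, n)
        moving = np.nonzero(d[t:end] > thr)[0] + t
        if moving.size == 0:
            frames = pressure[t:end]
        elif moving[0] > t:
            frames = pressure[t:moving[0]]       # quiet run before movement
        elif moving[-1] + 1 < end:
            frames = pressure[moving[-1] + 1:end]  # quiet run after movement
        else:
            frames = None                        # pure movement window
        if frames is not None and len(frames):
            label = model.classify(frames)
        elif raw:
            label = raw[-1][2]  # posture unchanged until movement resolves
        else:
            label = model.classify(pressure[t:end])
        raw.append((t, end, label))
        t = end

    segments: list[PostureSegment] = []
    for start, end, posture in raw:
        if segments and segments[-1].posture == posture:
            segments[-1] = PostureSegment(posture, segments[-1].start, end)
        else:
            segments.append(PostureSegment(posture, start, end))

    changes = [
        Event(EventKind.POSTURE_CHANGE, seg.start, seg.start + 1,
              attrs={"from": segments[i - 1].posture.value,
                     "to": seg.posture.value})
        for i, seg in enumerate(segments) if i > 0
    ]
    return segments, changes


# ---------------------------------------------------------------------------
# model persistence: versioned JSON metadata + joblib sidecar for the estimator

_MODEL_FORMAT_VERSION = 1


def save_posture_model(model, path) -> None:
    """Persist a posture model: ``<path>`` JSON + ``<path>.bin`` sidecar."""
    path = Path(path)
    meta = {"format_version": _MODEL_FORMAT_VERSION, "kind": model.kind}
    if isinstance(model, HeuristicPostureModel):
        meta["params"] = {
            "presence_threshold": model.presence_threshold,
            "c_lo": model.c_lo, "c_hi": model.c_hi,
            "left_is_low_index": model.left_is_low_index}
    elif isinstance(model, SvmPostureModel):
        meta["params"] = {
            "presence_threshold": model.presence_threshold,
            "feature_spec": list(model.feature_spec),
            "classes": list(model.classes),
            "sidecar": path.name + ".bin"}
        joblib.dump(model.estimator, path.with_name(path.name + ".bin"))
    else:
        raise ValidationError(f"unknown posture model type {type(model)!r}")
    path.write_text(json.dumps(meta, sort_keys=True, indent=2))


def load_posture_model(path):
    path = Path(path)
    meta = json.loads(path.read_text())
    if meta.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValidationError("unsupported posture-model format version")
    params = meta["params"]
    if meta["kind"] == "centroid_heuristic":
        return HeuristicPostureModel(**params)
    if meta["kind"] == "margin_classifier":
        est = joblib.load(path.with_name(params["sidecar"]))
        return SvmPostureModel(
            estimator=est,
            feature_spec=tuple(params["feature_spec"]),
            presence_threshold=params["presence_threshold"],
            classes=tuple(params["classes"]))
    raise ValidationError(f"unknown posture model kind {meta['kind']!r}")
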