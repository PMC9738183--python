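"""Two-stage REM/NREM scoring and evaluation.

Each 60 s epoch is scored from movement, snoring and temperature
evidence.  The rule-based scorer realizes the qualitative relations the
sensors support as a linear weighted sum of bounded sub-scores:

    nrem_score = w_move * s_move + w_snore * s_snore + w_temp * s_temp

with

* ``s_move  = 1 / (1 + toss_turn_rate * epoch_len / 60)`` — a quiet body
  favours NREM; frequent tossing and turning marks REM (the reciprocal of
  the time each posture is maintained),
* ``s_snore = snore_regular_frac`` when the epoch contains snoring, else
  a neutral 0.5 — regular ~3 s snoring marks NREM, irregular snoring REM,
* ``s_temp  = 1 / (1 + body_temp_std)`` — a stable artifact-masked body
  temperature favours NREM.

The heart-rate channel is deliberately excluded from scoring and from
the tree classifiers' predictors: it is the independent validation
reference (NREM shows a slow, stable rate; REM an elevated, variable
one), so agreement between the scorer and the heart-rate hypnogram is a
meaningful check rather than a tautology.

Tree classifiers (decision tree / random forest) trained on the same
epoch features provide the learned alternative, with per-epoch REM
probabilities for ROC analysis.  ``evaluate`` reports accuracy,
precision, recall, F1 at the 0.5 cut and AUC by the trapezoidal rule
over the empirical ROC, with REM as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.tree import DecisionTreeClassifier

from .events import SnoreParams, mask_temp_artifacts, snore_regularity
from .posture import PostureSegment
from .streams import (Event, EventKind, Hypnogram, Posture, SessionRecord,
                      Stage, ValidationError)

__all__ = [
    "PREDICTOR_COLUMNS",
    "DEFAULT_STAGE_WEIGHTS",
    "StagingModel",
    "MetricReport",
    "epoch_features",
    "stage_rule_based",
    "hr_reference_hypnogram",
    "train_stage_classifier",
    "evaluate",
    "summarize_night",
]

#: feature columns the tree classifiers may consume (heart rate excluded:
#: it is the validation reference, never a predictor)
PREDICTOR_COLUMNS = (
    "toss_turn_rate", "toss_turn_duration_s", "snore_count",
    "snore_regular_frac", "snore_mean_intensity_db",
    "body_temp_mean_c", "body_temp_std_c", "room_temp_mean_c",
    "co2_mean_ppm", "posture_code",
)

DEFAULT_STAGE_WEIGHTS = (0.5, 0.3, 0.2)  # (w_move, w_snore, w_temp)

_POSTURE_CODE = {Posture.SUPINE: 0, Posture.LEFT: 1, Posture.RIGHT: 2,
                 Posture.OFF_PILLOW: 3}


def epoch_features(
    session: SessionRecord,
    toss_events: Sequence[Event],
    snore_events: Sequence[Event],
    segments: Sequence[PostureSegment],
    posture_changes: Sequence[Event] = (),
    epoch_len: int = 60,
    snore_params: SnoreParams | None = None,
    artifact_pad: int = 30,
) -> pd.DataFrame:
    """Per-epoch feature table feeding rule-based and ML staging.

    Event counts are attributed to the epoch containing the event onset;
    movement duration is attributed by interval overlap.  Body-temperature
    statistics are computed on the artifact-masked channel (samples near
    posture changes excluded); if an epoch is fully masked the raw
    samples are used as a fallback.  Heart-rate columns appear only when
    the channel is present and are reserved for the validation reference.
    """
    n = session.duration_s
    if epoch_len <= 0 or n < epoch_len:
        raise ValidationError(
            f"epoch_len {epoch_len} s does not fit into the {n} s session")
    n_epochs = int(np.ceil(n / epoch_len))
    snore_params = snore_params or SnoreParams()

    _, snore_flags = snore_regularity(snore_events, snore_params)
    temp_masked, _ = mask_temp_artifacts(session.body_temp, posture_changes,
                                         pad=artifact_pad)

    def onset_epoch(e: Event) -> int:
        return min(e.start // epoch_len, n_epochs - 1)

    toss_by_epoch: list[list[Event]] = [[] for _ in range(n_epochs)]
    for e in toss_events:
        toss_by_epoch[onset_epoch(e)].append(e)
    snore_by_epoch: list[list[int]] = [[] for _ in range(n_epochs)]
    for i, e in enumerate(snore_events):
        snore_by_epoch[onset_epoch(e)].append(i)

    rows = []
    for k in range(n_epochs):
        lo, hi = k * epoch_len, min((k + 1) * epoch_len, n)
        span_min = (hi - lo) / 60.0

        toss = toss_by_epoch[k]
        overlap = sum(max(0, min(e.end, hi) - max(e.start, lo))
                      for e in toss_events)

        idx = snore_by_epoch[k]
        count = len(idx)
        flags = [snore_flags[i] for i in idx if snore_flags[i] is not None]
        regular_frac = (sum(flags) / len(flags)) if flags else 0.5
        intensity = (float(np.mean([snore_events[i].attrs.get("peak_db", np.nan)
                                    for i in idx])) if count else np.nan)

        temp = temp_masked[lo:hi]
        valid = temp[np.isfinite(temp)]
        if valid.size == 0:
            valid = session.body_temp[lo:hi]  # fully masked epoch: raw fallback
        # dominant posture by overlap
        best, best_overlap = Posture.OFF_PILLOW, -1
        for seg in segments:
            ov = max(0, min(seg.end, hi) - max(seg.start, lo))
            if ov > best_overlap:
                best, best_overlap = seg.posture, ov

        row = {
            "epoch_index": k,
            "toss_turn_rate": len(toss) / span_min,
            "toss_turn_duration_s": float(overlap),
            "snore_count": count,
            "snore_regular_frac": regular_frac,
            "snore_mean_intensity_db": intensity,
            "body_temp_mean_c": float(valid.mean()),
            "body_temp_std_c": float(valid.std()),
            "room_temp_mean_c": float(session.room_temp[lo:hi].mean()),
            "co2_mean_ppm": float(session.co2[lo:hi].mean()),
            "posture": best.value,
            "posture_code": _POSTURE_CODE[best],
        }
        if session.heart_rate is not None:
            hr = session.heart_rate[lo:hi]
            row["hr_mean_bpm"] = float(hr.mean())
            row["hr_std_bpm"] = float(hr.std())
        rows.append(row)
    return pd.DataFrame(rows)


def stage_rule_based(
    features: pd.DataFrame,
    weights: tuple[float, float, float] = DEFAULT_STAGE_WEIGHTS,
    epoch_len: int = 60,
) -> tuple[Hypnogram, np.ndarray]:
    """Score epochs with the linear weighted rule; NREM iff score >= 0.5.

    Consumes only movement, snoring and temperature columns — never heart
    rate.  Returns the hypnogram and the per-epoch ``nrem_score`` array.
    The scorer is monotone: more movement can only lower the NREM score,
    more regular snoring can only raise it.
    """
    w_move, w_snore, w_temp = weights
    rate = features["toss_turn_rate"].to_numpy(dtype=float)
    s_move = 1.0 / (1.0 + rate * epoch_len / 60.0)
    count = features["snore_count"].to_numpy(dtype=float)
    frac = features["snore_regular_frac"].to_numpy(dtype=float)
    s_snore = np.where(count > 0, frac, 0.5)
    s_temp = 1.0 / (1.0 + features["body_temp_std_c"].to_numpy(dtype=float))
    score = w_move * s_move + w_snore * s_snore + w_temp * s_temp
    labels = [Stage.NREM if s >= 0.5 else Stage.REM for s in score]
    return Hypnogram(labels=labels, epoch_len=epoch_len), score


def hr_reference_hypnogram(
    hr: np.ndarray | None,
    epoch_len: int = 60,
    lo_mean: float = 65.0,
    lo_std: float = 5.0,
) -> Hypnogram:
    """Heart-rate reference: NREM iff the epoch mean is slow (<= lo_mean)
    and stable (std <= lo_std), else REM.

    This is the binary validation reference; it shares no input channel
    with the rule-based scorer.
    """
    if hr is None:
        raise ValidationError("heart-rate channel is absent")
    hr = np.asarray(hr, dtype=float)
    n_epochs = int(np.ceil(hr.size / epoch_len))
    labels = []
    for k in range(n_epochs):
        chunk = hr[k * epoch_len:(k + 1) * epoch_len]
        nrem = chunk.mean() <= lo_mean and chunk.std() <= lo_std
        labels.append(Stage.NREM if nrem else Stage.REM)
    return Hypnogram(labels=labels, epoch_len=epoch_len)


def _binary_labels(ref) -> np.ndarray:
    """Stage labels -> 1 for REM (positive class), 0 for NREM.

    WAKE reference epochs map to REM: both are 'not in quiet sleep' for
    the binary comparison.
    """
    labels = ref.labels if isinstance(ref, Hypnogram) else list(ref)
    return np.array([0 if Stage(l) == Stage.NREM else 1 for l in labels])


@dataclass
class StagingModel:
    """Trained tree classifier exposing per-epoch REM probabilities."""

    estimator: object
    model: str
    predictors: tuple[str, ...] = PREDICTOR_COLUMNS

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        cols = [c for c in self.predictors if c in features.columns]
        return features[list(cols)].fillna(0.0).to_numpy(dtype=float)

    def predict_proba_rem(self, features: pd.DataFrame) -> np.ndarray:
        proba = self.estimator.predict_proba(self._matrix(features))
        rem_col = list(self.estimator.classes_).index(1)
        return proba[:, rem_col]

    def predict(self, features: pd.DataFrame, epoch_len: int = 60) -> Hypnogram:
        p = self.predict_proba_rem(features)
        return Hypnogram(
            labels=[Stage.REM if v > 0.5 else Stage.NREM for v in p],
            epoch_len=epoch_len)


def train_stage_classifier(
    features: pd.DataFrame,
    labels,
    model: str = "random_forest",
    seed: int = 0,
    **hyperparams,
) -> StagingModel:
    """Fit a decision tree or random forest on epoch features.

    ``labels`` is a Hypnogram or stage sequence; WAKE maps to REM.
    Heart-rate columns are never used as predictors.  Reproducible under
    a fixed seed.
    """
    y = _binary_labels(labels)
    if len(y) != len(features):
        raise ValidationError("features and labels must have equal length")
    if np.unique(y).size < 2:
        raise ValidationError("training labels contain a single class")
    if model == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **hyperparams)
    elif model == "random_forest":
        hyperparams.setdefault("n_estimators", 200)
        est = RandomForestClassifier(random_state=seed, **hyperparams)
    else:
        raise ValidationError(f"unknown model {model!r}")
    sm = StagingModel(estimator=est, model=model)
    est.fit(sm._matrix(features), y)
    return sm


@dataclass
class MetricReport:
    """Binary staging metrics with REM as the positive class."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
                "roc_points": [list(p) for p in self.roc_points]}


def evaluate(pred_scores: np.ndarray, ref) -> MetricReport:
    """Score per-epoch REM probabilities against a reference hypnogram.

    Threshold metrics use the 0.5 cut (REM predicted iff score > 0.5);
    AUC integrates the empirical ROC by the trapezoidal rule.  Raises
    when the reference contains a single class (AUC undefined).
    """
    scores = np.asarray(pred_scores, dtype=float)
    y = _binary_labels(ref)
    if len(scores) != len(y):
        raise ValidationError("scores and reference must have equal length")
    if np.unique(y).size < 2:
        raise ValidationError("AUC undefined: reference has a single class")
    pred = (scores > 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    accuracy = (tp + tn) / len(y)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return MetricReport(accuracy=float(accuracy), precision=float(precision),
                        recall=float(recall), f1=float(f1), auc=auc,
                        roc_points=[(float(a), float(b))
                                    for a, b in zip(fpr, tpr)])


def summarize_night(
    session: SessionRecord,
    segments: Sequence[PostureSegment],
    events: dict[EventKind, Sequence[Event]],
    hypnogram: Hypnogram,
) -> pd.DataFrame:
    """Per-stage night summary: minutes, posture breakdown, event counts
    and mean physiology/environment, one row per stage present.

    Stage minutes are exact (per-second attribution), so they sum to the
    session duration; events are attributed by onset.
    """
    n = session.duration_s
    per_sec = hypnogram.stage_per_second(n)
    stage_arr = np.array([s.value for s in per_sec])

    posture_per_sec = np.empty(n, dtype=object)
    for seg in segments:
        posture_per_sec[seg.start:min(seg.end, n)] = seg.posture.value

    rows = []
    for stage in (Stage.NREM, Stage.REM, Stage.WAKE):
        mask = stage_arr == stage.value
        secs = int(mask.sum())
        if secs == 0:
            continue
        row = {"stage": stage.value, "minutes": secs / 60.0}
        for posture in Posture:
            row[f"{posture.value}_min"] = float(
                np.sum(mask & (posture_per_sec == posture.value)) / 60.0)
        for kind, col in ((EventKind.TOSS_TURN, "toss_count"),
                          (EventKind.SNORE, "snore_count")):
            row[col] = sum(1 for e in events.get(kind, [])
                           if e.start < n and mask[e.start])
        row["hr_mean_bpm"] = (float(session.heart_rate[mask].mean())
                              if session.heart_rate is not None else np.nan)
        row["co2_mean_ppm"] = float(session.co2[mask].mean())
        row["room_temp_mean_c"] = float(session.room_temp[mask].mean())
        row["humidity_mean_pct"] = float(session.humidity[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)
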