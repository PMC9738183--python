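"""End-to-end night pipeline: configuration, orchestration, reporting.

``run_pipeline`` takes a session CSV through posture segmentation, event
detection, epoch feature extraction and two-stage scoring, writes the
artifact bundle (``events.json``, ``hypnogram.json``, ``summary.json``,
``report.md`` and, when a heart-rate channel is present, ``metrics.json``
scored against the heart-rate reference), and returns the in-memory
objects.  Given a fixed configuration the bundle is byte-identical
across runs.

Configuration is a TOML or JSON document mirroring the parameter blocks
of the detector and staging modules; unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .events import (SnoreParams, TossTurnParams, annotate_heart_rate,
                     detect_snore_events, detect_toss_turn)
from .posture import (HeuristicPostureModel, load_posture_model,
                      posture_segments)
from .staging import (DEFAULT_STAGE_WEIGHTS, MetricReport, epoch_features,
                      evaluate, hr_reference_hypnogram, stage_rule_based,
                      summarize_night, train_stage_classifier)
from .streams import (EventKind, Hypnogram, SessionRecord, Stage,
                      ValidationError, events_to_json, read_session)

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

logger = logging.getLogger("somnokit")


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown key(s) in {context}: {', '.join(sorted(unknown))}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """Full parameterization of one pipeline run.

    A fully-defaulted config (only ``session`` set) is valid.  ``mode``
    selects the stager: ``rule`` (the weighted linear scorer), or
    ``dt``/``rf`` (a tree classifier trained against the heart-rate
    reference of the same night, which then requires that channel).
    """

    session: str = ""
    out_dir: str = "somnokit_out"
    epoch_len: int = 60
    mode: str = "rule"                      # rule | dt | rf
    weights: tuple[float, float, float] = DEFAULT_STAGE_WEIGHTS
    toss: TossTurnParams = field(default_factory=TossTurnParams)
    snore: SnoreParams = field(default_factory=SnoreParams)
    posture_model: str | None = None        # path; None -> centroid heuristic
    base_cycle: int = 60
    min_cycle: int = 10
    artifact_pad: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("rule", "dt", "rf"):
            raise ValidationError(f"unknown staging mode {self.mode!r}")
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != 3:
            raise ValidationError("weights must be (w_move, w_snore, w_temp)")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "toss" in data:
            data["toss"] = _from_mapping(TossTurnParams, data["toss"], "toss")
        if "snore" in data:
            data["snore"] = _from_mapping(SnoreParams, data["snore"], "snore")
        return _from_mapping(cls, data, "pipeline config")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        elif path.suffix == ".json":
            data = json.loads(path.read_text())
        else:
            raise ValidationError(
                f"config must be .toml or .json, got {path.suffix!r}")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = list(self.weights)
        return d


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_json_safe(payload), sort_keys=True, indent=2)
                    + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline per config; write the artifact bundle.

    Returns a dict with the in-memory results (``session``, ``segments``,
    ``events``, ``features``, ``hypnogram``, ``scores``, ``summary``,
    ``metrics`` or None, ``paths``).  Errors from any stage propagate
    with the stage name prefixed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config: %s", json.dumps(config.to_dict(),
                                                  sort_keys=True))

    def stage_ctx(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, _StageError):
                    raise _StageError(f"{name}: {exc}") from exc
                return False
        return _Ctx()

    class _StageError(RuntimeError):
        pass

    with stage_ctx("read_session"):
        session = read_session(config.session)

    with stage_ctx("posture"):
        model = (load_posture_model(config.posture_model)
                 if config.posture_model else HeuristicPostureModel())
        segments, posture_changes = posture_segments(
            session.pressure, model,
            base_cycle=config.base_cycle, min_cycle=config.min_cycle,
            toss_threshold=config.toss.threshold)

    with stage_ctx("detect"):
        toss = detect_toss_turn(session.pressure, config.toss, segments)
        snore = detect_snore_events(session.sound_db, config.snore)
        hr_events = (annotate_heart_rate(session.heart_rate)
                     if session.heart_rate is not None else [])

    with stage_ctx("features"):
        features = epoch_features(
            session, toss, snore, segments, posture_changes,
            epoch_len=config.epoch_len, snore_params=config.snore,
            artifact_pad=config.artifact_pad)

    with stage_ctx("stage"):
        if config.mode == "rule":
            hypnogram, scores = stage_rule_based(
                features, weights=config.weights, epoch_len=config.epoch_len)
        else:
            ref = hr_reference_hypnogram(session.heart_rate,
                                         epoch_len=config.epoch_len)
            sm = train_stage_classifier(
                features, ref,
                model="decision_tree" if config.mode == "dt" else "random_forest",
                seed=config.seed)
            scores = 1.0 - sm.predict_proba_rem(features)  # nrem_score scale
            hypnogram = Hypnogram(
                labels=[Stage.NREM if s >= 0.5 else Stage.REM for s in scores],
                epoch_len=config.epoch_len)

    metrics: MetricReport | None = None
    if session.heart_rate is not None:
        with stage_ctx("evaluate"):
            ref = hr_reference_hypnogram(session.heart_rate,
                                         epoch_len=config.epoch_len)
            try:
                metrics = evaluate(1.0 - scores, ref)  # REM probabilities
            except ValidationError:
                metrics = None  # single-class reference night

    with stage_ctx("summarize"):
        events = {EventKind.TOSS_TURN: toss, EventKind.SNORE: snore,
                  EventKind.POSTURE_CHANGE: posture_changes}
        summary = summarize_night(session, segments, events, hypnogram)

    with stage_ctx("write"):
        all_events = sorted(toss + snore + posture_changes + hr_events,
                            key=lambda e: (e.start, e.kind.value))
        paths = {
            "events": out_dir / "events.json",
            "hypnogram": out_dir / "hypnogram.json",
            "summary": out_dir / "summary.json",
            "report": out_dir / "report.md",
        }
        paths["events"].write_text(events_to_json(all_events) + "\n")
        paths["hypnogram"].write_text(hypnogram.to_json() + "\n")
        _write_json(paths["summary"], summary.to_dict(orient="records"))
        if metrics is not None:
            paths["metrics"] = out_dir / "metrics.json"
            _write_json(paths["metrics"], metrics.to_dict())
        paths["report"].write_text(render_report(summary, metrics))

    return {"session": session, "segments": segments,
            "posture_changes": posture_changes,
            "events": {"toss_turn": toss, "snore": snore,
                       "heart_rate": hr_events},
            "features": features, "hypnogram": hypnogram, "scores": scores,
            "summary": summary, "metrics": metrics, "paths": paths}


def _fmt(value, unit: str = "", digits: int = 1) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "n/a"
    return f"{value:.{digits}f}{unit}"


def render_report(summary: pd.DataFrame, metrics: MetricReport | None = None
                  ) -> str:
    """Render the per-stage night summary as markdown.

    One section per stage with posture durations, movement and snore
    counts, and mean physiology/environment, followed by a totals row;
    absent channels render as "n/a".
    """
    lines = ["# Night summary", ""]
    for _, row in summary.iterrows():
        lines += [f"## {str(row['stage']).upper()} sleep",
                  "",
                  f"- total: {_fmt(row['minutes'])} min",
                  "- posture durations: "
                  + ", ".join(f"{p} {_fmt(row[f'{p}_min'])} min"
                              for p in ("supine", "left", "right", "off_pillow")
                              if row.get(f"{p}_min", 0) > 0) or "-",
                  f"- tosses and turns: {int(row['toss_count'])}",
                  f"- snores detected: {int(row['snore_count'])}",
                  f"- heart rate: {_fmt(row['hr_mean_bpm'], ' bpm')}",
                  f"- CO2: {_fmt(row['co2_mean_ppm'], ' ppm', 0)}",
                  f"- room temperature: {_fmt(row['room_temp_mean_c'], ' °C')}",
                  f"- humidity: {_fmt(row['humidity_mean_pct'], ' %')}",
                  ""]
    total_min = float(summary["minutes"].sum())
    lines += [f"**Total: {_fmt(total_min)} min across "
              f"{len(summary)} stage(s).**", ""]
    if metrics is not None:
        lines += ["## Agreement with the heart-rate reference", "",
                  f"- accuracy: {metrics.accuracy:.3f}",
                  f"- precision: {metrics.precision:.3f}",
                  f"- recall: {metrics.recall:.3f}",
                  f"- F1-score: {metrics.f1:.3f}",
                  f"- AUC: {metrics.auc:.3f}", ""]
    return "\n".join(lines)
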