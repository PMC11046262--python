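"""On-disk formats and session configuration.

All tables are plain CSV with headers; scalar reports are JSON — no binary
formats, so every intermediate of a session stays auditable.  Timestamps
are serialized in seconds at microsecond precision.

File formats
------------
detection log   one row per (camera, frame): session_id, camera_id,
                frame_index, timestamp_s, detected, marker_id,
                c0x,c0y,...,c3x,c3y (corner cells empty when detected=0)
trial events    trial_index, kind, start_s, end_s, trial_type
trial scores    trial_index, label, n_frames_seen, n_frames_engaged,
                first_engaged_s
trace           eval_min, n_trials, prob_pct, defined
metrics         JSON report + 2x2 confusion CSV

The session config is YAML; ``load_config`` validates it and applies the
standard defaults (yaw window 5-175 deg, 6 s / 3 s trial timing, 5 min /
1 min / 50% dynamics) for omitted fields, reporting every offending field
at once on schema violations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .detection import FrameRecord
from .dynamics import DynamicsConfig, EngagementTrace
from .geometry import MarkerObservation, Point2D, RegionOfInterest, WallSpec
from .metrics import ConfusionMatrix, MetricsReport
from .scoring import ClassifierConfig, TrialScore, TrialWindow

_FLOAT_FMT = "%.6f"


class ConfigError(ValueError):
    """Session-config schema violation; message lists every bad field."""


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

def write_detection_log(path: str | Path,
                        streams: Mapping[str, Sequence[FrameRecord]],
                        session_id: str = "session") -> None:
    rows = []
    for cam, stream in streams.items():
        for rec in stream:
            base = {"session_id": session_id, "camera_id": cam,
                    "frame_index": rec.frame_index,
                    "timestamp_s": rec.timestamp}
            if rec.observations:
                for obs in rec.observations:
                    row = dict(base, detected=1, marker_id=obs.marker_id)
                    for i, c in enumerate(obs.corners):
                        row[f"c{i}x"], row[f"c{i}y"] = c.x, c.y
                    rows.append(row)
            else:
                rows.append(dict(base, detected=0, marker_id=""))
    cols = (["session_id", "camera_id", "frame_index", "timestamp_s",
             "detected", "marker_id"]
            + [f"c{i}{a}" for i in range(4) for a in "xy"])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False,
                                            float_format=_FLOAT_FMT)


def read_detection_log(path: str | Path) -> dict[str, list[FrameRecord]]:
    df = pd.read_csv(path)
    streams: dict[str, list[FrameRecord]] = {}
    for cam, group in df.groupby("camera_id", sort=True):
        recs: list[FrameRecord] = []
        for (fi, ts), g in group.groupby(["frame_index", "timestamp_s"],
                                         sort=True):
            obs = []
            for _, row in g.iterrows():
                if int(row["detected"]) != 1:
                    continue
                corners = tuple(
                    Point2D(float(row[f"c{i}x"]), float(row[f"c{i}y"]))
                    for i in range(4))
                obs.append(MarkerObservation(
                    camera_id=str(cam), frame_index=int(fi),
                    timestamp=float(ts), marker_id=int(row["marker_id"]),
                    corners=corners))
            recs.append(FrameRecord(camera_id=str(cam), frame_index=int(fi),
                                    timestamp=float(ts),
                                    observations=tuple(obs)))
        recs.sort(key=lambda r: r.timestamp)
        streams[str(cam)] = recs
    return streams


def write_trial_events(path: str | Path,
                       windows: Sequence[TrialWindow]) -> None:
    pd.DataFrame([{"trial_index": w.trial_index, "kind": w.kind,
                   "start_s": w.start, "end_s": w.end,
                   "trial_type": w.trial_type} for w in windows]) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial_events(path: str | Path) -> list[TrialWindow]:
    # keep_default_na: the literal trial_type "n/a" must survive parsing
    df = pd.read_csv(path, keep_default_na=False)
    return [TrialWindow(trial_index=int(r.trial_index), kind=str(r.kind),
                        start=float(r.start_s), end=float(r.end_s),
                        trial_type=str(r.trial_type))
            for r in df.itertuples()]


def write_trial_scores(path: str | Path,
                       scores: Sequence[TrialScore]) -> None:
    pd.DataFrame([{"trial_index": s.trial_index, "label": s.label,
                   "n_frames_seen": s.n_frames_seen,
                   "n_frames_engaged": s.n_frames_engaged,
                   "first_engaged_s": ("" if s.first_engaged_timestamp is None
                                       else s.first_engaged_timestamp)}
                  for s in scores]) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial_scores(path: str | Path) -> list[TrialScore]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for r in df.itertuples():
        first = getattr(r, "first_engaged_s")
        first = None if (first == "" or (isinstance(first, float)
                                         and math.isnan(first))) else float(first)
        out.append(TrialScore(trial_index=int(r.trial_index),
                              label=str(r.label),
                              n_frames_seen=int(r.n_frames_seen),
                              n_frames_engaged=int(r.n_frames_engaged),
                              first_engaged_timestamp=first))
    return out


def write_trace(path: str | Path, trace: EngagementTrace) -> None:
    defined = ~np.isnan(trace.probabilities_pct)
    pd.DataFrame({
        "eval_min": trace.eval_times_min,
        "n_trials": trace.n_trials,
        "prob_pct": [("" if not d else p)
                     for p, d in zip(trace.probabilities_pct, defined)],
        "defined": defined.astype(int),
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_metrics_report(path: str | Path, cm: ConfusionMatrix,
                         report: MetricsReport) -> None:
    payload = {
        "confusion": {"TP": cm.TP, "TN": cm.TN, "FP": cm.FP, "FN": cm.FN},
        "raw": {"accuracy": report.accuracy, "precision": report.precision,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity, "f1": report.f1,
                "mcc": report.mcc},
        "display": report.rounded(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_confusion_csv(path: str | Path, cm: ConfusionMatrix) -> None:
    pd.DataFrame(
        [["truth_engaged", cm.TP, cm.FN],
         ["truth_distracted", cm.FP, cm.TN]],
        columns=["", "pred_engaged", "pred_distracted"]) \
        .to_csv(path, index=False)


# ---------------------------------------------------------------------------
# session config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionConfig:
    """Validated top-level configuration for a full pipeline run."""

    camera_ids: tuple[str, ...]
    frame_sources: Mapping[str, str | None]
    classifier: ClassifierConfig
    dynamics: DynamicsConfig
    trial_active_s: float = 6.0
    trial_inter_s: float = 3.0
    output_dir: str = "engagetrack_out"
    log_level: str = "INFO"


def _point(v: Any, errors: list[str], where: str) -> Point2D | None:
    if (not isinstance(v, (list, tuple)) or len(v) != 2
            or not all(isinstance(x, (int, float)) for x in v)):
        errors.append(f"{where}: expected [x, y], got {v!r}")
        return None
    return Point2D(float(v[0]), float(v[1]))


def load_config(path: str | Path) -> SessionConfig:
    """Load + validate a YAML session config, applying standard defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []

    cam_section = raw.get("cameras")
    cam_ids: list[str] = []
    frame_sources: dict[str, str | None] = {}
    if not isinstance(cam_section, list) or not cam_section:
        errors.append("cameras: expected a non-empty list")
        cam_section = []
    for i, cam in enumerate(cam_section):
        if not isinstance(cam, dict) or "id" not in cam:
            errors.append(f"cameras[{i}]: needs an 'id'")
            continue
        cam_ids.append(str(cam["id"]))
        frame_sources[str(cam["id"])] = cam.get("frames")

    cls = raw.get("classifier", {})
    yaw_min = cls.get("yaw_min", 5.0)
    yaw_max = cls.get("yaw_max", 175.0)
    front_edge = cls.get("front_edge", 0)
    target_id = cls.get("target_marker_id", 0)
    if not (isinstance(yaw_min, (int, float)) and isinstance(yaw_max, (int, float))
            and 0 <= yaw_min < yaw_max <= 180):
        errors.append(f"classifier: need 0 <= yaw_min < yaw_max <= 180, "
                      f"got {yaw_min!r}, {yaw_max!r}")
    if front_edge not in (0, 1, 2, 3):
        errors.append(f"classifier.front_edge: must be 0..3, got {front_edge!r}")

    rois: dict[str, tuple[RegionOfInterest, ...]] = {}
    walls: dict[str, WallSpec] = {}
    cam_cfgs = cls.get("cameras", {})
    if not isinstance(cam_cfgs, dict):
        errors.append("classifier.cameras: expected a mapping")
        cam_cfgs = {}
    for cam in cam_ids:
        sub = cam_cfgs.get(cam)
        if sub is None:
            errors.append(f"classifier.cameras.{cam}: missing (every camera "
                          "needs an ROI and a wall)")
            continue
        roi_lists = sub.get("rois")
        if roi_lists is None and "roi" in sub:
            roi_lists = [sub["roi"]]
        cam_rois = []
        if not isinstance(roi_lists, list) or not roi_lists:
            errors.append(f"classifier.cameras.{cam}.roi(s): expected polygon(s)")
            roi_lists = []
        for j, poly in enumerate(roi_lists):
            pts = [p for v in (poly or [])
                   if (p := _point(v, errors, f"{cam}.rois[{j}]")) is not None]
            if len(pts) >= 3:
                try:
                    cam_rois.append(RegionOfInterest(camera_id=cam,
                                                     vertices=tuple(pts)))
                except ValueError as e:
                    errors.append(f"classifier.cameras.{cam}.rois[{j}]: {e}")
            else:
                errors.append(f"classifier.cameras.{cam}.rois[{j}]: "
                              "needs >= 3 vertices")
        wall_raw = sub.get("wall")
        if not isinstance(wall_raw, dict):
            errors.append(f"classifier.cameras.{cam}.wall: missing")
        else:
            p0 = _point(wall_raw.get("p0"), errors, f"{cam}.wall.p0")
            p1 = _point(wall_raw.get("p1"), errors, f"{cam}.wall.p1")
            hint = _point(wall_raw.get("interior_hint"), errors,
                          f"{cam}.wall.interior_hint")
            if p0 and p1 and hint:
                try:
                    walls[cam] = WallSpec(p0=p0, p1=p1, interior_hint=hint)
                except ValueError as e:
                    errors.append(f"classifier.cameras.{cam}.wall: {e}")
        if cam_rois:
            rois[cam] = tuple(cam_rois)

    dyn = raw.get("dynamics", {})
    try:
        dynamics = DynamicsConfig(
            window_length=float(dyn.get("window_length_min", 5.0)),
            step=float(dyn.get("step_min", 1.0)),
            threshold=float(dyn.get("threshold_pct", 50.0)),
            min_consecutive=int(dyn.get("min_consecutive", 1)))
    except (TypeError, ValueError) as e:
        errors.append(f"dynamics: {e}")
        dynamics = DynamicsConfig()

    trials = raw.get("trials", {})
    active_s = float(trials.get("active_s", 6.0))
    inter_s = float(trials.get("inter_s", 3.0))
    if active_s <= 0 or inter_s <= 0:
        errors.append("trials: active_s and inter_s must be positive")

    if errors:
        raise ConfigError("invalid session config:\n  - "
                          + "\n  - ".join(errors))

    classifier = ClassifierConfig(
        rois={c: rois[c] for c in cam_ids},
        walls={c: walls[c] for c in cam_ids},
        front_edge=int(front_edge), yaw_min=float(yaw_min),
        yaw_max=float(yaw_max), target_marker_id=int(target_id))
    return SessionConfig(camera_ids=tuple(cam_ids),
                         frame_sources=frame_sources, classifier=classifier,
                         dynamics=dynamics, trial_active_s=active_s,
                         trial_inter_s=inter_s,
                         output_dir=str(raw.get("output_dir",
                                                "engagetrack_out")),
                         log_level=str(raw.get("log_level", "INFO")))


def save_config(path: str | Path, cfg: SessionConfig) -> None:
    """Serialize a SessionConfig back to YAML (inverse of load_config)."""
    cls = cfg.classifier
    data = {
        "cameras": [{"id": c, "frames": cfg.frame_sources.get(c)}
                    for c in cfg.camera_ids],
        "classifier": {
            "front_edge": cls.front_edge, "yaw_min": cls.yaw_min,
            "yaw_max": cls.yaw_max, "target_marker_id": cls.target_marker_id,
            "cameras": {
                c: {"rois": [[[v.x, v.y] for v in roi.vertices]
                             for roi in cls.rois[c]],
                    "wall": {"p0": [cls.walls[c].p0.x, cls.walls[c].p0.y],
                             "p1": [cls.walls[c].p1.x, cls.walls[c].p1.y],
                             "interior_hint": [cls.walls[c].interior_hint.x,
                                               cls.walls[c].interior_hint.y]}}
                for c in cfg.camera_ids}},
        "dynamics": {"window_length_min": cfg.dynamics.window_length,
                     "step_min": cfg.dynamics.step,
                     "threshold_pct": cfg.dynamics.threshold,
                     "min_consecutive": cfg.dynamics.min_consecutive},
        "trials": {"active_s": cfg.trial_active_s,
                   "inter_s": cfg.trial_inter_s},
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
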