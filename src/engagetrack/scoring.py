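"""Per-frame engagement classification and trial-level scoring.

A frame is classified *engaged* when the head-mounted marker is detected,
its center lies inside at least one region of interest of that camera, and
its nose-ward yaw relative to the module wall lies within a closed window
(5-175 degrees by default: pointed toward the wall, not grazing along it).
An undetected marker — occlusion, blur, the animal off-camera — defaults to
*distracted*.

Trials are scored by the any-frame rule: an active trial is engaged if any
frame within it classifies engaged on any camera, regardless of interleaved
distraction; a trial with no engaged frame (including one with no frames at
all) is distracted.  Inter-trial frames are classified for live annotation
only and never scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .detection import FrameRecord
from .geometry import (MarkerObservation, Point2D, RegionOfInterest,
                       WallSpec, point_in_roi, pose_from_corners, yaw_angle)
from .metrics import DISTRACTED, ENGAGED

logger = logging.getLogger(__name__)

ACTIVE = "active"
INTER_TRIAL = "inter_trial"

#: Live-annotation outline colors: (window kind, label) -> color.
ANNOTATION_COLORS: Mapping[tuple[str, str], str] = {
    (ACTIVE, ENGAGED): "green",
    (ACTIVE, DISTRACTED): "yellow",
    (INTER_TRIAL, ENGAGED): "purple",
    (INTER_TRIAL, DISTRACTED): "pink",
}


class CameraConfigError(KeyError):
    """A camera appears in the data but has no ROI/wall configuration."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Geometric engagement gates, configured per camera.

    rois : mapping camera_id -> list of RegionOfInterest
    walls : mapping camera_id -> WallSpec (module-wall segment in that
        camera's pixel frame)
    front_edge : which marker edge (corner pair k, k+1 mod 4) faces the
        animal's nose — depends on mount orientation
    yaw_min, yaw_max : closed engaged yaw window in degrees; the default
        5-175 gives the animal leeway in orientation while excluding
        headings away from or grazing the wall
    target_marker_id : dictionary ID of the tracked marker
    """

    rois: Mapping[str, Sequence[RegionOfInterest]]
    walls: Mapping[str, WallSpec]
    front_edge: int = 0
    yaw_min: float = 5.0
    yaw_max: float = 175.0
    target_marker_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.yaw_min < self.yaw_max <= 180.0):
            raise ValueError("need 0 <= yaw_min < yaw_max <= 180")
        if self.front_edge not in (0, 1, 2, 3):
            raise ValueError("front_edge must be in 0..3")
        for cam, rois in self.rois.items():
            if cam not in self.walls:
                raise ValueError(f"camera {cam!r} has ROIs but no wall")
            for roi in rois:
                if roi.camera_id != cam:
                    raise ValueError(
                        f"ROI for camera {roi.camera_id!r} filed under {cam!r}")

    def for_camera(self, camera_id: str) -> tuple[Sequence[RegionOfInterest], WallSpec]:
        try:
            return self.rois[camera_id], self.walls[camera_id]
        except KeyError as e:
            raise CameraConfigError(
                f"camera {camera_id!r} has no configured ROI/wall") from e


@dataclass(frozen=True)
class TrialWindow:
    """One timeline segment of the go/no-go task.

    Active trials last 6 s and are followed by a 3 s inter-trial period in
    the standard paradigm; ``trial_type`` distinguishes go from no-go cues
    where known ("n/a" otherwise, and for inter-trial windows).
    """

    trial_index: int
    kind: str  # ACTIVE or INTER_TRIAL
    start: float  # seconds from session start
    end: float
    trial_type: str = "n/a"  # go | no_go | n/a

    def __post_init__(self) -> None:
        if self.kind not in (ACTIVE, INTER_TRIAL):
            raise ValueError(f"bad window kind {self.kind!r}")
        if not self.end > self.start:
            raise ValueError("window must have positive duration")
        if self.trial_type not in ("go", "no_go", "n/a"):
            raise ValueError(f"bad trial_type {self.trial_type!r}")


@dataclass(frozen=True)
class TrialScore:
    """Outcome of scoring one active trial."""

    trial_index: int
    label: str
    n_frames_seen: int
    n_frames_engaged: int
    first_engaged_timestamp: float | None = None
    n_frames_detected: int = 0

    def __post_init__(self) -> None:
        if (self.label == ENGAGED) != (self.n_frames_engaged >= 1):
            raise ValueError("label must be engaged iff >= 1 engaged frame")


def classify_frame(obs: MarkerObservation | None,
                   cfg: ClassifierConfig) -> str:
    """Engagement label of a single (possibly absent) marker observation.

    Engaged requires all three gates: marker detected, center inside at
    least one ROI of its camera, and yaw within the closed
    [yaw_min, yaw_max] window.  ``None`` (occlusion / non-detection) is
    distracted by definition.
    """
    if obs is None:
        return DISTRACTED
    rois, wall = cfg.for_camera(obs.camera_id)
    center, heading = pose_from_corners(obs, cfg.front_edge)
    if not any(point_in_roi(center, roi) for roi in rois):
        return DISTRACTED
    yaw = yaw_angle(heading, wall)
    if cfg.yaw_min <= yaw <= cfg.yaw_max:
        return ENGAGED
    return DISTRACTED


def classify_record(rec: FrameRecord, cfg: ClassifierConfig) -> str:
    """Label for a fused frame: engaged if any of its observations is."""
    relevant = [o for o in rec.observations
                if o.marker_id == cfg.target_marker_id]
    if not relevant:
        return DISTRACTED
    for obs in relevant:
        if classify_frame(obs, cfg) == ENGAGED:
            return ENGAGED
    return DISTRACTED


def annotation_state(window_kind: str, label: str) -> str:
    """Outline color shown to the investigator for a (window, label) pair."""
    try:
        return ANNOTATION_COLORS[(window_kind, label)]
    except KeyError:
        raise ValueError(
            f"bad window kind / label: {window_kind!r}, {label!r}") from None


def score_trial(frames: Sequence[FrameRecord], window: TrialWindow,
                cfg: ClassifierConfig) -> TrialScore:
    """Score one active trial window by the any-frame rule.

    ``frames`` must already be restricted to [window.start, window.end).
    A trial with no frames (total occlusion) scores distracted.
    """
    if window.kind != ACTIVE:
        raise ValueError("only active windows are scored")
    n_engaged = 0
    n_detected = 0
    first_ts: float | None = None
    for rec in frames:
        if any(o.marker_id == cfg.target_marker_id for o in rec.observations):
            n_detected += 1
        if classify_record(rec, cfg) == ENGAGED:
            n_engaged += 1
            if first_ts is None:
                first_ts = rec.timestamp
    label = ENGAGED if n_engaged >= 1 else DISTRACTED
    return TrialScore(trial_index=window.trial_index, label=label,
                      n_frames_seen=len(frames), n_frames_engaged=n_engaged,
                      first_engaged_timestamp=first_ts,
                      n_frames_detected=n_detected)


def score_session(frames: Iterable[FrameRecord],
                  trial_windows: Sequence[TrialWindow],
                  cfg: ClassifierConfig) -> list[TrialScore]:
    """Score every active window of a session from fused frame records.

    Windows must be non-overlapping and time-ordered.  Frames outside all
    windows are ignored (a count is logged); inter-trial frames are not
    scored.  Returns one TrialScore per active window, in order.
    """
    windows = list(trial_windows)
    for a, b in zip(windows, windows[1:]):
        if b.start < a.end:
            raise ValueError("trial windows must be non-overlapping and ordered")
    buckets: list[list[FrameRecord]] = [[] for _ in windows]
    n_orphan = 0
    frames = sorted(frames, key=lambda r: r.timestamp)
    wi = 0
    for rec in frames:
        while wi < len(windows) and rec.timestamp >= windows[wi].end:
            wi += 1
        if wi < len(windows) and windows[wi].start <= rec.timestamp < windows[wi].end:
            buckets[wi].append(rec)
        else:
            n_orphan += 1
    if n_orphan:
        logger.info("ignored %d frames outside all trial windows", n_orphan)
    return [score_trial(bucket, win, cfg)
            for bucket, win in zip(buckets, windows)
            if win.kind == ACTIVE]
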