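"""Ground-truth session simulator and marker-frame renderer.

The simulator emulates what the tracking rig sees during a nose-poking
go/no-go session, so every pipeline stage is testable without animals or
recorded video:

* a trial timeline of 6 s active trials and 3 s inter-trial periods;
* a two-state latent engagement process — *engaged* until an optional
  planted disengagement time, *distracted* after it — with a per-trial
  probability of task engagement in each state;
* a per-frame head-pose trajectory (marker center + nose-ward heading)
  consistent with the latent state: engaged trials put the marker inside
  the ROI pointing at the module wall, distracted trials violate either
  the ROI gate or the yaw gate (half each, so both gates are exercised);
* per-camera detection dropout (occlusion) deleting observations
  independently per frame.

Everything is deterministic for a fixed seed.  The renderer rasterizes a
marker bitmap under rotation + translation with a white quiet zone and
optional linear motion blur, returning the planted corner ground truth so
detector accuracy can be measured against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point as _ShapelyPoint

from . import markers
from .detection import FrameRecord
from .geometry import (MarkerObservation, Point2D, RegionOfInterest,
                       WallSpec, point_in_roi, yaw_angle)
from .metrics import DISTRACTED, ENGAGED
from .scoring import (ACTIVE, INTER_TRIAL, ClassifierConfig, TrialScore,
                      TrialWindow)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of a simulated session.

    Defaults mirror the standard paradigm: 6 s active trials with 3 s
    inter-trial periods, 60 fps capture.  ``p_engaged_given_state`` gives
    the per-trial probability of task engagement in the latent engaged and
    disengaged states; the default (1, 0) is the deterministic two-state
    model, with label noise opt-in.  ``disengagement_minute`` plants a
    hard latent switch; None keeps the animal engaged throughout.
    """

    seed: int = 0
    session_length_min: float = 32.0
    trial_active_s: float = 6.0
    trial_inter_s: float = 3.0
    fps: float = 60.0
    n_cameras: int = 2
    p_engaged_given_state: tuple[float, float] = (1.0, 0.0)
    disengagement_minute: float | None = None
    dropout_prob: tuple[float, ...] = (0.0, 0.0)
    marker_size_px: float = 48.0
    frame_size: tuple[int, int] = (640, 480)  # (width, height)

    def __post_init__(self) -> None:
        if self.n_cameras not in (1, 2):
            raise ValueError("n_cameras must be 1 or 2")
        if not all(0.0 <= p <= 1.0 for p in self.p_engaged_given_state):
            raise ValueError("probabilities must be in [0, 1]")
        if not all(0.0 <= p <= 1.0 for p in self.dropout_prob):
            raise ValueError("dropout probabilities must be in [0, 1]")
        if min(self.session_length_min, self.trial_active_s,
               self.trial_inter_s, self.fps, self.marker_size_px) <= 0:
            raise ValueError("durations, fps and marker size must be positive")


@dataclass(frozen=True)
class SimulatedSession:
    """Simulator output: timeline, per-camera streams, and ground truth."""

    trial_windows: tuple[TrialWindow, ...]
    streams: tuple[tuple[FrameRecord, ...], ...]
    ground_truth: tuple[TrialScore, ...]
    camera_ids: tuple[str, ...]


def default_classifier_config(
    n_cameras: int = 2,
    frame_size: tuple[int, int] = (640, 480),
    target_marker_id: int = 0,
) -> ClassifierConfig:
    """Classifier geometry for the simulated chamber.

    The module wall is the right-hand image edge region; the engagement
    ROI spans from the chamber midline to that wall, mirroring the
    standard rig layout, identically for each overhead camera.
    """
    w, h = frame_size
    cams = tuple(f"cam{i + 1}" for i in range(n_cameras))
    rois = {}
    walls = {}
    margin = 0.08 * min(w, h)
    for cam in cams:
        rois[cam] = (RegionOfInterest(camera_id=cam, vertices=(
            Point2D(w / 2, margin), Point2D(w - margin, margin),
            Point2D(w - margin, h - margin), Point2D(w / 2, h - margin))),)
        walls[cam] = WallSpec(p0=Point2D(w - margin, margin),
                              p1=Point2D(w - margin, h - margin),
                              interior_hint=Point2D(w / 2, h / 2))
    return ClassifierConfig(rois=rois, walls=walls, front_edge=0,
                            target_marker_id=target_marker_id)


def build_trial_windows(cfg: SimConfig) -> tuple[TrialWindow, ...]:
    """Alternating active / inter-trial timeline filling the session."""
    windows: list[TrialWindow] = []
    t = 0.0
    idx = 0
    end_s = cfg.session_length_min * 60.0
    while t + cfg.trial_active_s <= end_s + 1e-9:
        windows.append(TrialWindow(trial_index=idx, kind=ACTIVE, start=t,
                                   end=t + cfg.trial_active_s))
        t_inter = t + cfg.trial_active_s
        if t_inter < end_s:
            windows.append(TrialWindow(
                trial_index=idx, kind=INTER_TRIAL, start=t_inter,
                end=min(t_inter + cfg.trial_inter_s, end_s)))
        t += cfg.trial_active_s + cfg.trial_inter_s
        idx += 1
    if not windows:
        raise ValueError("session too short for a single trial")
    return tuple(windows)


def _heading_from_yaw(yaw_deg: float, wall: WallSpec) -> np.ndarray:
    w = wall.direction()
    n = wall.toward_wall_normal()
    r = math.radians(yaw_deg)
    return math.cos(r) * w + math.sin(r) * n


def corners_from_pose(center: Point2D, heading: np.ndarray,
                      size_px: float) -> tuple[Point2D, ...]:
    """Square marker corners (canonical order) from center + heading.

    The front (nose-side) edge is the canonical top edge (corners 0-1),
    matching front_edge = 0.
    """
    u = np.asarray(heading, dtype=float)
    u = u / np.linalg.norm(u)
    r = np.array([-u[1], u[0]])  # screen-right when u is screen-up
    c = center.as_array()
    half = size_px / 2.0
    pts = [c + half * u - half * r, c + half * u + half * r,
           c - half * u + half * r, c - half * u - half * r]
    return tuple(Point2D(float(p[0]), float(p[1])) for p in pts)


def _sample_point_in_roi(rng: np.random.Generator, roi: RegionOfInterest,
                         shrink: float = 0.15) -> Point2D:
    """Uniform rejection sample inside the ROI, away from its boundary."""
    poly = roi._poly.buffer(-shrink * math.sqrt(roi._poly.area))
    if poly.is_empty:
        poly = roi._poly
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(1000):
        p = _ShapelyPoint(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if poly.covers(p):
            return Point2D(p.x, p.y)
    raise ValueError("classifier ROI is geometrically unsatisfiable")


def _sample_point_outside_rois(
        rng: np.random.Generator, rois: Sequence[RegionOfInterest],
        frame_size: tuple[int, int], margin: float) -> Point2D:
    w, h = frame_size
    for _ in range(1000):
        cand = Point2D(rng.uniform(margin, w - margin),
                       rng.uniform(margin, h - margin))
        if not any(r._poly.buffer(margin).covers(_ShapelyPoint(cand.x, cand.y))
                   for r in rois):
            return cand
    raise ValueError("no space outside the ROIs for a distracted pose")


def simulate_session(cfg: SimConfig,
                     classifier: ClassifierConfig | None = None
                     ) -> SimulatedSession:
    """Simulate one behavioral session.

    Returns the trial timeline, per-camera FrameRecord streams (after
    dropout), and ground-truth trial scores computed from the latent
    (pre-dropout) frames by the any-frame rule.  Deterministic for a
    fixed ``cfg.seed``.
    """
    if classifier is None:
        classifier = default_classifier_config(cfg.n_cameras, cfg.frame_size)
    rng = np.random.default_rng(cfg.seed)
    windows = build_trial_windows(cfg)
    cam_ids = tuple(sorted(classifier.rois))[:cfg.n_cameras]
    if len(cam_ids) < cfg.n_cameras:
        raise ValueError("classifier config covers fewer cameras than requested")

    switch_s = (None if cfg.disengagement_minute is None
                else cfg.disengagement_minute * 60.0)

    # per-trial latent engagement and base pose (one pose process per trial,
    # shared by active and following inter-trial window)
    active = [w for w in windows if w.kind == ACTIVE]
    trial_engaged: dict[int, bool] = {}
    trial_pose: dict[int, tuple[Point2D, float]] = {}  # center, yaw
    p_eng, p_dis = cfg.p_engaged_given_state
    for w in active:
        state_engaged = switch_s is None or w.start < switch_s
        p = p_eng if state_engaged else p_dis
        engaged = bool(rng.random() < p)
        trial_engaged[w.trial_index] = engaged
        cam0 = cam_ids[0]
        rois, wall = classifier.for_camera(cam0)
        if engaged:
            center = _sample_point_in_roi(rng, rois[0])
            yaw = float(rng.uniform(classifier.yaw_min + 10.0,
                                    classifier.yaw_max - 10.0))
        elif rng.random() < 0.5:  # ROI-violating distraction
            center = _sample_point_outside_rois(
                rng, rois, cfg.frame_size, cfg.marker_size_px)
            yaw = float(rng.uniform(-180.0, 180.0))
        else:  # yaw-violating distraction (facing away from the wall)
            center = _sample_point_in_roi(rng, rois[0])
            yaw = float(rng.uniform(-170.0, -10.0))
        trial_pose[w.trial_index] = (center, yaw)

    # frame grid over the whole session
    n_frames = int(math.floor(cfg.session_length_min * 60.0 * cfg.fps))
    dt = 1.0 / cfg.fps
    session_end = cfg.session_length_min * 60.0

    # locate the window for each frame time (windows tile the session)
    win_starts = np.array([w.start for w in windows])
    frame_times = np.arange(n_frames) * dt
    win_of_frame = np.searchsorted(win_starts, frame_times, side="right") - 1

    dropout = list(cfg.dropout_prob) + [0.0] * cfg.n_cameras
    keep = [rng.random(n_frames) >= dropout[ci]
            for ci in range(cfg.n_cameras)]
    jitter_xy = rng.normal(0.0, 1.5, size=(n_frames, 2))
    jitter_yaw = rng.normal(0.0, 2.0, size=n_frames)

    _, wall0 = classifier.for_camera(cam_ids[0])
    streams: list[list[FrameRecord]] = [[] for _ in cam_ids]
    latent_engaged_frame = np.zeros(n_frames, dtype=bool)

    for fi in range(n_frames):
        t = float(frame_times[fi])
        w = windows[win_of_frame[fi]]
        center, yaw = trial_pose[w.trial_index]
        cx = center.x + jitter_xy[fi, 0]
        cy = center.y + jitter_xy[fi, 1]
        yaw_f = yaw + jitter_yaw[fi]
        heading = _heading_from_yaw(yaw_f, wall0)
        corners = corners_from_pose(Point2D(cx, cy), heading,
                                    cfg.marker_size_px)
        if w.kind == ACTIVE and trial_engaged[w.trial_index]:
            # jitter must not carry the pose across a classifier gate
            rois, wall = classifier.for_camera(cam_ids[0])
            in_roi = any(point_in_roi(Point2D(cx, cy), r) for r in rois)
            good_yaw = (classifier.yaw_min <= yaw_angle(heading, wall)
                        <= classifier.yaw_max)
            if not (in_roi and good_yaw):
                heading = _heading_from_yaw(yaw, wall0)
                corners = corners_from_pose(center, heading,
                                            cfg.marker_size_px)
                cx, cy = center.x, center.y
            latent_engaged_frame[fi] = True
        for ci, cam in enumerate(cam_ids):
            obs = ()
            if keep[ci][fi]:
                obs = (MarkerObservation(
                    camera_id=cam, frame_index=fi, timestamp=t,
                    marker_id=classifier.target_marker_id,
                    corners=corners),)
            streams[ci].append(FrameRecord(camera_id=cam, frame_index=fi,
                                           timestamp=t, observations=obs))

    # ground truth by the any-frame rule on latent (pre-dropout) frames
    truth: list[TrialScore] = []
    for w in active:
        in_w = (frame_times >= w.start) & (frame_times < w.end)
        n_eng = int(latent_engaged_frame[in_w].sum())
        first = (float(frame_times[in_w][latent_engaged_frame[in_w]][0])
                 if n_eng else None)
        truth.append(TrialScore(
            trial_index=w.trial_index,
            label=ENGAGED if n_eng else DISTRACTED,
            n_frames_seen=int(in_w.sum()), n_frames_engaged=n_eng,
            first_engaged_timestamp=first,
            n_frames_detected=int(in_w.sum())))
    return SimulatedSession(trial_windows=windows,
                            streams=tuple(tuple(s) for s in streams),
                            ground_truth=tuple(truth), camera_ids=cam_ids)


def simulate_engagement_series(cfg: SimConfig):
    """Trial-label series from the latent process alone (no frames).

    For dynamics studies — changepoint recovery over long or repeated
    sessions — only the per-trial labels matter, so this skips pose and
    frame generation entirely.  Deterministic for a fixed seed.
    """
    from .dynamics import EngagementSeries
    rng = np.random.default_rng(cfg.seed)
    windows = build_trial_windows(cfg)
    switch_s = (None if cfg.disengagement_minute is None
                else cfg.disengagement_minute * 60.0)
    p_eng, p_dis = cfg.p_engaged_given_state
    starts, labels = [], []
    for w in windows:
        if w.kind != ACTIVE:
            continue
        p = p_eng if (switch_s is None or w.start < switch_s) else p_dis
        starts.append(w.start)
        labels.append(ENGAGED if rng.random() < p else DISTRACTED)
    return EngagementSeries.from_lists(starts, labels)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_marker_frame(
    bitmap: np.ndarray,
    center: Point2D,
    angle_deg: float,
    size_px: float,
    frame_size: tuple[int, int] = (640, 480),
    blur_kernel_px: float = 0.0,
    background: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a marker bitmap into a frame; return (image, corners).

    ``bitmap`` is either the 4x4 payload or the full 6x6 module grid
    (1 = white).  ``angle_deg`` is the in-plane rotation: 0 renders the
    pattern upright (nose-ward heading pointing up the image); positive
    angles rotate clockwise on screen.  ``size_px`` is the side length of
    the black border square.  A one-module white quiet zone is rendered
    around the border.  Optional linear motion blur convolves the frame
    with a ``blur_kernel_px``-long kernel along the heading direction.

    Returns the float image in [0, 1] and the planted outer-border corner
    coordinates, shape (4, 2), canonical order.
    """
    from skimage.transform import AffineTransform, warp

    bm = np.asarray(bitmap, dtype=float)
    if bm.shape == (markers.GRID_BITS, markers.GRID_BITS):
        grid = np.zeros((markers.MARKER_MODULES, markers.MARKER_MODULES))
        grid[1:-1, 1:-1] = bm
    elif bm.shape == (markers.MARKER_MODULES, markers.MARKER_MODULES):
        grid = bm
    else:
        raise ValueError(f"bitmap must be 4x4 or 6x6, got {bm.shape}")

    q = markers.QUIET_MODULES
    m = markers.MARKER_MODULES + 2 * q  # modules incl. quiet zone
    card = np.ones((m, m))
    card[q:-q, q:-q] = grid

    F = 16  # hires pixels per module
    hires = np.kron(card, np.ones((F, F)))
    hires = ndi.gaussian_filter(hires, sigma=1.2)  # soft printed/optics edge

    c0 = (m * F - 1) / 2.0  # hires center (pixel-center convention)
    scale = size_px / (markers.MARKER_MODULES * F)
    theta = math.radians(angle_deg)
    tf = (AffineTransform(translation=(-c0, -c0))
          + AffineTransform(scale=(scale, scale))
          + AffineTransform(rotation=theta)
          + AffineTransform(translation=(center.x, center.y)))

    # planted pattern corners: black-border square in hires coords
    lo, hi = q * F - 0.5, (m - q) * F - 0.5
    src_corners = np.array([[lo, lo], [hi, lo], [hi, hi], [lo, lo + (hi - lo)]])
    src_corners[3] = [lo, hi]
    corners = tf(src_corners)

    w, h = frame_size
    quiet_lo, quiet_hi = -0.5, m * F - 0.5
    quiet_src = np.array([[quiet_lo, quiet_lo], [quiet_hi, quiet_lo],
                          [quiet_hi, quiet_hi], [quiet_lo, quiet_hi]])
    quiet_img = tf(quiet_src)
    if (quiet_img[:, 0].min() < 0 or quiet_img[:, 1].min() < 0
            or quiet_img[:, 0].max() > w - 1 or quiet_img[:, 1].max() > h - 1):
        raise ValueError("marker (incl. quiet zone) extends past the frame")

    img = warp(hires, inverse_map=tf.inverse, output_shape=(h, w),
               order=1, cval=1.0, mode="constant")
    # outside the card: background
    yy, xx = np.mgrid[0:h, 0:w]
    inv = tf.inverse(np.column_stack([xx.ravel(), yy.ravel()]))
    outside = ((inv[:, 0] < quiet_lo) | (inv[:, 0] > quiet_hi)
               | (inv[:, 1] < quiet_lo) | (inv[:, 1] > quiet_hi))
    img = img.ravel()
    img[outside] = background
    img = img.reshape(h, w)

    if blur_kernel_px and blur_kernel_px > 0:
        heading = np.array([math.sin(theta), -math.cos(theta)])
        img = _motion_blur(img, heading, float(blur_kernel_px))
    return np.clip(img, 0.0, 1.0), corners


def _motion_blur(img: np.ndarray, direction: np.ndarray,
                 length_px: float) -> np.ndarray:
    """Linear motion blur: average along a segment of given pixel length."""
    d = direction / np.linalg.norm(direction)
    half = length_px / 2.0
    n = max(int(math.ceil(length_px * 4)), 2)
    ts = np.linspace(-half, half, n)
    k = int(math.ceil(half)) + 1
    kernel = np.zeros((2 * k + 1, 2 * k + 1))
    for t in ts:
        x, y = t * d[0] + k, t * d[1] + k
        x0, y0 = int(math.floor(x)), int(math.floor(y))
        fx, fy = x - x0, y - y0
        kernel[y0, x0] += (1 - fx) * (1 - fy)
        kernel[y0, x0 + 1] += fx * (1 - fy)
        kernel[y0 + 1, x0] += (1 - fx) * fy
        kernel[y0 + 1, x0 + 1] += fx * fy
    kernel /= kernel.sum()
    return ndi.convolve(img, kernel, mode="nearest")
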