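"""Fiducial-marker detection in raster frames and multi-camera fusion.

The detector finds square black-bordered markers by the classical pipeline:
global threshold, connected dark components, quadrilateral fitting on the
component contour, projective rectification of the 6x6 module grid, payload
read-out and dictionary match under all four rotations, then subpixel
corner refinement by intersecting least-squares lines fitted to the four
contour edges.  It is deterministic for a fixed frame.

Multi-camera fusion pairs frames across streams by nearest timestamp
(within half a frame period, since real capture clocks drift), takes the
logical OR of detections, and tallies the per-frame coverage account
(camera-1 exclusive / camera-2 exclusive / both / neither) used to quantify
what a second viewpoint buys.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu

from . import markers
from .geometry import MarkerObservation, Point2D

logger = logging.getLogger(__name__)

#: Reject candidate quads smaller than this many pixels of dark area.
MIN_QUAD_AREA_PX = 64.0


@dataclass(frozen=True)
class FrameRecord:
    """All marker observations in one frame of one camera (possibly none)."""

    camera_id: str
    frame_index: int
    timestamp: float
    observations: tuple[MarkerObservation, ...] = ()

    @property
    def detected(self) -> bool:
        return len(self.observations) > 0


@dataclass(frozen=True)
class FrameAccount:
    """Per-frame detection coverage over paired two-camera frames.

    The four categories partition the paired frames:
    n_cam1_only + n_cam2_only + n_both + n_neither == n_total_frames.
    """

    n_total_frames: int
    n_cam1_only: int
    n_cam2_only: int
    n_both: int
    n_neither: int

    def __post_init__(self) -> None:
        parts = (self.n_cam1_only, self.n_cam2_only, self.n_both,
                 self.n_neither)
        if any(v < 0 for v in (self.n_total_frames, *parts)):
            raise ValueError("frame counts must be non-negative")
        if sum(parts) != self.n_total_frames:
            raise ValueError("coverage categories must partition the frames")

    @property
    def fused_coverage(self) -> float:
        """Fraction of paired frames with a detection from any camera."""
        if self.n_total_frames == 0:
            return 0.0
        return (self.n_cam1_only + self.n_cam2_only
                + self.n_both) / self.n_total_frames


# ---------------------------------------------------------------------------
# single-frame detection
# ---------------------------------------------------------------------------

def _as_gray(frame: np.ndarray) -> np.ndarray:
    """Accept 8-bit or float, gray or RGB(A); return float gray in [0, 1]."""
    img = np.asarray(frame)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    elif img.ndim != 2:
        raise IOError(f"unreadable frame with shape {img.shape}")
    img = img.astype(float)
    if img.size == 0:
        raise IOError("empty frame")
    if img.max() > 1.0:
        img = img / 255.0
    return img


def _order_clockwise(pts: np.ndarray) -> np.ndarray:
    """Order 4 points clockwise as seen on screen (y-down raster coords)."""
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    # increasing atan2 angle in y-down coordinates IS clockwise on screen
    return pts[np.argsort(ang)]


def _fit_quad(contour_xy: np.ndarray) -> np.ndarray | None:
    """Fit 4 corner vertices to a closed contour; None if not quad-like."""
    if len(contour_xy) < 8:
        return None
    c = contour_xy.mean(axis=0)
    r = np.linalg.norm(contour_xy - c, axis=1)
    # seed corner: farthest point from centroid
    corners_idx = [int(np.argmax(r))]
    # greedily add the point maximizing summed distance to chosen corners
    for _ in range(3):
        d = np.zeros(len(contour_xy))
        for i in corners_idx:
            d += np.linalg.norm(contour_xy - contour_xy[i], axis=1)
        corners_idx.append(int(np.argmax(d)))
    quad = contour_xy[sorted(set(corners_idx))]
    if len(quad) != 4:
        return None
    quad = _order_clockwise(quad)
    area = 0.5 * abs(sum(
        quad[i, 0] * quad[(i + 1) % 4, 1] - quad[(i + 1) % 4, 0] * quad[i, 1]
        for i in range(4)))
    if area < MIN_QUAD_AREA_PX:
        return None
    # every contour point must lie near the quad outline (quad-likeness)
    max_dev = _max_contour_deviation(contour_xy, quad)
    diag = max(np.ptp(quad[:, 0]), np.ptp(quad[:, 1]))
    if max_dev > max(2.0, 0.12 * diag):
        return None
    return quad


def _max_contour_deviation(contour_xy: np.ndarray, quad: np.ndarray) -> float:
    dmin = np.full(len(contour_xy), np.inf)
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        dmin = np.minimum(dmin, _point_segment_distance(contour_xy, a, b))
    return float(dmin.max())


def _point_segment_distance(pts: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
    proj = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, pts.shape)
    return np.linalg.norm(pts - proj, axis=1)


def _refine_corners(contour_xy: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Subpixel corners: intersect total-least-squares lines per edge.

    Contour points are assigned to their nearest quad edge; points within
    15% of the edge length of either endpoint are dropped (corner rounding
    from blur/rasterization), and each edge line is fitted by PCA.
    """
    dists = np.stack([
        _point_segment_distance(contour_xy, quad[i], quad[(i + 1) % 4])
        for i in range(4)])
    owner = np.argmin(dists, axis=0)
    lines = []
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        pts = contour_xy[owner == i]
        if len(pts) >= 4:
            ab = b - a
            L = np.linalg.norm(ab)
            t = ((pts - a) @ ab) / (L * L)
            pts = pts[(t > 0.15) & (t < 0.85)]
        if len(pts) < 2:
            lines.append(None)
            continue
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
        lines.append((mean, vt[0]))
    refined = quad.copy()
    for i in range(4):
        l1, l2 = lines[i - 1], lines[i]  # edges meeting at corner i
        if l1 is None or l2 is None:
            continue
        p = _line_intersection(l1, l2)
        if p is not None and np.linalg.norm(p - quad[i]) < 5.0:
            refined[i] = p
    return refined


def _line_intersection(l1, l2) -> np.ndarray | None:
    (p1, d1), (p2, d2) = l1, l2
    det = d1[0] * (-d2[1]) - (-d2[0]) * d1[1]
    if abs(det) < 1e-9:
        return None
    rhs = p2 - p1
    t = (rhs[0] * (-d2[1]) - (-d2[0]) * rhs[1]) / det
    return p1 + t * d1


def _sample_bilinear(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    # map_coordinates expects (row, col) = (y, x)
    return ndi.map_coordinates(img, [xy[:, 1], xy[:, 0]], order=1,
                               mode="nearest")


def _projective_from_unit_grid(quad: np.ndarray) -> "np.ndarray":
    """Homography mapping module coords (u,v) in [0,6]^2 to image coords.

    u runs along quad edge 0->1, v along edge 0->3.
    """
    from skimage.transform import ProjectiveTransform
    n = markers.MARKER_MODULES
    src = np.array([[0, 0], [n, 0], [n, n], [0, n]], dtype=float)
    tf = ProjectiveTransform.from_estimate(src, quad)
    if not tf:
        raise RuntimeError("degenerate quad: homography estimation failed")
    return tf


def _read_payload(gray: np.ndarray, quad: np.ndarray) -> np.ndarray | None:
    """Sample the 6x6 module grid; return the 4x4 payload bits or None."""
    n = markers.MARKER_MODULES
    tf = _projective_from_unit_grid(quad)
    # 3x3 sample points per module, away from module borders
    offs = np.array([0.3, 0.5, 0.7])
    uu, vv = np.meshgrid(offs, offs)
    samples = np.zeros((n, n))
    for i in range(n):  # module row (v)
        for j in range(n):  # module col (u)
            pts = np.column_stack([j + uu.ravel(), i + vv.ravel()])
            vals = _sample_bilinear(gray, tf(pts))
            samples[i, j] = float(np.median(vals))
    lo, hi = samples.min(), samples.max()
    if hi - lo < 0.15:  # no contrast: not a marker
        return None
    bits = (samples > (lo + hi) / 2.0).astype(np.uint8)
    if bits[0, :].any() or bits[-1, :].any() or bits[:, 0].any() \
            or bits[:, -1].any():
        return None  # border must be fully black
    b = markers.BORDER_MODULES
    return bits[b:-b, b:-b]


def detect_markers(
    frame: np.ndarray,
    camera_id: str = "cam",
    frame_index: int = 0,
    timestamp: float = 0.0,
    target_marker_id: int | None = None,
    n_markers: int = 50,
) -> list[MarkerObservation]:
    """Detect dictionary markers in one frame.

    Returns zero or more observations with corners in canonical order
    (pattern top-left first, then clockwise).  When ``target_marker_id``
    is given, detections of other IDs are dropped.  Deterministic for a
    fixed frame.
    """
    gray = _as_gray(frame)
    if np.ptp(gray) < 0.1:  # uniform frame: nothing to threshold
        return []
    thr = threshold_otsu(gray)
    dark = gray < thr
    labeled, n_comp = ndi.label(dark)
    if n_comp == 0:
        return []
    table = markers.rotation_code_table(n_markers)
    out: list[MarkerObservation] = []
    objects = ndi.find_objects(labeled)
    for comp_idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labeled[sl] == comp_idx
        if mask.sum() < MIN_QUAD_AREA_PX:
            continue
        padded = np.pad(mask.astype(float), 2)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # find_contours yields (row, col); convert to (x, y) in full-frame coords
        offset = np.array([sl[1].start - 2, sl[0].start - 2], dtype=float)
        contour_xy = contour[:, ::-1] + offset
        quad = _fit_quad(contour_xy)
        if quad is None:
            continue
        quad = _refine_corners(contour_xy, quad)
        payload = _read_payload(gray, quad)
        if payload is None:
            continue
        hit = table.get(markers.bits_to_code(payload))
        if hit is None:
            continue
        marker_id, k = hit
        if target_marker_id is not None and marker_id != target_marker_id:
            continue
        canon = np.roll(quad, shift=k, axis=0)
        corners = tuple(Point2D(float(x), float(y)) for x, y in canon)
        out.append(MarkerObservation(camera_id=camera_id,
                                     frame_index=frame_index,
                                     timestamp=timestamp,
                                     marker_id=marker_id,
                                     corners=corners))  # type: ignore[arg-type]
    return out


# ---------------------------------------------------------------------------
# multi-camera fusion
# ---------------------------------------------------------------------------

def _median_frame_period(streams: Sequence[Sequence[FrameRecord]]) -> float:
    diffs: list[float] = []
    for stream in streams:
        ts = [r.timestamp for r in stream]
        diffs.extend(b - a for a, b in zip(ts, ts[1:]))
    return float(np.median(diffs)) if diffs else 1.0 / 60.0


def fuse_streams(
    streams: Sequence[Sequence[FrameRecord]],
    pair_tolerance_s: float | None = None,
) -> tuple[list[FrameRecord], FrameAccount]:
    """Fuse per-camera frame streams into one observation sequence.

    Frames are paired across cameras by nearest timestamp within
    ``pair_tolerance_s`` (default: half the median frame period).  Each
    fused record carries the union of observations from every paired
    camera — the logical OR of detection.  The FrameAccount tallies, over
    paired frames, which camera(s) detected the marker; with a single
    stream the fused sequence is the input and the camera-2 categories are
    zero.

    Frames that cannot be paired (clock drift beyond tolerance) are kept
    as their own fused records, with a warning.
    """
    streams = [list(s) for s in streams]
    if not streams or all(len(s) == 0 for s in streams):
        raise ValueError("need at least one non-empty stream")
    for s in streams:
        ts = [r.timestamp for r in s]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be non-decreasing per stream")
    cam_ids = [s[0].camera_id if s else f"cam{i}"
               for i, s in enumerate(streams)]
    if len(streams) > 2:
        raise ValueError("coverage accounting is defined for 1 or 2 cameras")

    tol = pair_tolerance_s if pair_tolerance_s is not None \
        else 0.5 * _median_frame_period(streams)

    events = sorted(
        ((rec.timestamp, si, rec) for si, s in enumerate(streams) for rec in s),
        key=lambda e: (e[0], e[1]))
    clusters: list[dict[int, FrameRecord]] = []
    cur: dict[int, FrameRecord] = {}
    cur_t0 = None
    n_unpaired = 0
    for ts, si, rec in events:
        if cur_t0 is not None and (ts - cur_t0) <= tol and si not in cur:
            cur[si] = rec
        else:
            if cur:
                clusters.append(cur)
            cur = {si: rec}
            cur_t0 = ts
    if cur:
        clusters.append(cur)

    if len(streams) == 2:
        n_unpaired = sum(1 for c in clusters if len(c) < 2)
        if n_unpaired:
            warnings.warn(
                f"{n_unpaired} frames could not be paired across cameras "
                "(clock drift beyond tolerance); counted per-camera",
                stacklevel=2)

    fused: list[FrameRecord] = []
    n1 = n2 = nb = nn = 0
    for fi, cluster in enumerate(clusters):
        recs = [cluster[si] for si in sorted(cluster)]
        obs = tuple(o for r in recs for o in r.observations)
        fused.append(FrameRecord(camera_id="fused", frame_index=fi,
                                 timestamp=min(r.timestamp for r in recs),
                                 observations=obs))
        d1 = 0 in cluster and cluster[0].detected
        d2 = 1 in cluster and cluster[1].detected
        if d1 and d2:
            nb += 1
        elif d1:
            n1 += 1
        elif d2:
            n2 += 1
        else:
            nn += 1
    account = FrameAccount(n_total_frames=len(clusters), n_cam1_only=n1,
                           n_cam2_only=n2, n_both=nb, n_neither=nn)
    return fused, account
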