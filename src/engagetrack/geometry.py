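"""Planar geometry for head-mounted fiducial markers.

Everything here works in raster image coordinates: origin at the top-left
corner, x increasing rightward, y increasing downward, units of pixels.
The functions are pure and carry no imaging dependencies; they are the
substrate for both the classifier (ROI + yaw gates) and the synthetic
session generator.

Conventions
-----------
* Marker corners are stored in the detector's canonical order: corner 0 is
  the pattern's top-left cell, then clockwise (as the upright pattern is
  read), i.e. 0 -> 1 is the pattern's top edge.
* The *heading* of a marker is the unit vector from its center toward the
  midpoint of its nose-side ("front") edge.  Which physical edge faces the
  animal's nose depends on how the mount is glued, so the front edge index
  is configuration, not geometry.
* Yaw is measured against the chamber's module wall (the wall holding the
  nose-poke and reward ports): 90 deg means the heading points squarely at
  the wall, 0/180 deg graze along it, and negative values point away from
  it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon


class DegeneratePoseError(ValueError):
    """Marker quadrilateral collapses: no center/heading can be derived."""


def _seg_cross(p, q, r, s) -> bool:
    """True iff open segments pq and rs properly intersect."""
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return int(v > 0) - int(v < 0)
    return (orient(p, q, r) * orient(p, q, s) < 0
            and orient(r, s, p) * orient(r, s, q) < 0)


def _is_simple_quad(pts) -> bool:
    """Cheap validity check: nonzero area, non-crossing opposite edges."""
    area2 = sum(pts[i][0] * pts[(i + 1) % 4][1]
                - pts[(i + 1) % 4][0] * pts[i][1] for i in range(4))
    if area2 == 0.0:
        return False
    # a quad self-intersects iff one pair of opposite edges crosses
    return not (_seg_cross(pts[0], pts[1], pts[2], pts[3])
                or _seg_cross(pts[1], pts[2], pts[3], pts[0]))


@dataclass(frozen=True)
class Point2D:
    """A point in image coordinates (pixels, origin top-left, y down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class MarkerObservation:
    """One detected marker in one frame of one camera.

    ``corners`` holds exactly four points in canonical order (pattern
    top-left first, then clockwise).  The quadrilateral must be simple
    (non-self-intersecting) with nonzero area.
    """

    camera_id: str
    frame_index: int
    timestamp: float
    marker_id: int
    corners: tuple[Point2D, Point2D, Point2D, Point2D]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if len(self.corners) != 4:
            raise ValueError("a marker observation needs exactly 4 corners")
        pts = [(c.x, c.y) for c in self.corners]
        if not _is_simple_quad(pts):
            raise ValueError("corners must form a simple quadrilateral "
                             "with nonzero area")

    def corner_array(self) -> np.ndarray:
        """Corners as a (4, 2) float array."""
        return np.array([[c.x, c.y] for c in self.corners], dtype=float)


@dataclass(frozen=True)
class WallSpec:
    """Directed segment along the module wall in one camera's image.

    ``interior_hint`` is any point inside the chamber away from the wall;
    it orients the wall normal so that yaw signs are unambiguous even
    though camera mounting mirrors differ.
    """

    p0: Point2D
    p1: Point2D
    interior_hint: Point2D

    def __post_init__(self) -> None:
        d = self.p1.as_array() - self.p0.as_array()
        if np.allclose(d, 0.0):
            raise ValueError("wall endpoints coincide")
        # interior_hint must be off the wall line
        r = self.interior_hint.as_array() - self.p0.as_array()
        cross = d[0] * r[1] - d[1] * r[0]
        if abs(cross) <= 1e-12 * max(1.0, float(np.linalg.norm(d)) ** 2):
            raise ValueError("interior_hint lies on the wall line")

    def direction(self) -> np.ndarray:
        """Unit vector along the wall, p0 -> p1."""
        d = self.p1.as_array() - self.p0.as_array()
        return d / np.linalg.norm(d)

    def toward_wall_normal(self) -> np.ndarray:
        """Unit normal of the wall pointing from the interior toward it."""
        w = self.direction()
        n = np.array([-w[1], w[0]])
        # flip if n points from the wall toward the interior hint
        r = self.interior_hint.as_array() - self.p0.as_array()
        if float(np.dot(n, r)) > 0.0:
            n = -n
        return n


@dataclass(frozen=True)
class RegionOfInterest:
    """A simple polygon in one camera's pixel frame.

    Several ROIs per camera are allowed; engagement requires the marker
    center inside at least one.  The boundary counts as inside.
    """

    camera_id: str
    vertices: tuple[Point2D, ...]
    _poly: _ShapelyPolygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("an ROI polygon needs at least 3 vertices")
        poly = _ShapelyPolygon([(v.x, v.y) for v in self.vertices])
        if not poly.is_valid or poly.area == 0.0:
            raise ValueError("ROI polygon must be simple with nonzero area")
        object.__setattr__(self, "_poly", poly)


def pose_from_corners(
    obs: MarkerObservation, front_edge: int
) -> tuple[Point2D, np.ndarray]:
    """Marker center and nose-ward heading from its four corners.

    Parameters
    ----------
    obs
        The detected marker; corners in canonical order.
    front_edge
        Index k in 0..3 selecting the corner pair (k, k+1 mod 4) that is
        the edge nearest the animal's nose.

    Returns
    -------
    center : Point2D
        Arithmetic mean of the four corners.
    heading : ndarray, shape (2,)
        Unit vector from the center toward the midpoint of the front edge.

    Raises
    ------
    DegeneratePoseError
        If the front-edge midpoint coincides with the center (no direction
        can be derived).
    """
    if front_edge not in (0, 1, 2, 3):
        raise ValueError("front_edge must be in 0..3")
    pts = obs.corner_array()
    center = pts.mean(axis=0)
    mid = (pts[front_edge] + pts[(front_edge + 1) % 4]) / 2.0
    v = mid - center
    norm = float(np.linalg.norm(v))
    scale = float(np.abs(pts).max()) or 1.0
    if norm <= 1e-9 * scale:
        raise DegeneratePoseError(
            "front-edge midpoint coincides with marker center")
    return Point2D(float(center[0]), float(center[1])), v / norm


def yaw_angle(heading: Sequence[float] | np.ndarray, wall: WallSpec) -> float:
    """Yaw of a heading vector relative to the module wall, in degrees.

    Returns atan2(h . n, h . w) in (-180, 180], where w is the unit wall
    direction and n the unit wall normal pointing from the chamber
    interior toward the wall.  90 means facing the wall squarely, 0 and
    180 mean parallel to it, negative values point away from the wall.
    The value is invariant under translation and uniform scaling of the
    scene.
    """
    h = np.asarray(heading, dtype=float)
    norm = float(np.linalg.norm(h))
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError("heading must be a non-zero finite vector")
    h = h / norm
    w = wall.direction()
    n = wall.toward_wall_normal()
    ang = math.degrees(math.atan2(float(np.dot(h, n)), float(np.dot(h, w))))
    if ang <= -180.0:  # atan2 returns (-180, 180]; normalize the edge case
        ang += 360.0
    return ang


def point_in_roi(p: Point2D, roi: RegionOfInterest) -> bool:
    """True iff ``p`` lies inside or on the boundary of the ROI polygon."""
    return bool(roi._poly.covers(_ShapelyPoint(p.x, p.y)))
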