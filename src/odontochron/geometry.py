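"""Planar geometry primitives for digitized thin-section tracings.

All coordinates are micrometres (µm) in the section plane, with an
arbitrary origin and orientation: every downstream quantity (segment
lengths, EDJ arc positions, stria intersections) is built from arc
lengths and distances only, so no global coordinate convention is
imposed on the input tracings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon


@dataclass(frozen=True)
class Point2D:
    """A point in the section plane, in µm."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates: ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


class Polyline:
    """An ordered open polyline (≥2 vertices, no repeated consecutive points).

    Parameters
    ----------
    points
        Sequence of (x, y) pairs or :class:`Point2D`, in µm.
    dedup
        Collapse exactly repeated consecutive vertices instead of
        rejecting them (used when ingesting raw digitizer exports).
    """

    def __init__(self, points: Iterable, dedup: bool = False):
        arr = np.asarray(
            [(p.x, p.y) if isinstance(p, Point2D) else tuple(p) for p in points],
            dtype=float,
        )
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("polyline needs an (n, 2) coordinate array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("polyline has non-finite coordinates")
        if dedup and len(arr) > 1:
            keep = np.ones(len(arr), dtype=bool)
            keep[1:] = np.any(np.diff(arr, axis=0) != 0.0, axis=1)
            arr = arr[keep]
        if len(arr) < 2:
            raise ValueError("polyline needs at least 2 distinct points")
        seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("polyline has repeated consecutive points")
        self._coords = arr
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])
        self._line = LineString(arr)

    # -- basic accessors -------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        """Vertex array of shape (n, 2), µm."""
        return self._coords

    @property
    def arc_length(self) -> float:
        """Total length along the polyline, µm."""
        return float(self._cum[-1])

    @property
    def shapely(self) -> LineString:
        return self._line

    def __len__(self) -> int:
        return len(self._coords)

    def __eq__(self, other) -> bool:
        return isinstance(other, Polyline) and np.array_equal(
            self._coords, other._coords
        )

    def __repr__(self) -> str:
        return f"Polyline(n={len(self)}, arc_length={self.arc_length:.3f} µm)"

    # -- arc-length parameterisation ------------------------------------
    def point_at(self, arc: float) -> Point2D:
        """Point at a given arc-length position (clamped to the ends)."""
        p = self._line.interpolate(float(np.clip(arc, 0.0, self.arc_length)))
        return Point2D(p.x, p.y)

    def project(self, point: Point2D) -> float:
        """Arc-length position of the closest point on the polyline."""
        return float(self._line.project(Point(point.x, point.y)))

    def distance_to_point(self, point: Point2D) -> float:
        return float(self._line.distance(Point(point.x, point.y)))

    def intersections_with(self, other: "Polyline") -> list[tuple[float, Point2D]]:
        """Crossings with another polyline as (arc position on self, point).

        Returned sorted by arc position. Tangential overlaps contribute
        their representative points.
        """
        inter = self._line.intersection(other._line)
        if inter.is_empty:
            return []
        geoms = getattr(inter, "geoms", [inter])
        out = []
        for g in geoms:
            if g.geom_type == "Point":
                pts = [g]
            else:  # line overlap: use its endpoints
                pts = [Point(c) for c in g.coords]
            for p in pts:
                out.append((float(self._line.project(p)), Point2D(p.x, p.y)))
        out.sort(key=lambda t: t[0])
        return out

    def reversed(self) -> "Polyline":
        return Polyline(self._coords[::-1])


def polygon_area(outline: Polyline) -> float:
    """Area (µm²) of the closed region bounded by a polyline (shoelace)."""
    ring = outline.coords
    return float(Polygon(ring).area)


def close_outline(outline: Polyline) -> Polygon:
    """Shapely polygon from an outline; first/last vertices are joined."""
    poly = Polygon(outline.coords)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def resample_arc(poly: Polyline, n: int) -> Polyline:
    """Resample a polyline at n points equally spaced in arc length."""
    arcs = np.linspace(0.0, poly.arc_length, n)
    return Polyline([(p.x, p.y) for p in (poly.point_at(a) for a in arcs)])
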