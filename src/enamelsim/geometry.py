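"""Shared planar geometry primitives.

All simulation mathematics lives on the unit square ``[0, 1]²`` with *y*
increasing upward; conversion to raster (image) convention happens only at
write time, with an explicit vertical flip.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely


@dataclass
class ContourPolyline:
    """An ordered planar polyline, open or closed.

    Closed contours store each vertex once: the closing edge from the last
    vertex back to the first is implicit.  ``units`` records whether the
    coordinates are raw digitisation pixels or simulation-domain units.
    """

    vertices: np.ndarray
    closed: bool = True
    units: str = "domain"

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.closed and len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) > 1:
            keep = np.ones(len(v), dtype=bool)
            keep[1:] = np.any(v[1:] != v[:-1], axis=1)
            v = v[keep]
        if self.closed and len(v) < 3:
            raise ValueError("closed contour needs at least 3 distinct vertices")
        if not self.closed and len(v) < 2:
            raise ValueError("open contour needs at least 2 distinct vertices")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment endpoint arrays ``(A, B)``, including the closing edge."""
        v = self.vertices
        if self.closed:
            return v, np.roll(v, -1, axis=0)
        return v[:-1], v[1:]

    def length(self) -> float:
        a, b = self.segments
        return float(np.sum(np.hypot(*(b - a).T)))

    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise closed contours."""
        if not self.closed:
            raise ValueError("signed area is defined for closed contours only")
        x, y = self.vertices.T
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def oriented_ccw(self) -> "ContourPolyline":
        if not self.closed or self.signed_area() > 0:
            return self
        return ContourPolyline(self.vertices[::-1].copy(), True, self.units)

    def bbox(self) -> tuple[float, float, float, float]:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1])

    def transformed(self, scale: float, offset: np.ndarray) -> "ContourPolyline":
        return ContourPolyline(
            self.vertices * scale + np.asarray(offset, dtype=float),
            self.closed,
            "domain",
        )

    def as_shapely(self):
        """The boundary as a shapely ``LinearRing`` / ``LineString``."""
        if self.closed:
            return shapely.LinearRing(self.vertices)
        return shapely.LineString(self.vertices)

    def polygon(self) -> shapely.Polygon:
        if not self.closed:
            raise ValueError("polygon requires a closed contour")
        return shapely.Polygon(self.vertices)

    def is_simple(self) -> bool:
        return bool(self.as_shapely().is_simple)


def point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    """Minimum distance from each point to any of the segments ``a[i]–b[i]``.

    Brute force over all point/segment pairs, chunked to bound memory.  This
    doubles as the exact geometric reference for all signed-distance work.
    """
    points = np.asarray(points, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    ab2 = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        ap = p[:, None, :] - a[None, :, :]
        t = np.clip(np.einsum("pij,ij->pi", ap, ab) / ab2, 0.0, 1.0)
        d = ap - t[:, :, None] * ab[None, :, :]
        out[s : s + chunk] = np.sqrt(np.min(np.einsum("pij,pij->pi", d, d), axis=1))
    return out


def signed_distance(contour: ContourPolyline, points: np.ndarray) -> np.ndarray:
    """Signed distance from ``points`` to a closed contour, negative inside.

    The sign comes from an orientation-independent point-in-polygon test, the
    magnitude from exact distance to the boundary (via shapely).
    """
    if not contour.closed:
        raise ValueError("signed distance requires a closed contour")
    points = np.asarray(points, dtype=float)
    boundary = shapely.LinearRing(contour.vertices)
    d = shapely.distance(shapely.points(points), boundary)
    inside = shapely.contains_xy(
        shapely.Polygon(contour.vertices), points[:, 0], points[:, 1]
    )
    return np.where(inside, -d, d)
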