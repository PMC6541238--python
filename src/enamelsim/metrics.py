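"""Measurement procedures.

Everything quantitative reported about a run comes from here: ridge/valley
thickness progression along labelled probe rays (the virtual incremental
lines), per-slice enamel area and perimeter, box-counting dimension of
binary contour rasters, slice stacking into 3D surfaces, and Hausdorff-style
distance summaries between surfaces.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import trimesh as _trimesh
from scipy import ndimage
from skimage import draw

from .contour_io import resample_by_count
from .geometry import ContourPolyline


# ---------------------------------------------------------------------------
# Thickness progression along labelled rays
# ---------------------------------------------------------------------------

@dataclass
class Landmark:
    """A labelled probe ray anchored on the EDJ, pointing outward."""

    label: str  # "ridge" or "valley"
    anchor: tuple
    direction: tuple


@dataclass
class ThicknessSeries:
    """Per-step matrix thickness at each landmark, plus label summaries."""

    table: pd.DataFrame  # columns: step, landmark, label, thickness

    def summary(self) -> pd.DataFrame:
        return (self.table.groupby(["step", "label"])["thickness"]
                .agg(["mean", "std"]).reset_index())

    def ratio(self, num: str = "ridge", den: str = "valley") -> pd.Series:
        s = self.summary().pivot(index="step", columns="label", values="mean")
        return s[num] / s[den]


def _ray_thickness(anchor, direction, contours, max_len: float = 4.0) -> float:
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    a = np.asarray(anchor, float)
    ray = shapely.LineString([a, a + max_len * direction])
    best = np.nan
    for c in contours:
        inter = ray.intersection(c.as_shapely())
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            coords = getattr(g, "coords", [])
            for xy in coords:
                d = float(np.hypot(xy[0] - a[0], xy[1] - a[1]))
                if not np.isfinite(best) or d < best:
                    best = d
    return best


def thickness_profile(history, landmarks: list[Landmark],
                      anchor_tol: float | None = None) -> ThicknessSeries:
    """Distance from each landmark anchor to the recorded fronts, per step.

    Rays that miss the front at a step yield NaN (absent), never zero.
    Anchors must lie on the initial EDJ contour (within ``anchor_tol``,
    default one mesh spacing when the history carries its state).
    """
    edj = history.initial
    if anchor_tol is None:
        anchor_tol = (history.final_state.mesh.h
                      if history.final_state is not None else 0.02)
    boundary = edj.as_shapely()
    for lm in landmarks:
        if boundary.distance(shapely.Point(lm.anchor)) > anchor_tol:
            raise ValueError(
                f"landmark {lm.label!r} anchor {lm.anchor} is not on the EDJ "
                f"(tolerance {anchor_tol:.4g})"
            )
    rows = []
    for step_idx, contours in history.records:
        for i, lm in enumerate(landmarks):
            rows.append({
                "step": step_idx,
                "landmark": i,
                "label": lm.label,
                "thickness": _ray_thickness(lm.anchor, lm.direction, contours),
            })
    return ThicknessSeries(pd.DataFrame(rows))


def cusp_landmarks(edj: ContourPolyline, n_ridges: int,
                   center=None) -> list[Landmark]:
    """Radial ridge/valley landmarks for a cosine-lobe cusp section.

    Ridge rays at the lobe angles, valley rays halfway between, all anchored
    at the EDJ crossing of the radial direction and pointing outward.
    """
    c = np.asarray(center if center is not None
                   else edj.vertices.mean(axis=0))
    ring = edj.as_shapely()
    out = []
    for j in range(n_ridges):
        for label, angle in (
            ("ridge", 2 * np.pi * j / n_ridges),
            ("valley", (2 * j + 1) * np.pi / n_ridges),
        ):
            d = np.array([np.cos(angle), np.sin(angle)])
            ray = shapely.LineString([c, c + 2.0 * d])
            hit = ray.intersection(ring)
            if hit.is_empty:
                continue
            geoms = getattr(hit, "geoms", [hit])
            pts = [xy for g in geoms for xy in getattr(g, "coords", [])]
            far = max(pts, key=lambda p: np.hypot(p[0] - c[0], p[1] - c[1]))
            out.append(Landmark(label, (far[0], far[1]), (d[0], d[1])))
    return out


# ---------------------------------------------------------------------------
# Area / perimeter
# ---------------------------------------------------------------------------

def area_perimeter(front: ContourPolyline, edj: ContourPolyline
                   ) -> tuple[float, float]:
    """Enamel area (front minus EDJ polygon areas) and front perimeter."""
    if not (front.closed and edj.closed):
        raise ValueError("area_perimeter requires closed contours")
    fp = front.polygon()
    ep = edj.polygon()
    if not fp.buffer(1e-9).contains(ep):
        raise ValueError("EDJ is not contained in the front contour")
    return float(fp.area - ep.area), float(front.length())


# ---------------------------------------------------------------------------
# Box-counting dimension
# ---------------------------------------------------------------------------

@dataclass
class BoxCountResult:
    estimates: pd.DataFrame  # columns: origin, rotation_deg, D_B
    mean: float
    sd: float


def rasterize_contour(contours, size: int = 1024, pad: float = 0.05,
                      y_min: float | None = None) -> np.ndarray:
    """Rasterise contour(s) into a binary image of 1-pixel-wide outlines.

    ``y_min`` drops segments whose midpoint lies below that level — used to
    exclude the outer walls/base of closed vertical profiles so only the
    crown surface contributes to complexity measures.
    """
    if isinstance(contours, ContourPolyline):
        contours = [contours]
    if not contours:
        raise ValueError("no contours to rasterize")
    boxes = np.array([c.bbox() for c in contours])
    lo = boxes[:, :2].min(axis=0)
    hi = boxes[:, 2:].max(axis=0)
    span = float(max(hi - lo))
    if span <= 0:
        raise ValueError("degenerate contour extent")
    margin = pad * span
    scale = (size - 1) / (span + 2 * margin)
    img = np.zeros((size, size), dtype=bool)
    for c in contours:
        a, b = c.segments
        if y_min is not None:
            keep = 0.5 * (a[:, 1] + b[:, 1]) > y_min
            a, b = a[keep], b[keep]
        for p, q in zip(a, b):
            r0, c0 = (p[1] - lo[1] + margin) * scale, (p[0] - lo[0] + margin) * scale
            r1, c1 = (q[1] - lo[1] + margin) * scale, (q[0] - lo[0] + margin) * scale
            rr, cc = draw.line(int(round(r0)), int(round(c0)),
                               int(round(r1)), int(round(c1)))
            ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            img[rr[ok], cc[ok]] = True
    return img


def _count_boxes(img: np.ndarray, s: int, ox: int, oy: int) -> int:
    padded = np.pad(img, ((oy, s), (ox, s)))
    h = (padded.shape[0] // s) * s
    w = (padded.shape[1] // s) * s
    blocks = padded[:h, :w].reshape(h // s, s, w // s, s)
    return int(blocks.any(axis=(1, 3)).sum())


def box_counting_dimension(
    image: np.ndarray,
    grid_origins: int = 12,
    rotation_step: float = 36.0,
    min_box: int = 2,
    max_box: int | None = None,
) -> BoxCountResult:
    """Box-counting dimension of a binary contour raster.

    The contour (not the grid) is rotated through ``360/rotation_step``
    angles with nearest-neighbour resampling and re-binarisation; for each
    rotation, ``grid_origins`` deterministic grid offsets are tried.  Box
    sizes run in a geometric series (ratio 2) from ``min_box`` to a quarter
    of the image side, and each estimate is the negative slope of
    log N(s) vs log s.  Sizes so large that fewer than 8 boxes are occupied
    are saturated by the object's finite extent and are dropped from the
    regression (kept only if fewer than 4 sizes would remain).
    """
    image = np.asarray(image).astype(bool)
    if not image.any():
        raise ValueError("empty image")
    side = max(image.shape)
    if max_box is None:
        max_box = side // 4
    sizes = []
    s = min_box
    while s <= max_box:
        sizes.append(s)
        s *= 2
    if len(sizes) < 4:
        raise ValueError("image too small: fewer than 4 box sizes available")
    n_rot = int(round(360.0 / rotation_step))
    rows = []
    for k_rot in range(n_rot):
        angle = k_rot * rotation_step
        if angle == 0:
            rot = image
        else:
            # bilinear + re-threshold keeps 1-px outlines connected
            rot = ndimage.rotate(image.astype(float), angle,
                                 order=1, reshape=True) >= 0.5
        for k in range(grid_origins):
            logs, logn = [], []
            fallback = []
            for s in sizes:
                ox = ((k % 4) * s) // 4
                oy = ((k // 4) * s) // 3
                count = _count_boxes(rot, s, ox, oy)
                if count >= 8:
                    logs.append(np.log(s))
                    logn.append(np.log(count))
                elif count > 0:
                    fallback.append((np.log(s), np.log(count)))
            while len(logs) < 4 and fallback:
                ls_, ln_ = fallback.pop(0)
                logs.append(ls_)
                logn.append(ln_)
            slope = np.polyfit(logs, logn, 1)[0]
            rows.append({"origin": k, "rotation_deg": angle, "D_B": -slope})
    df = pd.DataFrame(rows)
    return BoxCountResult(df, float(df["D_B"].mean()), float(df["D_B"].std()))


# ---------------------------------------------------------------------------
# Slice stacking and surface distances
# ---------------------------------------------------------------------------

@dataclass
class SurfaceStack:
    """Ordered 2D slices at uniform z spacing with a triangulated side
    surface (vertex ring correspondence by arc length)."""

    slices: list
    z_spacing: float
    vertices: np.ndarray
    faces: np.ndarray

    @property
    def mesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)

    def lateral_area(self) -> float:
        return float(self.mesh.area)


def stack_slices(slices: list[ContourPolyline], z_spacing: float,
                 n_vertices: int | None = None) -> SurfaceStack:
    """Stack per-slice contours into a 3D side surface.

    Slices are resampled to a common vertex count; each ring is rolled so
    vertex 0 is the point nearest (in xy) to the previous ring's vertex 0,
    then consecutive rings are joined by triangle pairs.
    """
    if len(slices) < 2:
        raise ValueError("stacking requires at least 2 slices")
    closures = {c.closed for c in slices}
    if len(closures) != 1:
        raise ValueError("cannot stack a mix of open and closed slices")
    closed = slices[0].closed
    if n_vertices is None:
        n_vertices = max(len(c) for c in slices)
    rings = []
    for c in slices:
        r = resample_by_count(c.oriented_ccw() if closed else c, n_vertices)
        rings.append(r)
    if closed:
        aligned = [rings[0]]
        for r in rings[1:]:
            ref = aligned[-1].vertices[0]
            d = np.hypot(*(r.vertices - ref).T)
            roll = int(np.argmin(d))
            aligned.append(ContourPolyline(np.roll(r.vertices, -roll, axis=0),
                                           True, r.units))
        rings = aligned
    verts = np.concatenate([
        np.column_stack([r.vertices, np.full(n_vertices, i * z_spacing)])
        for i, r in enumerate(rings)
    ])
    faces = []
    m = n_vertices
    n_quads = m if closed else m - 1
    for i in range(len(rings) - 1):
        base = i * m
        for j in range(n_quads):
            a = base + j
            b = base + (j + 1) % m
            faces.append([a, b, b + m])
            faces.append([a, b + m, a + m])
    return SurfaceStack(rings, z_spacing, verts, np.asarray(faces))


@dataclass
class DistanceSummary:
    """One-sided and symmetric distance statistics between two surfaces."""

    mean_ab: float
    max_ab: float
    sd_ab: float
    mean_ba: float
    max_ba: float
    sd_ba: float

    @property
    def hausdorff(self) -> float:
        return max(self.max_ab, self.max_ba)

    @property
    def mean_symmetric(self) -> float:
        return 0.5 * (self.mean_ab + self.mean_ba)


def _sample_contour(c: ContourPolyline, n: int = 1024) -> np.ndarray:
    return resample_by_count(c, max(n, 2 * len(c))).vertices


def _contour_distances(a: ContourPolyline, b: ContourPolyline,
                       n: int = 1024) -> np.ndarray:
    pts = _sample_contour(a, n)
    return np.asarray(shapely.distance(shapely.points(pts), b.as_shapely()))


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray,
                             chunk: int = 256) -> np.ndarray:
    """Exact minimum distance from 3D points to a triangle soup.

    Barycentric-region clamping (the classic closest-point-on-triangle
    construction), vectorised over point chunks × all triangles.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk][:, None, :]  # (P,1,3)
        ap = p - a
        d1 = np.einsum("ij,pij->pi", ab, ap)
        d2 = np.einsum("ij,pij->pi", ac, ap)
        bp = p - b
        d3 = np.einsum("ij,pij->pi", ab, bp)
        d4 = np.einsum("ij,pij->pi", ac, bp)
        cp = p - c
        d5 = np.einsum("ij,pij->pi", ab, cp)
        d6 = np.einsum("ij,pij->pi", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = np.where(np.abs(va + vb + vc) < 1e-300, 1.0, va + vb + vc)
        v = vb / denom
        w = vc / denom
        closest = a + v[..., None] * ab + w[..., None] * ac
        # vertex regions
        m = (d1 <= 0) & (d2 <= 0)
        closest = np.where(m[..., None], a, closest)
        m = (d3 >= 0) & (d4 <= d3)
        closest = np.where(m[..., None], b, closest)
        m = (d6 >= 0) & (d5 <= d6)
        closest = np.where(m[..., None], c, closest)
        # edge regions
        t_ab = np.where(np.abs(d1 - d3) < 1e-300, 0.0, d1 / np.where(
            np.abs(d1 - d3) < 1e-300, 1.0, d1 - d3))
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        closest = np.where(m[..., None], a + np.clip(t_ab, 0, 1)[..., None] * ab,
                           closest)
        t_ac = np.where(np.abs(d2 - d6) < 1e-300, 0.0, d2 / np.where(
            np.abs(d2 - d6) < 1e-300, 1.0, d2 - d6))
        m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        closest = np.where(m[..., None], a + np.clip(t_ac, 0, 1)[..., None] * ac,
                           closest)
        denom_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(np.abs(denom_bc) < 1e-300, 0.0,
                        (d4 - d3) / np.where(np.abs(denom_bc) < 1e-300, 1.0,
                                             denom_bc))
        m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        closest = np.where(m[..., None],
                           b + np.clip(t_bc, 0, 1)[..., None] * (c - b), closest)
        out[s:s + chunk] = np.sqrt(
            np.min(np.einsum("pij,pij->pi", p - closest, p - closest), axis=1))
    return out


def _stack_distances(a: SurfaceStack, b: SurfaceStack) -> np.ndarray:
    tri_b = b.vertices[b.faces]
    pts = np.vstack([a.vertices, a.vertices[a.faces].mean(axis=1)])
    return _point_triangle_distance(pts, tri_b)


def surface_distance(a, b) -> DistanceSummary:
    """Dense point sampling of each surface measured against the other.

    Accepts two contours (2D, point-to-segment) or two stacks (3D,
    point-to-triangle).  ``hausdorff`` on the result is the symmetric
    Hausdorff estimate over the sample points.
    """
    if isinstance(a, ContourPolyline) and isinstance(b, ContourPolyline):
        d_ab = _contour_distances(a, b)
        d_ba = _contour_distances(b, a)
    elif isinstance(a, SurfaceStack) and isinstance(b, SurfaceStack):
        d_ab = _stack_distances(a, b)
        d_ba = _stack_distances(b, a)
    else:
        raise ValueError("surface_distance needs two contours or two stacks")
    if d_ab.size == 0 or d_ba.size == 0:
        raise ValueError("empty geometry")
    return DistanceSummary(
        float(d_ab.mean()), float(d_ab.max()), float(d_ab.std()),
        float(d_ba.mean()), float(d_ba.max()), float(d_ba.std()),
    )
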