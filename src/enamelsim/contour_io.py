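"""Contour input/output and level-set conversion.

EDJ traces arrive as plain-text two-column XY coordinate files (one vertex
per line; whitespace, comma or tab separated — digitisation exports vary).
This module reads and resamples them, scales them into the unit simulation
domain with a configurable border margin, converts them to signed-distance
level sets, and writes every artefact the pipeline produces: step images,
XY contours, Wavefront OBJ surfaces and JSON run manifests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from PIL import Image

from .domain import LevelSetField, TriMesh
from .geometry import ContourPolyline, signed_distance


@dataclass
class ConversionSpec:
    """How a contour is placed on the simulation domain.

    ``node_density`` is the number of mesh nodes along each axis; ``border``
    the proportional margin left around the scaled shape.  When
    ``registration_triangles`` is set, two small static solid triangles are
    placed in diagonally opposite corners (legs ``triangle_size`` of the
    domain side, default ``border/2``); they act as no-flux obstacles,
    are excluded from growth and from every measurement, and mark the frame
    used to keep differently sized slices of one stack at a common scale.
    ``bbox`` optionally overrides the contour's own bounding box with a
    shared one (used by stacked runs).
    """

    node_density: int = 129
    border: float = 0.32
    registration_triangles: bool = False
    triangle_size: float | None = None
    bbox: tuple | None = None

    def __post_init__(self) -> None:
        if not 0 < self.border < 1:
            raise ValueError("border must be in (0, 1)")
        if self.node_density < 16:
            raise ValueError("node_density must be at least 16")
        if self.triangle_size is not None and self.triangle_size <= 0:
            raise ValueError("triangle_size must be positive")


def read_xy_contour(path, closed: bool | None = None) -> ContourPolyline:
    """Read a two-column XY contour file.

    Closure is taken from the ``closed`` flag when given, otherwise inferred
    from the first and last vertices coinciding.  Blank lines and ``#``
    comments are skipped; anything else must be two numeric tokens.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            tokens = text.replace(",", " ").split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two columns, got {text!r}"
                )
            try:
                rows.append((float(tokens[0]), float(tokens[1])))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric token in {text!r}"
                ) from exc
    if len(rows) < 3:
        raise ValueError(f"{path}: fewer than 3 parsable vertices")
    v = np.asarray(rows)
    if closed is None:
        closed = bool(np.allclose(v[0], v[-1]))
    return ContourPolyline(v, closed=closed, units="pixel")


def write_xy_contour(contour: ContourPolyline, path) -> None:
    np.savetxt(path, contour.vertices, fmt="%.8f")


def resample_contour(contour: ContourPolyline, interval: float) -> ContourPolyline:
    """Resample to equally spaced vertices along the polygonal arc length.

    Closed contours get ``round(L/interval)`` vertices spaced exactly
    ``L/n``; open contours keep both endpoints and use the nearest vertex
    count to the requested spacing.
    """
    total = contour.length()
    if total <= 0:
        raise ValueError("cannot resample a degenerate (zero-length) contour")
    if not 0 < interval < total / 3:
        raise ValueError("interval must be positive and < total length / 3")
    v = contour.vertices
    pts = np.vstack([v, v[:1]]) if contour.closed else v
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if contour.closed:
        n_out = max(3, int(round(total / interval)))
        targets = np.arange(n_out) * total / n_out
    else:
        n_out = max(2, int(round(total / interval)) + 1)
        targets = np.linspace(0.0, total, n_out)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return ContourPolyline(np.column_stack([x, y]), contour.closed, contour.units)


def resample_by_count(contour: ContourPolyline, n_out: int) -> ContourPolyline:
    """Resample to exactly ``n_out`` equally spaced vertices."""
    total = contour.length()
    if total <= 0:
        raise ValueError("cannot resample a degenerate contour")
    v = contour.vertices
    pts = np.vstack([v, v[:1]]) if contour.closed else v
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if contour.closed:
        targets = np.arange(n_out) * total / n_out
    else:
        targets = np.linspace(0.0, total, n_out)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return ContourPolyline(np.column_stack([x, y]), contour.closed, contour.units)


def scale_to_domain(contour: ContourPolyline, spec: ConversionSpec) -> ContourPolyline:
    """Translate/scale so the (possibly shared) bbox fills the domain minus
    the border margins.  Open profiles keep their base on the lower margin
    line y = border."""
    x0, y0, x1, y1 = spec.bbox if spec.bbox is not None else contour.bbox()
    span = max(x1 - x0, y1 - y0)
    if span <= 0:
        raise ValueError("degenerate contour bounding box")
    scale = (1.0 - 2 * spec.border) / span
    if contour.closed:
        cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
        offset = np.array([0.5 - scale * cx, 0.5 - scale * cy])
    else:
        cx = 0.5 * (x0 + x1)
        offset = np.array([0.5 - scale * cx, spec.border - scale * y0])
    out = contour.transformed(scale, offset)
    lo_x, lo_y, hi_x, hi_y = out.bbox()
    if min(lo_x, lo_y) < -1e-9 or max(hi_x, hi_y) > 1 + 1e-9:
        raise ValueError("contour exceeds the unit domain after scaling; "
                         "check border and shared bbox")
    return out


def _close_along_base(contour: ContourPolyline) -> ContourPolyline:
    """Close an open vertical profile by joining its endpoints along the
    base line (the straight closing edge of the polygon)."""
    return ContourPolyline(contour.vertices.copy(), closed=True,
                           units=contour.units)


def registration_triangle_contours(spec: ConversionSpec) -> list[np.ndarray]:
    t = spec.triangle_size if spec.triangle_size is not None else spec.border / 2
    m = 0.02
    bl = np.array([[m, m], [m + t, m], [m, m + t]])
    tr = np.array([[1 - m, 1 - m], [1 - m - t, 1 - m], [1 - m, 1 - m - t]])
    return [bl, tr]


def contour_to_levelset(
    contour: ContourPolyline, spec: ConversionSpec, mesh: TriMesh
) -> LevelSetField:
    """Scale a contour into the domain and sample its signed distance.

    φ is the exact signed distance to the scaled contour at every node,
    negative inside the solid (dentine) region.  Open profiles are closed
    along the domain base line first.  Registration triangles, if requested,
    become static obstacle nodes.
    """
    if not contour.as_shapely().is_simple:
        raise ValueError("contour must be simple (non-self-intersecting)")
    scaled = scale_to_domain(contour, spec)
    if not scaled.closed:
        scaled = _close_along_base(scaled)
    scaled = scaled.oriented_ccw()
    phi = signed_distance(scaled, mesh.nodes)
    ls = LevelSetField(mesh, phi)
    if spec.registration_triangles:
        for tri in registration_triangle_contours(spec):
            poly = shapely.Polygon(tri)
            inside = shapely.contains_xy(poly, mesh.nodes[:, 0], mesh.nodes[:, 1])
            ls.obstacle_mask |= inside
            ls.obstacle_contours.append(ContourPolyline(tri, closed=True))
    return ls


def add_obstacle_rectangles(ls: LevelSetField, rects) -> None:
    """Mark axis-aligned rectangles (x0, y0, x1, y1) as static obstacles."""
    x, y = ls.mesh.nodes.T
    for x0, y0, x1, y1 in rects:
        inside = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        ls.obstacle_mask |= inside
        ls.obstacle_contours.append(ContourPolyline(
            np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]), closed=True))


def write_step_image(state, path, scale: int = 4,
                     show_nutrient: bool = True) -> None:
    """Render the current state to a lossless PNG.

    Solid matrix is grey, obstacles dark grey, and (optionally) the nutrient
    concentration shades the exterior in blue.  The domain's y-up convention
    is flipped to the image's row-down convention here, and nowhere else.
    Output is deterministic for a fixed state and canvas size.
    """
    ls = state.ls if hasattr(state, "ls") else state
    n = ls.mesh.node_density
    rgb = np.full((n, n, 3), 255, dtype=np.uint8)
    if show_nutrient and hasattr(state, "nutrients"):
        u = state.nutrients.u.reshape(n, n)
        umax = float(u.max())
        if umax > 0:
            shade = (u / umax * 80).astype(np.uint8)
            rgb[..., 0] -= shade
            rgb[..., 1] -= shade // 2
    solid = (ls.phi < 0).reshape(n, n)
    rgb[solid] = (130, 130, 130)
    obst = ls.obstacle_mask.reshape(n, n)
    rgb[obst] = (60, 60, 60)
    # interface: exterior pixels adjacent to solid drawn black
    from .nutrients import front_nodes

    rgb[front_nodes(ls).reshape(n, n)] = (0, 0, 0)
    rgb = rgb[::-1]  # y-up -> row-down
    img = Image.fromarray(rgb, "RGB")
    if scale > 1:
        img = img.resize((n * scale, n * scale), Image.NEAREST)
    img.save(path, format="PNG")


def write_surface_obj(stack, path) -> None:
    """Write a stacked surface as Wavefront OBJ (v/f records, 1-based)."""
    if len(stack.slices) < 2:
        raise ValueError("a surface needs at least 2 slices")
    with open(path, "w") as fh:
        for v in stack.vertices:
            fh.write(f"v {v[0]:.8f} {v[1]:.8f} {v[2]:.8f}\n")
        for f in stack.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_obj_vertices(path) -> np.ndarray:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("v "):
                out.append([float(t) for t in line.split()[1:4]])
    return np.asarray(out)


def write_manifest(config: dict, path) -> None:
    """JSON run manifest: the full configuration needed to reproduce a run."""
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
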