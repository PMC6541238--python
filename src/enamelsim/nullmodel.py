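"""Geometric extrapolation — the uniform-thickness null model.

The null hypothesis for enamel distribution is that the outer enamel surface
is simply the EDJ offset outward by a constant thickness: the outer boundary
of the morphological dilation of the dentine region by a disk.  The primary
implementation offsets the signed-distance field (mesh-consistent with the
simulator and resolution-independent in the limit); a raster grey-morphology
path built on the Euclidean distance transform exists for cross-validation.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .domain import LevelSetField, extract_interface
from .geometry import ContourPolyline, signed_distance


def _grid_for(contour: ContourPolyline, radius: float, resolution: int):
    x0, y0, x1, y1 = contour.bbox()
    pad = 1.2 * radius + 0.02 * max(x1 - x0, y1 - y0)
    lo = np.array([x0, y0]) - pad
    hi = np.array([x1, y1]) + pad
    span = float(max(hi - lo))
    step = span / (resolution - 1)
    nx = int(np.ceil((hi[0] - lo[0]) / step)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / step)) + 1
    xs = lo[0] + np.arange(nx) * step
    ys = lo[1] + np.arange(ny) * step
    return xs, ys, step


def geometric_extrapolation(
    edj: ContourPolyline,
    radius: float,
    resolution: int = 512,
    bounds: tuple | None = None,
) -> ContourPolyline:
    """Offset a closed EDJ contour outward by a fixed disk radius.

    Returns the outer boundary of the dilated solid (the level-``radius``
    isocontour of the signed distance field), in the contour's own units.
    Narrow concave notches with mouths below ``2·radius`` close up — the
    fissure-filling behaviour that distinguishes the null model from
    diffusion-limited growth.  ``bounds = (x0, y0, x1, y1)`` optionally
    enforces that the result stays inside a domain.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not edj.as_shapely().is_simple:
        raise ValueError("EDJ contour must be simple")
    closed_edj = edj if edj.closed else ContourPolyline(
        edj.vertices.copy(), closed=True, units=edj.units)
    xs, ys, step = _grid_for(closed_edj, radius, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    phi = signed_distance(closed_edj, pts).reshape(gy.shape)
    contours = measure.find_contours(phi, radius)
    if not contours:
        raise ValueError("no offset contour found (radius too large?)")
    best = max(contours, key=len)
    xy = np.column_stack([xs[0] + best[:, 1] * step, ys[0] + best[:, 0] * step])
    out = ContourPolyline(xy, closed=bool(np.allclose(best[0], best[-1])),
                          units=edj.units)
    if bounds is not None:
        bx0, by0, bx1, by1 = bounds
        lx0, ly0, lx1, ly1 = out.bbox()
        if lx0 < bx0 or ly0 < by0 or lx1 > bx1 or ly1 > by1:
            raise ValueError("dilated contour exits the allowed domain")
    return out


def geometric_extrapolation_raster(
    edj: ContourPolyline, radius: float, resolution: int = 1024
) -> ContourPolyline:
    """Raster cross-validation path: binary dilation via the Euclidean
    distance transform of the rasterised solid, thresholded at ``radius``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    closed_edj = edj if edj.closed else ContourPolyline(
        edj.vertices.copy(), closed=True, units=edj.units)
    xs, ys, step = _grid_for(closed_edj, radius, resolution)
    gx, gy = np.meshgrid(xs, ys)
    import shapely

    inside = shapely.contains_xy(closed_edj.polygon(), gx.ravel(), gy.ravel())
    mask = inside.reshape(gy.shape)
    # EDT measures to the nearest solid pixel centre; the true boundary lies
    # about half a pixel further out
    dist = (ndimage.distance_transform_edt(~mask) - 0.5) * step
    contours = measure.find_contours(dist, radius)
    if not contours:
        raise ValueError("no offset contour found")
    best = max(contours, key=len)
    xy = np.column_stack([xs[0] + best[:, 1] * step, ys[0] + best[:, 0] * step])
    return ContourPolyline(xy, closed=True, units=edj.units)


def offset_front(ls: LevelSetField, radius: float) -> list[ContourPolyline]:
    """Offset fronts of an existing simulation level set, for side-by-side
    comparison with simulated fronts on the same mesh."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return extract_interface(ls, level=radius)
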