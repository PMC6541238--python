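"""Simulation domain: structured triangular mesh and level-set operations.

The unit square is triangulated by a regular grid of right isosceles
triangles (``node_density`` nodes per axis, every quad split along the same
diagonal so interior nodes have six neighbours).  The growing solid —
dentine plus deposited enamel matrix — is represented implicitly by a
signed-distance level-set field φ on the nodes, φ < 0 inside the solid.

Static obstacles (corner registration triangles, lateral braces) are kept in
a separate per-node boolean mask rather than folded into φ: they block
diffusion and growth but are never part of the advected interface, which
keeps interface extraction and all measurements free of obstacle artefacts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import shapely
from skimage import measure

from .geometry import ContourPolyline


@dataclass
class TriMesh:
    """Regular triangulation of the unit square.

    ``node_density`` nodes along each axis; node ``(i, j)`` (row ``i`` = y,
    column ``j`` = x) has flat index ``i * n + j`` and coordinates
    ``(j*h, i*h)`` with ``h = 1/(n-1)``.
    """

    node_density: int
    nodes: np.ndarray
    triangles: np.ndarray
    h: float
    stiffness: sp.csr_matrix
    lumped_mass: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def boundary_nodes(self, side: str) -> np.ndarray:
        n = self.node_density
        idx = np.arange(n)
        return {
            "left": idx * n,
            "right": idx * n + (n - 1),
            "bottom": idx,
            "top": (n - 1) * n + idx,
        }[side]


def build_mesh(node_density: int) -> TriMesh:
    """Structured triangulation with P1 stiffness and lumped mass matrices."""
    if node_density < 16:
        raise ValueError("node_density must be at least 16")
    n = node_density
    h = 1.0 / (n - 1)
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    nodes = np.column_stack([jj.ravel() * h, ii.ravel() * h])

    i, j = np.meshgrid(np.arange(n - 1), np.arange(n - 1), indexing="ij")
    v00 = (i * n + j).ravel()
    v01 = v00 + 1
    v10 = v00 + n
    v11 = v10 + 1
    # split every quad along the v00–v11 diagonal, both triangles CCW
    tris = np.concatenate([
        np.column_stack([v00, v01, v11]),
        np.column_stack([v00, v11, v10]),
    ])

    p = nodes[tris]  # (M, 3, 2)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    area = 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    # gradients of the barycentric basis functions
    g = np.empty_like(p)
    g[:, 0] = np.column_stack([p[:, 1, 1] - p[:, 2, 1], p[:, 2, 0] - p[:, 1, 0]])
    g[:, 1] = np.column_stack([p[:, 2, 1] - p[:, 0, 1], p[:, 0, 0] - p[:, 2, 0]])
    g[:, 2] = np.column_stack([p[:, 0, 1] - p[:, 1, 1], p[:, 1, 0] - p[:, 0, 0]])
    g /= (2 * area)[:, None, None]
    k_local = np.einsum("mid,mjd->mij", g, g) * area[:, None, None]

    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    stiffness = sp.coo_matrix(
        (k_local.ravel(), (rows, cols)), shape=(n * n, n * n)
    ).tocsr()

    lumped = np.zeros(n * n)
    np.add.at(lumped, tris.ravel(), np.repeat(area / 3.0, 3))

    return TriMesh(n, nodes, tris, h, stiffness, lumped)


@dataclass
class LevelSetField:
    """Signed-distance field of the growing solid plus static obstacles."""

    mesh: TriMesh
    phi: np.ndarray
    obstacle_mask: np.ndarray = None
    obstacle_contours: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.obstacle_mask is None:
            self.obstacle_mask = np.zeros(self.mesh.n_nodes, dtype=bool)

    def grid(self) -> np.ndarray:
        n = self.mesh.node_density
        return self.phi.reshape(n, n)

    @property
    def solid_mask(self) -> np.ndarray:
        """Nodes inside dentine/matrix or an obstacle."""
        return (self.phi < 0) | self.obstacle_mask

    @property
    def active_mask(self) -> np.ndarray:
        """Exterior nodes where nutrients live."""
        return (self.phi >= 0) & ~self.obstacle_mask

    def copy(self) -> "LevelSetField":
        return LevelSetField(self.mesh, self.phi.copy(), self.obstacle_mask.copy(),
                             list(self.obstacle_contours))


def extract_interface(ls: LevelSetField, level: float = 0.0) -> list[ContourPolyline]:
    """Isocontours of φ as polylines (marching on the node grid).

    Returns domain-unit polylines; a single-signed field yields an empty
    list.  Obstacles are not part of φ, so no obstacle contour can appear.
    """
    n = ls.mesh.node_density
    h = ls.mesh.h
    out: list[ContourPolyline] = []
    for rc in measure.find_contours(ls.grid(), level):
        closed = bool(np.allclose(rc[0], rc[-1]))
        xy = np.column_stack([rc[:, 1] * h, rc[:, 0] * h])
        try:
            out.append(ContourPolyline(xy, closed=closed))
        except ValueError:
            continue  # degenerate speck below vertex minimum
    return out


def reinitialize(ls: LevelSetField) -> LevelSetField:
    """Restore the signed-distance property of φ.

    Geometric reinitialisation: the zero isocontour is extracted by linear
    interpolation, resampled densely (spacing h/8), and the distance to the
    sample points is recomputed at every node via a KD-tree, keeping each
    node's current sign.  The distance error is at most h/16, so the zero
    contour moves by far less than h/2.
    """
    from scipy.spatial import cKDTree

    phi = ls.phi
    if not (np.any(phi < 0) and np.any(phi > 0)):
        raise ValueError("cannot reinitialize a single-sign level-set field")
    contours = extract_interface(ls)
    if not contours:
        raise ValueError("no interface found during reinitialization")
    h = ls.mesh.h
    pts = []
    for c in contours:
        n_dense = max(len(c), int(np.ceil(c.length() / (h / 8))))
        pts.append(_densify(c, n_dense))
    d, _ = cKDTree(np.concatenate(pts)).query(ls.mesh.nodes)
    phi_new = np.where(phi < 0, -d, d)
    return LevelSetField(ls.mesh, phi_new, ls.obstacle_mask.copy(),
                         list(ls.obstacle_contours))


def _densify(c: ContourPolyline, n_out: int) -> np.ndarray:
    """Equally spaced points along a polyline (arc-length interpolation)."""
    v = c.vertices
    pts = np.vstack([v, v[:1]]) if c.closed else v
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return v
    t = (np.arange(n_out) * s[-1] / n_out if c.closed
         else np.linspace(0.0, s[-1], n_out))
    return np.column_stack([np.interp(t, s, pts[:, 0]),
                            np.interp(t, s, pts[:, 1])])


def smooth_front_values(coords: np.ndarray, values: np.ndarray,
                        weights: np.ndarray, radius: float,
                        passes: int = 2) -> np.ndarray:
    """Weighted moving average of per-node values over nearby front nodes.

    The staircase discretisation of the interface makes nodal flux and
    curvature noisy at grid scale; without a short tangential smoothing that
    noise is amplified by the diffusion-limited instability into pure grid
    artefacts.  The smoothing radius is a few node spacings — below any
    feature the mesh can resolve.
    """
    from scipy.spatial import cKDTree

    neighbors = cKDTree(coords).query_ball_point(coords, radius)
    out = np.asarray(values, dtype=float).copy()
    weights = np.asarray(weights, dtype=float)
    for _ in range(passes):
        new = np.empty_like(out)
        for i, nb in enumerate(neighbors):
            w = weights[nb]
            new[i] = np.dot(out[nb], w) / w.sum()
        out = new
    return out


def curvature(ls: LevelSetField, return_mask: bool = False):
    """Mean curvature κ = div(∇φ/|∇φ|) per node.

    κ > 0 where the solid bulges into the exterior (convex ridge), κ < 0 in
    concavities.  Nodes with vanishing gradient get κ = 0 (flagged in the
    optional mask); values are clamped to the grid-resolvable bound 1/h.
    """
    h = ls.mesh.h
    g = ls.grid()
    gy, gx = np.gradient(g, h)
    gyy, gyx = np.gradient(gy, h)
    gxy, gxx = np.gradient(gx, h)
    norm2 = gx * gx + gy * gy
    degenerate = norm2 < 1e-12
    denom = np.where(degenerate, 1.0, norm2 ** 1.5)
    kappa = (gxx * gy * gy - (gxy + gyx) * gx * gy + gyy * gx * gx) / denom
    kappa[degenerate] = 0.0
    kappa = np.clip(kappa, -1.0 / h, 1.0 / h).ravel()
    if return_mask:
        return kappa, degenerate.ravel()
    return kappa


def _one_sided_diffs(g: np.ndarray, h: float, axis: int):
    """Backward/forward differences with edge replication."""
    dm = np.empty_like(g)
    dp = np.empty_like(g)
    sl = [slice(None)] * g.ndim

    def ax(s):
        out = list(sl)
        out[axis] = s
        return tuple(out)

    diff = np.diff(g, axis=axis) / h
    dm[ax(slice(1, None))] = diff
    dm[ax(slice(0, 1))] = diff[ax(slice(0, 1))]
    dp[ax(slice(None, -1))] = diff
    dp[ax(slice(-1, None))] = diff[ax(slice(-1, None))]
    return dm, dp


def advect(ls: LevelSetField, vn: np.ndarray, dt: float,
           cfl: float = 0.5) -> LevelSetField:
    """One step of φ_t + Vn·|∇φ| = 0 with Godunov upwinding.

    Substeps internally to keep ``max|Vn|·dt_sub ≤ cfl·h``.  Obstacle nodes
    are never modified.
    """
    vn = np.asarray(vn, dtype=float)
    if np.any(~np.isfinite(vn)):
        raise ValueError("NaN/Inf in normal velocity")
    h = ls.mesh.h
    n = ls.mesh.node_density
    vmax = float(np.max(np.abs(vn))) if vn.size else 0.0
    nsub = max(1, int(np.ceil(vmax * dt / (cfl * h)))) if vmax > 0 else 1
    dts = dt / nsub

    phi = ls.phi.copy()
    vg = vn.reshape(n, n)
    pos = vg > 0
    neg = vg < 0
    obstacle = ls.obstacle_mask
    phi_obs = ls.phi[obstacle]
    for _ in range(nsub):
        g = phi.reshape(n, n)
        dmx, dpx = _one_sided_diffs(g, h, axis=1)
        dmy, dpy = _one_sided_diffs(g, h, axis=0)
        grad_pos = np.sqrt(
            np.maximum(dmx, 0) ** 2 + np.minimum(dpx, 0) ** 2
            + np.maximum(dmy, 0) ** 2 + np.minimum(dpy, 0) ** 2
        )
        grad_neg = np.sqrt(
            np.minimum(dmx, 0) ** 2 + np.maximum(dpx, 0) ** 2
            + np.minimum(dmy, 0) ** 2 + np.maximum(dpy, 0) ** 2
        )
        upd = np.zeros_like(g)
        upd[pos] = vg[pos] * grad_pos[pos]
        upd[neg] = vg[neg] * grad_neg[neg]
        phi = (g - dts * upd).ravel()
        phi[obstacle] = phi_obs
    return LevelSetField(ls.mesh, phi, ls.obstacle_mask.copy(),
                         list(ls.obstacle_contours))


def solid_area(ls: LevelSetField) -> float:
    """Area of the growing solid, by polygon quadrature of the interface.

    Handles nested contours (holes created when fronts merge) by even-odd
    containment depth.  Obstacles are excluded by construction.
    """
    contours = [c for c in extract_interface(ls) if c.closed]
    if not contours:
        return 0.0
    polys = [c.polygon() for c in contours]
    total = 0.0
    for i, c in enumerate(contours):
        depth = sum(
            1 for j, p in enumerate(polys)
            if j != i and p.contains(shapely.Point(c.vertices[0]))
        )
        total += abs(c.signed_area()) * (1 if depth % 2 == 0 else -1)
    return total
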