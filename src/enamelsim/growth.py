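"""The moving-boundary engine.

Matrix deposition is a one-phase Stefan problem: the ameloblast front (the
zero level set of φ) advances at a normal speed set by the diffusive nutrient
flux into it,

    Vn = (D/λ) ∂u/∂n |_exterior ,

where λ is the nutrient mass required per unit area of deposited matrix.
Each step couples one implicit diffusion solve, velocity evaluation on the
interface, band extension, upwind level-set advection and periodic
reinitialisation.  Deposition is irreversible by default (Vn clamped ≥ 0),
so the solid region grows monotonically.

Two velocity extractions are available.  ``"reaction"`` (default) reads the
discrete Stefan flux absorbed at each interface-adjacent Dirichlet node off
the residual of the diffusion solve and divides by λ and the interface length
attributed to the node — this makes the nutrient bookkeeping close against
λ × deposited area by construction.  ``"gradient"`` evaluates (D/λ)·∂u/∂n by
one-sided differences on the exterior side.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .contour_io import ConversionSpec, contour_to_levelset, add_obstacle_rectangles
from .domain import (LevelSetField, advect, build_mesh, extract_interface,
                     reinitialize, smooth_front_values, solid_area)
from .geometry import ContourPolyline
from .nutrients import (BoundarySpec, NutrientField, diffusion_step,
                        front_nodes, initialize_nutrients)

log = logging.getLogger(__name__)


@dataclass
class GrowthParams:
    """Dimensionless model parameters.

    All values are dimensionless; only their ratios matter.  ``D`` is the
    nutrient diffusion rate, ``lam`` (λ) the nutrient mass consumed per unit
    area of matrix, ``sigma`` the interfacial tension of the ameloblast
    layer, ``f`` the uniform background nutrient production on the exterior,
    ``u_init`` the initial exterior concentration, and ``dt`` the fixed time
    step.  ``record_every`` sets the spacing of recorded virtual incremental
    lines.  ``vmax`` is the intrinsic maximum secretion speed of the
    ameloblast layer: nutrient-limited speeds are capped there, so excess
    nutrient availability produces uniform front advance instead of a
    runaway.  The engine itself contains no randomness; ``seed`` exists
    only to propagate into synthetic-shape noise.
    """

    D: float = 0.05
    lam: float = 25.0
    sigma: float = 0.15
    f: float = 30.0
    u_init: float = 2.0
    dt: float = 0.001
    n_iter: int = 400
    record_every: int = 4
    clamp_nonnegative: bool = True
    seed: int = 0
    u_ref: float = 0.0
    tension_mode: str = "boundary"      # "boundary" (Gibbs-Thomson) or "velocity"
    velocity_source: str = "reaction"   # "reaction" or "gradient"
    quasi_static: bool = False
    reinit_every: int = 5
    band_width: float = 5.0
    vmax: float = 0.4

    def __post_init__(self) -> None:
        if self.D <= 0 or self.lam <= 0:
            raise ValueError("D and lam must be positive")
        if min(self.sigma, self.f, self.u_init) < 0:
            raise ValueError("sigma, f and u_init must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tension_mode not in ("boundary", "velocity"):
            raise ValueError("tension_mode must be 'boundary' or 'velocity'")
        if self.velocity_source not in ("reaction", "gradient"):
            raise ValueError("velocity_source must be 'reaction' or 'gradient'")
        if self.vmax <= 0:
            raise ValueError("vmax must be positive")


@dataclass
class SimulationState:
    """The coupled (φ, u) pair plus bookkeeping."""

    mesh: object
    ls: LevelSetField
    nutrients: NutrientField
    bc: BoundarySpec
    step: int = 0
    accounting: dict = field(default_factory=dict)


@dataclass
class FrontHistory:
    """Recorded interface positions — the virtual incremental lines."""

    initial: ContourPolyline
    records: list = field(default_factory=list)  # (step, [ContourPolyline])
    record_every: int = 4
    final_state: SimulationState | None = None
    accounting: dict = field(default_factory=dict)
    stop_reason: str = ""

    @property
    def steps(self) -> list[int]:
        return [s for s, _ in self.records]

    def fronts_at(self, step: int) -> list[ContourPolyline]:
        for s, contours in self.records:
            if s == step:
                return contours
        raise KeyError(f"no record at step {step}")

    @property
    def final_fronts(self) -> list[ContourPolyline]:
        return self.records[-1][1]


def _extend_to_band(mesh, ls: LevelSetField, idx: np.ndarray,
                    values: np.ndarray, band_width: float) -> np.ndarray:
    """Constant-along-normal extension: copy each band node's value from the
    nearest velocity-carrying interface node."""
    out = np.zeros(mesh.n_nodes)
    if idx.size == 0:
        return out
    band = np.abs(ls.phi) <= band_width * mesh.h
    band &= ~ls.obstacle_mask
    if not band.any():
        return out
    tree = cKDTree(mesh.nodes[idx])
    _, nearest = tree.query(mesh.nodes[band])
    out[band] = values[nearest]
    return out


def _flux_density(ls: LevelSetField, idx: np.ndarray, flux: np.ndarray,
                  radius_h: float = 1.5) -> np.ndarray:
    """Flux per unit interface length at each front node.

    Kernel ratio estimate: total absorbed flux of front nodes within a few
    node spacings, divided by the interface length within the same
    neighbourhood.  Smooth by construction and asymptotically conserves the
    total flux, unlike a per-node Voronoi partition of the staircase front.
    """
    h = ls.mesh.h
    contours = extract_interface(ls)
    if not contours or idx.size == 0:
        return np.zeros(idx.size)
    mids, seg_len = [], []
    for c in contours:
        a, b = c.segments
        mids.append(0.5 * (a + b))
        seg_len.append(np.hypot(*(b - a).T))
    mids = np.concatenate(mids)
    seg_len = np.concatenate(seg_len)
    coords = ls.mesh.nodes[idx]
    # Voronoi partition of the interface length over front nodes (total
    # length conserved exactly), then a ratio-of-sums kernel over the same
    # node set, so the varying node density of the staircase front cancels.
    _, owner = cKDTree(coords).query(mids)
    assigned = np.zeros(idx.size)
    np.add.at(assigned, owner, seg_len)
    r = radius_h * h
    flux_near = np.zeros(idx.size)
    len_near = np.zeros(idx.size)
    for i, nb in enumerate(cKDTree(coords).query_ball_point(coords, r)):
        flux_near[i] = flux[nb].sum()
        len_near[i] = assigned[nb].sum()
    len_near = np.maximum(len_near, 0.5 * h)
    return flux_near / len_near


def interface_velocity(nf: NutrientField, ls: LevelSetField,
                       params: GrowthParams, diag=None) -> np.ndarray:
    """Normal front speed per node, extended to the advection band.

    With ``velocity_source == "reaction"`` the per-node absorbed flux from
    the diffusion diagnostics is used (requires ``diag``); otherwise the
    one-sided exterior gradient of u.  ``tension_mode == "velocity"``
    subtracts σκ from the speed instead of modifying the interface value.
    """
    mesh = ls.mesh
    front = front_nodes(ls)
    idx = np.flatnonzero(front)
    if idx.size == 0:
        return np.zeros(mesh.n_nodes)

    if params.velocity_source == "reaction" and diag is not None:
        # diag.front_idx matches `idx`: both derive from the same φ
        q = _flux_density(ls, diag.front_idx, diag.front_flux) / params.dt
        vn_front_all = q / params.lam
        lookup = dict(zip(diag.front_idx.tolist(), vn_front_all.tolist()))
        vn_front = np.array([lookup.get(i, 0.0) for i in idx])
    else:
        vn_front = _gradient_velocity(nf, ls, params, idx)
        vn_front = smooth_front_values(mesh.nodes[idx], vn_front,
                                       np.ones(idx.size), radius=2.5 * mesh.h)

    if params.tension_mode == "velocity" and params.sigma > 0:
        from .domain import curvature

        kappa = curvature(ls)
        vn_front = vn_front - params.sigma * kappa[idx]
    if params.clamp_nonnegative:
        np.maximum(vn_front, 0.0, out=vn_front)
    # Ameloblasts have a finite intrinsic secretion rate: with excess
    # nutrients the front advances at this cap, uniformly, rather than at an
    # unbounded Stefan speed — production beyond the cap "overcomes" the
    # diffusion-limited patterning.
    np.minimum(vn_front, params.vmax, out=vn_front)
    return _extend_to_band(mesh, ls, idx, vn_front, params.band_width)


def _gradient_velocity(nf: NutrientField, ls: LevelSetField,
                       params: GrowthParams, idx: np.ndarray) -> np.ndarray:
    n = ls.mesh.node_density
    h = ls.mesh.h
    ug = nf.u.reshape(n, n)
    act = ls.active_mask.reshape(n, n)

    def one_sided(axis):
        fwd_ok = np.zeros_like(act)
        bwd_ok = np.zeros_like(act)
        sl_f = [slice(None)] * 2
        sl_b = [slice(None)] * 2
        sl_f[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        fwd_ok[tuple(sl_f)] = act[tuple(sl_b)]
        bwd_ok[tuple(sl_b)] = act[tuple(sl_f)]
        u_f = np.roll(ug, -1, axis=axis)
        u_b = np.roll(ug, 1, axis=axis)
        both = fwd_ok & bwd_ok
        grad = np.zeros_like(ug)
        grad[both] = (u_f[both] - u_b[both]) / (2 * h)
        only_f = fwd_ok & ~bwd_ok
        grad[only_f] = (u_f[only_f] - ug[only_f]) / h
        only_b = bwd_ok & ~fwd_ok
        grad[only_b] = (ug[only_b] - u_b[only_b]) / h
        return grad

    gux = one_sided(1).ravel()
    guy = one_sided(0).ravel()
    pg = ls.grid()
    py, px = np.gradient(pg, h)
    norm = np.hypot(px, py)
    norm[norm < 1e-12] = 1.0
    nx = (px / norm).ravel()
    ny = (py / norm).ravel()
    return (params.D / params.lam) * (gux[idx] * nx[idx] + guy[idx] * ny[idx])


def step(state: SimulationState, params: GrowthParams) -> SimulationState:
    """One growth cycle: diffuse → velocity → advect → account → reinit."""
    nf2, diag = diffusion_step(state.nutrients, state.ls, params, state.bc)
    vn = interface_velocity(nf2, state.ls, params, diag)
    ls2 = advect(state.ls, vn, params.dt)

    mesh = state.mesh
    newly_solid = (ls2.phi < 0) & (state.ls.phi >= 0) & ~state.ls.obstacle_mask
    swallowed = float(np.sum(mesh.lumped_mass[newly_solid] * nf2.u[newly_solid]))
    nf2.u[newly_solid] = 0.0

    acc = state.accounting
    if not params.quasi_static:
        acc["produced"] = acc.get("produced", 0.0) + diag.produced
        acc["absorbed"] = acc.get("absorbed", 0.0) + diag.absorbed_total
        acc["swallowed"] = acc.get("swallowed", 0.0) + swallowed

    state.ls = ls2
    state.nutrients = nf2
    state.step += 1
    if params.reinit_every and state.step % params.reinit_every == 0:
        state.ls = reinitialize(state.ls)
    return state


def _touches_boundary(ls: LevelSetField, skip_bottom: bool) -> bool:
    n = ls.mesh.node_density
    sg = (ls.phi < 0).reshape(n, n)
    if sg[:, 0].any() or sg[:, -1].any() or sg[-1, :].any():
        return True
    return (not skip_bottom) and bool(sg[0, :].any())


def _probe_thickness(ls: LevelSetField, initial: ContourPolyline,
                     probe) -> float:
    import shapely

    anchor, direction, _target = probe
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    ray = shapely.LineString([anchor, np.asarray(anchor) + 2.0 * direction])
    best = np.inf
    for c in extract_interface(ls):
        inter = ray.intersection(c.as_shapely())
        if inter.is_empty:
            continue
        pts = getattr(inter, "geoms", [inter])
        for g in pts:
            for xy in getattr(g, "coords", []):
                best = min(best, float(np.hypot(xy[0] - anchor[0],
                                                xy[1] - anchor[1])))
    return best


def run_simulation(
    edj: ContourPolyline,
    params: GrowthParams,
    conversion: ConversionSpec,
    bc: BoundarySpec | None = None,
    braces=None,
    probe=None,
    on_record=None,
) -> FrontHistory:
    """Full run from an EDJ contour.

    ``braces`` is an optional list of axis-aligned obstacle rectangles
    ``(x0, y0, x1, y1)`` in domain units, mimicking adjacent teeth and bone.
    ``probe = (anchor, direction, target_thickness)`` stops the run once the
    matrix thickness along the probe ray reaches the target (within one mesh
    spacing); otherwise the run stops at ``n_iter``.  Aborts if the front
    reaches a domain side (excluding braces and, with a basal sink, the
    bottom).
    """
    bc = bc or BoundarySpec.neumann()
    mesh = build_mesh(conversion.node_density)
    ls = contour_to_levelset(edj, conversion, mesh)
    if braces:
        add_obstacle_rectangles(ls, braces)
    nf = initialize_nutrients(ls, params.u_init)
    state = SimulationState(mesh, ls, nf, bc)
    state.accounting["initial_mass"] = nf.total_mass(ls)
    state.accounting["initial_area"] = solid_area(ls)

    initial_contours = extract_interface(ls)
    initial = max(initial_contours, key=lambda c: c.length())
    history = FrontHistory(initial=initial, record_every=params.record_every)
    history.records.append((0, initial_contours))

    stop_reason = "n_iter"
    for _ in range(params.n_iter):
        step(state, params)
        if state.step % params.record_every == 0:
            history.records.append((state.step, extract_interface(state.ls)))
            if on_record is not None:
                on_record(state)
        if _touches_boundary(state.ls, skip_bottom=bc.base_y is not None):
            raise RuntimeError(
                f"front reached the domain boundary at step {state.step}; "
                "the domain is too small (raise border or lower n_iter)"
            )
        if probe is not None:
            t = _probe_thickness(state.ls, initial, probe)
            if np.isfinite(t) and t >= probe[2] - mesh.h:
                stop_reason = f"probe target at step {state.step}"
                break
    if state.step != history.records[-1][0]:
        history.records.append((state.step, extract_interface(state.ls)))

    acc = state.accounting
    acc["final_mass"] = state.nutrients.total_mass(state.ls)
    acc["final_area"] = solid_area(state.ls)
    history.final_state = state
    history.accounting = acc
    history.stop_reason = stop_reason
    log.info("run finished: %s; area %.4f -> %.4f", stop_reason,
             acc["initial_area"], acc["final_area"])
    return history


def run_stack(
    edj_slices: list[ContourPolyline],
    params: GrowthParams,
    conversion: ConversionSpec,
    bc: BoundarySpec | None = None,
    braces=None,
) -> list[FrontHistory]:
    """Independent per-slice runs with identical parameters.

    All slices share one bounding box for the level-set conversion (the role
    the corner registration triangles play when slices are digitised as
    images), so differently sized EDJs keep a common scale.
    """
    if len(edj_slices) < 2:
        raise ValueError("run_stack needs at least 2 slices")
    closures = {c.closed for c in edj_slices}
    if len(closures) != 1:
        raise ValueError("slices mix open and closed contours")
    boxes = np.array([c.bbox() for c in edj_slices])
    common = (boxes[:, 0].min(), boxes[:, 1].min(),
              boxes[:, 2].max(), boxes[:, 3].max())
    conv = replace(conversion, bbox=common)
    histories = []
    for k, edj in enumerate(edj_slices):
        try:
            histories.append(run_simulation(edj, params, conv, bc, braces))
        except Exception as exc:
            raise RuntimeError(f"slice {k} failed: {exc}") from exc
    return histories
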