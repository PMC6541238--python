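"""Nutrient diffusion on the exterior (non-solid) region.

The ameloblast front consumes a diffusing "nutrient" — the collective stand-in
for everything the secreting cells need — whose concentration u obeys

    u_t = D ∆u + f        on the exterior region,

with homogeneous Neumann domain sides by default, optional zero-Dirichlet
sinks (domain sides or a horizontal basal line), and an absorbing interface:
the front carries the Gibbs–Thomson value

    u_Γ = max(0, u* + σ κ),

so nutrients flow into the front and, for σ > 0, convex ridges (κ > 0) see a
raised interface concentration that throttles their influx — the discrete
analogue of interfacial tension stiffening the ameloblast layer.

Discretisation: P1 finite elements on the structured triangulation with a
lumped mass matrix and implicit Euler in time.  Solid nodes (φ < 0, plus
obstacle nodes) are removed from the system sharply.  On this right-triangle
mesh the operator is an M-matrix, so nonnegative data stay nonnegative.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domain import LevelSetField, curvature, smooth_front_values

_SIDES = ("left", "right", "bottom", "top")


@dataclass
class BoundarySpec:
    """Domain-side conditions plus an optional basal sink line.

    Each side is ``"neumann"`` (no flux) or ``"dirichlet_zero"`` (perfect
    sink).  ``base_y`` places an additional zero-Dirichlet sink on the
    horizontal line y = base_y restricted to the exterior region — the
    model's approximation of the shorter matrix-secretion period near the
    crown base.
    """

    sides: dict = field(default_factory=lambda: {s: "neumann" for s in _SIDES})
    base_y: float | None = None

    def __post_init__(self) -> None:
        for s, kind in self.sides.items():
            if s not in _SIDES or kind not in ("neumann", "dirichlet_zero"):
                raise ValueError(f"bad boundary spec entry {s!r}: {kind!r}")
        self.sides = {s: self.sides.get(s, "neumann") for s in _SIDES}
        if self.base_y is not None and not 0 < self.base_y < 1:
            raise ValueError("base_y must lie in (0, 1)")

    @classmethod
    def neumann(cls) -> "BoundarySpec":
        return cls()

    @classmethod
    def basal_sink(cls, base_y: float) -> "BoundarySpec":
        """Mixed Dirichlet/Neumann: Neumann sides plus the basal sink line."""
        return cls(base_y=base_y)


@dataclass
class NutrientField:
    mesh: object
    u: np.ndarray

    def total_mass(self, ls: LevelSetField) -> float:
        act = ls.active_mask
        return float(np.sum(self.mesh.lumped_mass[act] * self.u[act]))


@dataclass
class DiffusionDiagnostics:
    """Per-step bookkeeping emitted alongside the updated field.

    ``front_flux`` is the nutrient mass absorbed at each interface-adjacent
    Dirichlet node during the step (the discrete Stefan flux);
    ``absorbed_total`` is the exact mass-balance deficit of the step, i.e.
    everything consumed at the front plus anything drained by sinks.
    """

    front_idx: np.ndarray
    front_flux: np.ndarray
    produced: float
    absorbed_total: float


def front_nodes(ls: LevelSetField) -> np.ndarray:
    """Exterior nodes with at least one growing-solid grid neighbour."""
    n = ls.mesh.node_density
    sg = (ls.phi < 0).reshape(n, n)
    nb = np.zeros_like(sg)
    nb[:, 1:] |= sg[:, :-1]
    nb[:, :-1] |= sg[:, 1:]
    nb[1:, :] |= sg[:-1, :]
    nb[:-1, :] |= sg[1:, :]
    return ls.active_mask & nb.ravel()


def initialize_nutrients(ls: LevelSetField, u_init: float) -> NutrientField:
    """Uniform initial concentration on the exterior, zero on the solid."""
    if u_init < 0:
        raise ValueError("u_init must be nonnegative")
    u = np.where(ls.active_mask, float(u_init), 0.0)
    return NutrientField(ls.mesh, u)


def _sink_mask(ls: LevelSetField, bc: BoundarySpec) -> np.ndarray:
    mesh = ls.mesh
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    for side, kind in bc.sides.items():
        if kind == "dirichlet_zero":
            mask[mesh.boundary_nodes(side)] = True
    if bc.base_y is not None:
        row = int(round(bc.base_y * (mesh.node_density - 1)))
        n = mesh.node_density
        mask[row * n : (row + 1) * n] = True
    return mask & ls.active_mask


def diffusion_step(
    nf: NutrientField,
    ls: LevelSetField,
    params,
    bc: BoundarySpec,
) -> tuple[NutrientField, DiffusionDiagnostics]:
    """Advance u by one implicit Euler step (or solve the quasi-static limit).

    ``params`` needs attributes D, f, dt, sigma, u_ref, tension_mode and
    quasi_static (see :class:`enamelsim.growth.GrowthParams`).
    """
    mesh = nf.mesh
    active = ls.active_mask
    act_idx = np.flatnonzero(active)
    if act_idx.size == 0:
        raise ValueError("no exterior nodes: the solid fills the domain")

    front = front_nodes(ls)
    dirichlet_vals = np.full(mesh.n_nodes, np.nan)
    u_base = max(0.0, float(params.u_ref))
    if front.any():
        if params.sigma > 0 and params.tension_mode == "boundary":
            # κ is smoothed along the front so the Gibbs-Thomson value sees
            # the resolved interface curvature, not staircase noise
            kappa = curvature(ls)
            f_idx = np.flatnonzero(front)
            k_smooth = smooth_front_values(
                mesh.nodes[f_idx], kappa[f_idx], np.ones(f_idx.size),
                radius=2.5 * mesh.h)
            dirichlet_vals[f_idx] = np.maximum(
                0.0, params.u_ref + params.sigma * k_smooth)
        else:
            dirichlet_vals[front] = u_base
    sink = _sink_mask(ls, bc)
    dirichlet_vals[sink] = 0.0

    m_act = mesh.lumped_mass[act_idx]
    k_act = mesh.stiffness[act_idx][:, act_idx]
    # Removing solid columns leaves positive row sums on interface-adjacent
    # rows, which would act as spurious flux into the solid whenever the
    # interface value is nonzero.  Restoring zero row sums makes the cut a
    # true no-flux boundary.
    rowsum = np.asarray(k_act.sum(axis=1)).ravel()
    k_act = (k_act - sp.diags(rowsum)).tocsr()
    dt = float(params.dt)
    if params.quasi_static:
        if not np.any(np.isfinite(dirichlet_vals[act_idx])):
            raise ValueError("quasi-static solve needs at least one Dirichlet node")
        a_mat = (params.D * k_act).tocsr()
        rhs = m_act * params.f
    else:
        a_mat = (sp.diags(m_act) + dt * params.D * k_act).tocsr()
        rhs = m_act * nf.u[act_idx] + dt * m_act * params.f

    vals_act = dirichlet_vals[act_idx]
    fixed = np.isfinite(vals_act)
    free = ~fixed
    u_act = np.where(fixed, vals_act, nf.u[act_idx])
    if free.any():
        a_ff = a_mat[free][:, free]
        b = rhs[free]
        if fixed.any():
            b = b - a_mat[free][:, fixed] @ vals_act[fixed]
        precond = sp.diags(1.0 / a_ff.diagonal())
        x, info = spla.cg(a_ff, b, x0=nf.u[act_idx][free], M=precond,
                          rtol=1e-10, atol=0.0, maxiter=2000)
        if info != 0:
            x = spla.spsolve(a_ff.tocsc(), b)
            if not np.all(np.isfinite(x)):
                raise RuntimeError(
                    f"diffusion linear solve failed (cg info={info})"
                )
        u_act[free] = x
    np.maximum(u_act, 0.0, out=u_act)

    u_new = np.zeros(mesh.n_nodes)
    u_new[act_idx] = u_act

    residual = rhs - a_mat @ u_act
    front_act = front[act_idx]
    front_flux = residual[front_act]
    if params.quasi_static:
        produced = absorbed = float("nan")
    else:
        produced = float(np.sum(dt * m_act * params.f))
        absorbed = float(np.sum(m_act * nf.u[act_idx]) + produced
                         - np.sum(m_act * u_act))
    return (
        NutrientField(mesh, u_new),
        DiffusionDiagnostics(
            front_idx=act_idx[front_act],
            front_flux=np.asarray(front_flux, dtype=float),
            produced=produced,
            absorbed_total=absorbed,
        ),
    )
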