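"""Reference study conditions for the regime demonstrations.

These are the package's canonical synthetic-EDJ experiments: the geometries,
parameter sets and stopping rules used to demonstrate the diffusion-limited
vs excess-nutrient dichotomy, the interfacial-tension sweep, and the
surface-complexity ordering.  Tests and the reproduction script both import
from here so the conditions are defined exactly once.

Background production levels 30 / 75 / 160 are the strong-diffusion-limited,
weak-diffusion-limited and excess-nutrient conditions respectively; all
other parameters are shared within an experiment family.
"""
from __future__ import annotations

import numpy as np
import shapely

from .contour_io import ConversionSpec, add_obstacle_rectangles, contour_to_levelset
from .domain import build_mesh, extract_interface
from .geometry import ContourPolyline
from .growth import FrontHistory, GrowthParams, SimulationState, step
from .nutrients import BoundarySpec, initialize_nutrients
from .shapes import ShapeSpec, make_shape

#: production levels: strong DL, weak DL, excess
PRODUCTION_LEVELS = (30.0, 75.0, 160.0)

#: lateral obstacle rectangles flanking vertical profiles (adjacent teeth/bone)
VERTICAL_BRACES = [(0.0, 0.20, 0.14, 0.80), (0.86, 0.20, 1.0, 0.80)]

#: basal sink position for vertical crown simulations
BASAL_SINK_Y = 0.25

#: crown-surface cutoff: front samples below this height belong to the base
CROWN_Y_MIN = 0.34


def reference_cusp(seed: int = 3, n_vertices: int = 256) -> ContourPolyline:
    """The 4-lobe molar-cusp cross-section used in the regime experiments:
    blunt convex ridges and open concave valleys, with seeded smooth noise."""
    return make_shape(
        ShapeSpec(kind="cusp_section", size=0.3, n_ridges=4,
                  ridge_amplitude=0.3, concavity_amplitude=0.0,
                  noise_amplitude=0.02, seed=seed),
        n_vertices,
    )


def notched_cusp(seed: int = 3, n_vertices: int = 256) -> ContourPolyline:
    """A fissured variant: narrow Gaussian notches in the valleys whose
    mouths are narrower than twice a typical enamel thickness, so uniform
    dilation closes them."""
    return make_shape(
        ShapeSpec(kind="cusp_section", size=0.3, n_ridges=4,
                  ridge_amplitude=0.15, concavity_amplitude=0.2,
                  noise_amplitude=0.0, seed=seed),
        n_vertices,
    )


def reference_vertical(seed: int = 5, n_vertices: int = 256) -> ContourPolyline:
    """Low-relief wavy vertical crown profile (human/orangutan-like)."""
    return make_shape(
        ShapeSpec(kind="vertical_profile", size=0.3,
                  waviness_amplitude=0.05, waviness_wavelength=0.15,
                  noise_amplitude=0.02, seed=seed),
        n_vertices,
    )


def cusp_params(f: float = 30.0, **overrides) -> GrowthParams:
    """Shared parameters of the cusp-section experiment family."""
    defaults = dict(D=0.05, lam=25.0, sigma=0.15, u_init=2.0, vmax=0.4,
                    f=f, n_iter=800)
    defaults.update(overrides)
    return GrowthParams(**defaults)


def vertical_params(f: float = 30.0, **overrides) -> GrowthParams:
    """Shared parameters of the vertical-profile experiment family.

    Interfacial tension is lower than in the cusp family so the subtle
    surface ripples can be amplified by the diffusion-limited effect, and
    the secretion cap slightly higher so the excess run tracks (rather than
    over-smooths) the rippled template."""
    defaults = dict(D=0.05, lam=25.0, sigma=0.02, u_init=2.0, vmax=0.5,
                    f=f, n_iter=1500)
    defaults.update(overrides)
    return GrowthParams(**defaults)


def largest_front(contours) -> ContourPolyline:
    closed = [c for c in contours if c.closed]
    return max(closed, key=lambda c: c.length())


def front_thickness_samples(front: ContourPolyline, edj: ContourPolyline,
                            n: int = 800, y_min: float | None = None
                            ) -> np.ndarray:
    """Distances from evenly sampled front points to the EDJ contour."""
    from .contour_io import resample_by_count

    pts = resample_by_count(front, n).vertices
    if y_min is not None:
        pts = pts[pts[:, 1] > y_min]
    return np.asarray(shapely.distance(shapely.points(pts), edj.as_shapely()))


def run_to_mean_thickness(
    edj: ContourPolyline,
    params: GrowthParams,
    conversion: ConversionSpec | None = None,
    bc: BoundarySpec | None = None,
    braces=None,
    target: float | None = None,
    y_min: float | None = None,
    check_every: int = 4,
) -> FrontHistory:
    """Run the simulation, stopping once the mean front-to-EDJ distance
    reaches ``target`` (or at ``params.n_iter``).

    This is the matched-thickness protocol used whenever two regimes are
    compared "at the same mean matrix thickness".  Fronts are recorded every
    ``check_every`` steps.  Raises if the front reaches an unbraced domain
    side.
    """
    conversion = conversion or ConversionSpec()
    bc = bc or BoundarySpec.neumann()
    mesh = build_mesh(conversion.node_density)
    ls = contour_to_levelset(edj, conversion, mesh)
    if braces:
        add_obstacle_rectangles(ls, braces)
    nf = initialize_nutrients(ls, params.u_init)
    state = SimulationState(mesh, ls, nf, bc)
    init_contours = extract_interface(ls)
    initial = max(init_contours, key=lambda c: c.length())
    history = FrontHistory(initial=initial, records=[(0, init_contours)],
                           record_every=check_every)
    n = conversion.node_density
    stop = "n_iter"
    for _ in range(params.n_iter):
        step(state, params)
        if state.step % check_every:
            continue
        solid = (state.ls.phi < 0).reshape(n, n)
        if (solid[:, 0].any() or solid[:, -1].any() or solid[-1, :].any()
                or (bc.base_y is None and solid[0, :].any())):
            raise RuntimeError(
                f"front reached the domain boundary at step {state.step}")
        contours = extract_interface(state.ls)
        history.records.append((state.step, contours))
        if target is not None:
            d = front_thickness_samples(largest_front(contours), initial,
                                        n=400, y_min=y_min)
            if d.size and float(d.mean()) >= target:
                stop = f"thickness target at step {state.step}"
                break
    history.final_state = state
    history.accounting = state.accounting
    history.stop_reason = stop
    return history
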