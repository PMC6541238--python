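"""The moving-boundary engine."""
import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

import enamelsim as es
from enamelsim.domain import LevelSetField
from enamelsim.growth import (GrowthParams, SimulationState, interface_velocity,
                              run_simulation, run_stack, step)
from enamelsim.nutrients import (BoundarySpec, NutrientField, front_nodes,
                                 initialize_nutrients)


def test_params_validation():
    with pytest.raises(ValueError):
        GrowthParams(D=-1)
    with pytest.raises(ValueError):
        GrowthParams(sigma=-0.1)
    with pytest.raises(ValueError):
        GrowthParams(velocity_source="psychic")


def test_velocity_zero_field_gives_zero(mesh65):
    phi = mesh65.nodes[:, 1] - 0.5
    ls = LevelSetField(mesh65, phi)
    nf = NutrientField(mesh65, np.zeros(mesh65.n_nodes))
    vn = interface_velocity(nf, ls, GrowthParams(velocity_source="gradient"))
    assert np.all(vn == 0)


def test_velocity_flat_interface_linear_field(mesh65):
    # u = g·distance above a flat solid: Vn = D·g/λ on the interface
    phi = mesh65.nodes[:, 1] - 0.5
    ls = LevelSetField(mesh65, phi)
    g = 3.0
    u = np.where(phi >= 0, g * phi, 0.0)
    nf = NutrientField(mesh65, u)
    params = GrowthParams(D=0.05, lam=25.0, velocity_source="gradient",
                          vmax=10.0)
    vn = interface_velocity(nf, ls, params)
    front = front_nodes(ls)
    expected = params.D * g / params.lam
    assert np.abs(vn[front] - expected).max() / expected < 0.05


def laplace_flux_oracle(ls):
    """Independent dense 5-point Laplace solve: u=0 on solid-adjacent nodes,
    u=1 on the domain boundary; returns outward flux at each front node."""
    mesh = ls.mesh
    n = mesh.node_density
    h = mesh.h
    solid = (ls.phi < 0)
    front = front_nodes(ls)
    lap = sp.lil_matrix((n * n, n * n))
    rhs = np.zeros(n * n)
    boundary = np.zeros(n * n, bool)
    for side in ("left", "right", "top", "bottom"):
        boundary[mesh.boundary_nodes(side)] = True
    for idx in range(n * n):
        if solid[idx] or front[idx]:
            lap[idx, idx] = 1.0
            rhs[idx] = 0.0
        elif boundary[idx]:
            lap[idx, idx] = 1.0
            rhs[idx] = 1.0
        else:
            lap[idx, idx] = -4.0
            for nb in (idx - 1, idx + 1, idx - n, idx + n):
                lap[idx, nb] = 1.0
    u = spla.spsolve(lap.tocsr(), rhs)
    flux = np.zeros(n * n)
    for idx in np.flatnonzero(front):
        for nb in (idx - 1, idx + 1, idx - n, idx + n):
            if 0 <= nb < n * n and not solid[nb] and not front[nb]:
                flux[idx] += (u[nb] - u[idx]) / h
    return flux


def test_ridge_receives_more_flux_than_valley(mesh65):
    # screening: convex ridge tips outcompete concave valleys for nutrients,
    # in the model and in an independent dense Laplace oracle
    theta = np.arctan2(mesh65.nodes[:, 1] - 0.5, mesh65.nodes[:, 0] - 0.5)
    r = np.hypot(mesh65.nodes[:, 0] - 0.5, mesh65.nodes[:, 1] - 0.5)
    phi = r - 0.22 * (1 + 0.3 * np.cos(4 * theta))
    ls = es.reinitialize(LevelSetField(mesh65, phi))
    flux = laplace_flux_oracle(ls)
    front = np.flatnonzero(front_nodes(ls))
    th = theta[front]
    ridge = np.abs(np.remainder(th + np.pi / 4, np.pi / 2) - np.pi / 4) < 0.2
    valley = ~ridge & (np.abs(np.remainder(th, np.pi / 2) - np.pi / 4) < 0.2)
    assert flux[front][ridge].mean() > flux[front][valley].mean()

    # the simulator's own velocity shows the same ordering (uncapped so the
    # sub-cap flux pattern is visible)
    nf = initialize_nutrients(ls, 2.0)
    params = GrowthParams(sigma=0.0, vmax=100.0)
    from enamelsim.nutrients import diffusion_step

    nf2, diag = diffusion_step(nf, ls, params, BoundarySpec.neumann())
    vn = interface_velocity(nf2, ls, params, diag)
    assert vn[front][ridge].mean() > vn[front][valley].mean()


def make_state(contour, n=65, u_init=2.0, braces=None):
    mesh = es.build_mesh(n)
    ls = es.contour_to_levelset(contour, es.ConversionSpec(node_density=n), mesh)
    if braces:
        es.contour_io.add_obstacle_rectangles(ls, braces)
    nf = initialize_nutrients(ls, u_init)
    return SimulationState(mesh, ls, nf, BoundarySpec.neumann())


def test_zero_iterations_leaves_state_unchanged(circle_contour):
    params = GrowthParams(n_iter=0)
    h = run_simulation(circle_contour, params, es.ConversionSpec(node_density=65))
    assert len(h.records) == 1 and h.records[0][0] == 0


def test_monotone_solid_growth(circle_contour):
    state = make_state(circle_contour)
    params = GrowthParams()
    prev_solid = state.ls.phi < 0
    for _ in range(20):
        step(state, params)
        solid = state.ls.phi < 0
        assert np.all(solid[prev_solid])
        prev_solid = solid


def test_run_is_deterministic(cusp_contour):
    params = GrowthParams(n_iter=24)
    conv = es.ConversionSpec(node_density=65)
    h1 = run_simulation(cusp_contour, params, conv)
    h2 = run_simulation(cusp_contour, params, conv)
    assert h1.steps == h2.steps
    for (s1, c1), (s2, c2) in zip(h1.records, h2.records):
        assert s1 == s2 and len(c1) == len(c2)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.vertices, b.vertices)


def test_recording_interval(short_run):
    steps = short_run.steps
    assert steps[0] == 0
    assert all(b - a == 4 for a, b in zip(steps[:-2], steps[1:-1]))


def test_braces_never_invaded(circle_contour):
    braces = [(0.0, 0.4, 0.15, 0.6)]
    state = make_state(circle_contour, braces=braces)
    params = GrowthParams(f=160.0)
    x, y = state.mesh.nodes.T
    inside = (x <= 0.15) & (y >= 0.4) & (y <= 0.6)
    for _ in range(30):
        step(state, params)
        assert not (state.ls.phi[inside] < 0).any()


def test_boundary_abort(circle_contour):
    params = GrowthParams(f=160.0, n_iter=4000)
    with pytest.raises(RuntimeError, match="domain boundary"):
        run_simulation(circle_contour, params,
                       es.ConversionSpec(node_density=65, border=0.2))


def test_probe_stop(circle_contour):
    params = GrowthParams(n_iter=500)
    probe = ((0.5 + 0.2, 0.5), (1.0, 0.0), 0.03)
    h = run_simulation(circle_contour, params,
                       es.ConversionSpec(node_density=65, border=0.35),
                       probe=probe)
    assert "probe" in h.stop_reason
    assert h.records[-1][0] < 500


def test_nutrient_accounting_closes_over_run(circle_contour):
    params = GrowthParams(n_iter=100)
    h = run_simulation(circle_contour, params, es.ConversionSpec(node_density=65))
    acc = h.accounting
    lhs = acc["initial_mass"] + acc["produced"] - acc["absorbed"] - acc["swallowed"]
    assert np.isclose(lhs, acc["final_mass"], rtol=1e-6, atol=1e-9)


def test_run_stack_identical_slices(circle_contour):
    params = GrowthParams(n_iter=16)
    conv = es.ConversionSpec(node_density=65)
    histories = run_stack([circle_contour, circle_contour, circle_contour],
                          params, conv)
    assert len(histories) == 3
    f0 = histories[0].final_fronts[0].vertices
    for h in histories[1:]:
        assert np.array_equal(h.final_fronts[0].vertices, f0)


def test_run_stack_input_validation(circle_contour):
    params = GrowthParams(n_iter=4)
    conv = es.ConversionSpec(node_density=65)
    with pytest.raises(ValueError):
        run_stack([], params, conv)
    with pytest.raises(ValueError):
        run_stack([circle_contour], params, conv)
    open_c = es.ContourPolyline([[0, 0], [1, 0.5], [2, 0]], closed=False)
    with pytest.raises(ValueError, match="mix"):
        run_stack([circle_contour, open_c], params, conv)


def test_run_stack_common_scale():
    # shrinking slices share one bounding box, hence one scale factor
    big = es.make_shape(es.ShapeSpec(kind="circle", size=0.3), 128)
    small = es.make_shape(es.ShapeSpec(kind="circle", size=0.15), 128)
    params = GrowthParams(n_iter=0)
    conv = es.ConversionSpec(node_density=65, border=0.3)
    hb, hs = run_stack([big, small], params, conv)
    rb = np.hypot(*(hb.initial.vertices - 0.5).T).mean()
    rs = np.hypot(*(hs.initial.vertices - 0.5).T).mean()
    assert np.isclose(rb / rs, 2.0, rtol=0.05)
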