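"""Contour file IO, resampling, level-set conversion and artefact output."""
import numpy as np
import pytest

import enamelsim as es
from enamelsim.contour_io import (ConversionSpec, contour_to_levelset,
                                  read_xy_contour, registration_triangle_contours,
                                  resample_by_count, resample_contour,
                                  scale_to_domain, write_step_image,
                                  write_surface_obj, write_xy_contour,
                                  read_obj_vertices)
from enamelsim.geometry import ContourPolyline, point_segment_distance


def test_read_square_and_roundtrip(tmp_path):
    p = tmp_path / "sq.xy"
    p.write_text("0 0\n1 0\n1 1\n0 1\n")
    c = read_xy_contour(p, closed=True)
    assert len(c) == 4 and c.closed and c.units == "pixel"
    out = tmp_path / "out.xy"
    write_xy_contour(c, out)
    c2 = read_xy_contour(out, closed=True)
    assert np.allclose(c.vertices, c2.vertices)


def test_delimiters_and_closure_inference(tmp_path):
    p = tmp_path / "c.xy"
    p.write_text("0,0\n1\t0\n1 1\n0 1\n0 0\n")
    c = read_xy_contour(p)
    assert c.closed and len(c) == 4


def test_parse_error_names_line(tmp_path):
    p = tmp_path / "bad.xy"
    p.write_text("0 0\na b\n1 1\n")
    with pytest.raises(ValueError, match="line 2"):
        read_xy_contour(p)
    p2 = tmp_path / "short.xy"
    p2.write_text("0 0\n1 1\n")
    with pytest.raises(ValueError, match="fewer than 3"):
        read_xy_contour(p2)


def test_resample_square_perimeter40_interval10_gives_corners():
    sq = ContourPolyline([[0, 0], [10, 0], [10, 10], [0, 10]], closed=True)
    r = resample_contour(sq, 10.0)
    assert len(r) == 4
    assert np.allclose(sorted(map(tuple, r.vertices)), sorted(map(tuple, sq.vertices)))


def test_resample_exact_count_for_matching_interval(circle_contour):
    total = circle_contour.length()
    r = resample_contour(circle_contour, total / 100)
    assert len(r) == 100
    seg = np.hypot(*np.diff(np.vstack([r.vertices, r.vertices[:1]]), axis=0).T)
    assert np.allclose(seg, total / 100, rtol=5e-2)


def test_resample_idempotent_count():
    sq = ContourPolyline([[0, 0], [10, 0], [10, 10], [0, 10]], closed=True)
    once = resample_contour(sq, 2.0)
    twice = resample_contour(once, 2.0)
    assert len(once) == len(twice)


def test_resample_invalid_interval(circle_contour):
    with pytest.raises(ValueError):
        resample_contour(circle_contour, 0.0)
    with pytest.raises(ValueError):
        resample_contour(circle_contour, circle_contour.length())


def test_levelset_matches_brute_force_distance(mesh65):
    # exact-geometry contract: conversion agrees with the point-to-segment
    # oracle at every node to 1e-9
    cusp = es.make_shape(es.ShapeSpec(kind="cusp_section", size=0.3,
                                      ridge_amplitude=0.2, n_ridges=4), 128)
    spec = ConversionSpec(node_density=65, border=0.3)
    ls = contour_to_levelset(cusp, spec, mesh65)
    scaled = scale_to_domain(cusp, spec).oriented_ccw()
    a, b = scaled.segments
    oracle = point_segment_distance(mesh65.nodes, a, b)
    assert np.allclose(np.abs(ls.phi), oracle, atol=1e-9)


def test_levelset_sign_convention(mesh65, circle_contour):
    ls = contour_to_levelset(circle_contour, ConversionSpec(node_density=65),
                             mesh65)
    centre = np.argmin(np.hypot(mesh65.nodes[:, 0] - 0.5,
                                mesh65.nodes[:, 1] - 0.5))
    corner = 0
    assert ls.phi[centre] < 0
    assert ls.phi[corner] > 0


def test_centered_square_phi_at_center():
    # axis-aligned square of side s: distance from centre to nearest side s/2
    mesh = es.build_mesh(65)
    sq = ContourPolyline([[-1, -1], [1, -1], [1, 1], [-1, 1]], closed=True)
    spec = ConversionSpec(node_density=65, border=0.25)
    ls = contour_to_levelset(sq, spec, mesh)
    centre = np.argmin(np.hypot(mesh.nodes[:, 0] - 0.5, mesh.nodes[:, 1] - 0.5))
    assert np.isclose(ls.phi[centre], -0.25, atol=1e-9)


def test_registration_triangles_are_obstacles_clear_of_edj(mesh65, cusp_contour):
    spec = ConversionSpec(node_density=65, border=0.3,
                          registration_triangles=True)
    ls = contour_to_levelset(cusp_contour, spec, mesh65)
    assert ls.obstacle_mask.any()
    # obstacles sit strictly in the border margins, away from the solid
    assert not (ls.obstacle_mask & (ls.phi < 0)).any()
    for tri in registration_triangle_contours(spec):
        assert tri.max() < 0.3 or tri.min() > 0.7


def test_open_profile_closed_along_base(mesh65):
    prof = es.make_shape(es.ShapeSpec(kind="vertical_profile", size=0.3,
                                      waviness_amplitude=0.03,
                                      waviness_wavelength=0.2, seed=1), 128)
    ls = contour_to_levelset(prof, ConversionSpec(node_density=65), mesh65)
    assert (ls.phi < 0).any() and (ls.phi > 0).any()
    contours = es.extract_interface(ls)
    assert any(c.closed for c in contours)


def test_step_image_deterministic_and_area_faithful(tmp_path, mesh65):
    # lower half of the domain solid -> half the pixels solid-coloured
    phi = mesh65.nodes[:, 1] - 0.5
    ls = es.LevelSetField(mesh65, phi)
    p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
    write_step_image(ls, p1, scale=2)
    write_step_image(ls, p2, scale=2)
    assert p1.read_bytes() == p2.read_bytes()
    from PIL import Image

    arr = np.asarray(Image.open(p1))
    solid_frac = np.mean(np.all(arr == 130, axis=-1))
    assert abs(solid_frac - 0.5) < 0.02


def test_surface_obj_roundtrip(tmp_path):
    sq = ContourPolyline([[0, 0], [1, 0], [1, 1], [0, 1]], closed=True)
    stack = es.stack_slices([sq, sq], z_spacing=1.0)
    path = tmp_path / "s.obj"
    write_surface_obj(stack, path)
    verts = read_obj_vertices(path)
    assert len(verts) == len(stack.vertices) == 8
    assert len(stack.faces) == 8


def test_conversion_spec_validation():
    with pytest.raises(ValueError):
        ConversionSpec(border=1.2)
    with pytest.raises(ValueError):
        ConversionSpec(node_density=8)
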