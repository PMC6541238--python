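"""Synthetic enamel–dentine-junction (EDJ) geometries.

Real EDJ traces come from tomography sections; this module generates
stand-ins with controllable convex ridges and concave valleys so the whole
pipeline is exercisable without scan data.  Two families matter:

* ``cusp_section`` — a closed molar-cusp cross-section: a cosine-lobe radius
  function (convex ridges) with optional localized Gaussian concavities in
  the valleys, mimicking pig-molar horizontal slices.
* ``vertical_profile`` — an open, low-relief wavy crown profile whose two
  endpoints sit on the crown-base line, mimicking human/orangutan vertical
  sections.

``circle`` and ``square`` are analytic controls, and the Koch snowflake is
the fractal reference curve for the box-counting estimator.

Seeded noise is band-limited (a few smooth Fourier modes), never per-vertex
white noise, so interfacial-tension effects in the simulator are not
confounded by sub-mesh roughness.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ContourPolyline

_KINDS = ("cusp_section", "vertical_profile", "circle", "square", "koch_curve")


@dataclass
class ShapeSpec:
    """Parameters of a synthetic EDJ shape.

    ``size`` is the base radius (closed kinds) or width (vertical profiles).
    Amplitudes are fractions of ``size``.  For ``koch_curve``, ``n_ridges``
    is reused as the recursion level.  The same spec and seed always produce
    byte-identical output.
    """

    kind: str = "cusp_section"
    size: float = 0.3
    n_ridges: int = 4
    ridge_amplitude: float = 0.0
    concavity_amplitude: float = 0.0
    waviness_wavelength: float = 0.25
    waviness_amplitude: float = 0.0
    noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; choose from {_KINDS}")
        for name in ("ridge_amplitude", "concavity_amplitude", "noise_amplitude",
                     "waviness_amplitude"):
            val = getattr(self, name)
            if not 0 <= val < 1:
                raise ValueError(f"{name} must be in [0, 1), got {val}")
        if self.size <= 0:
            raise ValueError("size must be positive")


def _smooth_noise(t: np.ndarray, amplitude: float, seed: int,
                  modes: range) -> np.ndarray:
    """Band-limited periodic noise on t ∈ [0, 1), max amplitude as given."""
    if amplitude == 0:
        return np.zeros_like(t)
    rng = np.random.default_rng(seed)
    out = np.zeros_like(t)
    for m in modes:
        a, phase = rng.normal(), rng.uniform(0, 2 * np.pi)
        out += a * np.cos(2 * np.pi * m * t + phase)
    peak = np.max(np.abs(out))
    return out * (amplitude / peak) if peak > 0 else out


def _wrapped_angle(theta: np.ndarray, center: float) -> np.ndarray:
    d = (theta - center) % (2 * np.pi)
    return np.where(d > np.pi, d - 2 * np.pi, d)


def make_shape(spec: ShapeSpec, n_vertices: int = 256) -> ContourPolyline:
    """Generate a contour from a :class:`ShapeSpec`.

    Raises ``ValueError`` for parameter combinations that would produce a
    degenerate or self-intersecting contour.
    """
    if n_vertices < 8:
        raise ValueError("n_vertices must be at least 8")
    if spec.kind == "circle":
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        v = spec.size * np.column_stack([np.cos(theta), np.sin(theta)])
        return ContourPolyline(v, closed=True)
    if spec.kind == "square":
        k = n_vertices // 4
        s = np.linspace(-1, 1, k, endpoint=False)
        one = np.ones(k)
        v = spec.size * np.concatenate([
            np.column_stack([s, -one]),
            np.column_stack([one, s]),
            np.column_stack([-s, one]),
            np.column_stack([-one, -s]),
        ])
        return ContourPolyline(v, closed=True)
    if spec.kind == "koch_curve":
        return make_koch_contour(spec.n_ridges, size=spec.size)
    if spec.kind == "cusp_section":
        return _cusp_section(spec, n_vertices)
    return _vertical_profile(spec, n_vertices)


def _cusp_section(spec: ShapeSpec, n_vertices: int) -> ContourPolyline:
    k = spec.n_ridges
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = 1.0 + spec.ridge_amplitude * np.cos(k * theta)
    if spec.concavity_amplitude > 0:
        width = np.pi / (3 * max(k, 1))
        for j in range(k):
            center = (2 * j + 1) * np.pi / k
            d = _wrapped_angle(theta, center)
            r -= spec.concavity_amplitude * np.exp(-0.5 * (d / width) ** 2)
    r += _smooth_noise(theta / (2 * np.pi), spec.noise_amplitude, spec.seed,
                       modes=range(k + 3, k + 9))
    r *= spec.size
    if np.any(r <= 0):
        raise ValueError(
            "cusp_section radius function goes non-positive; reduce "
            "concavity_amplitude/noise_amplitude relative to ridge_amplitude"
        )
    v = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    contour = ContourPolyline(v, closed=True)
    if not contour.is_simple():
        raise ValueError(
            "cusp_section parameters produce a self-intersecting contour; "
            "reduce amplitudes or increase n_vertices"
        )
    return contour


def _vertical_profile(spec: ShapeSpec, n_vertices: int) -> ContourPolyline:
    # Open crown profile: a dome of height 0.45·size with superimposed
    # waviness and noise, both tapered to zero at the basal endpoints.
    t = np.linspace(0.0, 1.0, n_vertices)
    x = spec.size * t
    envelope = np.sin(np.pi * t) ** 0.7
    y = 0.45 * spec.size * envelope
    if spec.waviness_amplitude > 0:
        wavelength = spec.waviness_wavelength * spec.size
        y += (spec.waviness_amplitude * spec.size
              * np.sin(2 * np.pi * x / wavelength) * np.sin(np.pi * t))
    y += spec.size * _smooth_noise(0.5 * t, spec.noise_amplitude, spec.seed,
                                   modes=range(6, 13)) * np.sin(np.pi * t)
    y[0] = y[-1] = 0.0
    if np.any(y[1:-1] <= 0):
        raise ValueError(
            "vertical_profile dips below the base line; reduce "
            "waviness_amplitude/noise_amplitude"
        )
    contour = ContourPolyline(np.column_stack([x, y]), closed=False)
    if not contour.is_simple():
        raise ValueError("vertical_profile parameters produce self-intersection")
    return contour


def make_koch_contour(level: int, size: float = 1.0) -> ContourPolyline:
    """Koch-snowflake boundary at the given recursion level.

    Level 0 is an equilateral triangle of side ``size``; each level replaces
    every edge with four edges of a third the length, so the boundary has
    ``3·4**level`` segments and perimeter ``3·size·(4/3)**level``.
    """
    if not 0 <= level <= 7:
        raise ValueError("level must be in [0, 7]")
    v = size * np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    for _ in range(level):
        a, b = v, np.roll(v, -1, axis=0)
        d = b - a
        p1 = a + d / 3
        p2 = a + 2 * d / 3
        # outward (right-of-travel for a CCW polygon) bump tip
        normal = np.column_stack([d[:, 1], -d[:, 0]])
        tip = a + d / 2 + normal * (np.sqrt(3) / 6)
        v = np.stack([a, p1, tip, p2], axis=1).reshape(-1, 2)
    return ContourPolyline(v, closed=True)
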