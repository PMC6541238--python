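# Methods

## Model

Enamel matrix secretion is modelled as a one-phase Stefan-type free
boundary problem on the unit square. The solid region (dentine plus
deposited matrix) is the sublevel set {φ < 0} of a signed-distance field φ
sampled on a regular right-triangle mesh with `node_density` nodes per axis
(spacing h = 1/(node_density−1)). A scalar nutrient concentration u lives
on the exterior nodes and obeys

  u_t = D Δu + f,

discretised with P1 finite elements, a lumped mass matrix and implicit
Euler at a fixed time step dt = 0.001. Solid nodes are removed from the
system sharply; the row sums of the cut stiffness matrix are restored to
zero so the cut acts as a true no-flux boundary. On this triangulation the
operator is the five-point M-matrix, so nonnegative data stay nonnegative
and the discrete Neumann mass balance is exact.

The interface carries a Dirichlet value with the Gibbs–Thomson curvature
penalty, u|_Γ = max(0, u* + σκ) with κ > 0 at convex ridges (clamped to
the grid-resolvable bound 1/h and smoothed tangentially over 2.5h so the
penalty sees the resolved interface, not staircase noise). Raising σ
throttles influx at convex tips and smooths the front; σ → 0 admits
crenulation. The front's normal speed is the Stefan flux balance

  V_n = min( flux / (λ ℓ), V_max ),   clamped ≥ 0,

where, in the default "reaction" extraction, *flux* is the nutrient mass
absorbed at each interface-adjacent Dirichlet node (read off the residual
of the implicit solve) and ℓ the interface length attributed to the node
(Voronoi partition of the extracted zero contour, then a ratio-of-sums
kernel of radius 1.5h to cancel staircase node-density noise). This makes
total consumption equal λ × swept area by construction; the measured
closure against the geometric area gain is 1–3% at node_density 129. A
"gradient" extraction (one-sided exterior difference of u along the
normal, the textbook form) is available and is what the velocity-law unit
tests exercise; it is less conservative (~25% at the same resolution).

V_max is the ameloblast layer's intrinsic maximum secretion speed. It is
the mechanism behind the excess-nutrient regime: when background
production outruns what the cells can use, the front advances uniformly at
the cap and the result approximates the geometric extrapolation of the
EDJ. Without a cap the pure Stefan model cannot produce this regime — the
approach of u to the Stefan capacity λ is always ridge-first, so *more*
production gives *more* fingering, the opposite of the uniform-matrix
behaviour the model is meant to capture. Biologically the cap encodes that
secretion rate saturates; "excess production overcomes diffusion-limited
effects" is then literal: the diffusion field stops being the limiting
factor.

Velocity values are extended from the interface to a band of half-width 5h
(constant along the normal, by nearest interface node) and φ is advected
with a Godunov upwind scheme, CFL-substepped at max|V_n|·dt_sub ≤ h/2.
Every 5 steps φ is reinitialised geometrically: the zero contour is
extracted (marching squares, linear interpolation), resampled at h/8, and
exact distances to it are recomputed with each node keeping its sign. The
fixed point of this reinitialisation is interpolation-limited (O(h²), about
2·10⁻⁴ at node_density 129), far below the h/2 displacement bound.

Static obstacles — corner registration triangles and the lateral "braces"
that mimic adjacent teeth and bone in vertical simulations — are held in a
separate node mask rather than inside φ: they block diffusion and growth
but never appear in extracted fronts or measurements. Domain sides are
no-flux by default; a basal sink (u = 0 on a horizontal line below the
crown base) models the shorter secretion period low on the crown, and in
those runs thickness declines from cusp tip toward the base.

## Parameters

All quantities are dimensionless; only ratios matter.

| parameter | default | meaning |
|---|---|---|
| D | 0.05 | nutrient diffusion rate |
| λ (`lam`) | 25 | nutrient mass per unit area of matrix |
| σ (`sigma`) | 0.15 | interfacial tension (0.02 in vertical runs) |
| f | 30 | background production; 30/75/160 = strong-DL/weak-DL/excess |
| u_init | 2 | initial exterior concentration |
| V_max (`vmax`) | 0.4 | max secretion speed (0.5 in vertical runs) |
| dt | 0.001 | time step |
| node_density | 129 | mesh nodes per axis |
| border | 0.32 | margin fraction around the scaled EDJ |
| record_every | 4 | spacing of recorded fronts (virtual incremental lines) |

The production levels 30/75/160 are the strong-diffusion-limited, weak and
excess conditions used throughout. D, λ, u_init and V_max were chosen once
so that those three levels actually straddle the regime boundary: with
u_init well below λ both regimes start alike ("initially uniform"
incremental lines); at f = 30 consumption balances production below λ, the
quasi-static field screens the valleys and ridge/valley divergence grows;
at f = 160 the front saturates at V_max everywhere and advances uniformly.
The vertical family lowers σ (so subtle surface ripples can be amplified
at all) and raises V_max slightly (so the capped excess run tracks rather
than over-smooths the rippled template). The velocity cap value matters at
the few-percent level: the cusp family uses 0.4 because at 0.5 the cap can
fail to engage inside deep noise-valleys for some shape seeds, leaving a
thickness deficit there.

## Synthetic geometry

The shape generator emulates two EDJ archetypes. Closed cusp sections use
a cosine-lobe radius function r(θ) = size·(1 + a·cos kθ), optionally with
localized Gaussian notches in the valleys (the "fissured" variant, whose
mouths are narrower than twice a typical enamel thickness so the
uniform-dilation null model bridges them) and band-limited seeded noise —
never per-vertex white noise, so interfacial-tension effects are not
confounded with sub-mesh roughness. Open vertical profiles are a dome with
superimposed waviness, endpoints on the crown-base line; they are closed
along that line before level-set conversion. The Koch snowflake provides
an analytic fractal (perimeter 3·(4/3)^k, dimension log4/log3) for the
box-counting estimator.

These shapes reproduce the *qualitative* features that drive the model —
convexity contrasts, narrow fissures, low-relief ripples — but no attempt
is made to match real pig or hominid EDJ shape statistics, curvature
spectra, or the scale hierarchy of a whole tooth. Passing tests on them
shows the mechanism and the measurement chain behave as described, not
that any particular species' enamel distribution is predicted; applying
the simulator to real scans requires digitised EDJ contours and a
thickness calibration against the specimen.

## Measurements

Thickness progression is measured along labelled rays (ridge tips, valley
bottoms) anchored on the EDJ; a ray that misses the front records an
absent value, never zero. Enamel area and front perimeter come from the
extracted polygons. The box-counting dimension follows the
12-grid-origins × 10-rotations protocol (120 estimates per contour;
rotation of the raster, bilinear with re-binarisation): box sizes run in a
geometric series from 2 px to a quarter of the image side, and sizes with
fewer than 8 occupied boxes are dropped from the log–log regression
because they are saturated by the object's finite extent (a straight line
otherwise reads ≈0.93; with the filter, ≈0.97 unrotated; residual raster-
rotation bias leaves the pooled mean for a line near 0.94). Surface
distance summaries sample one geometry densely against the other
(point-to-segment in 2D, exact point-to-triangle in 3D) in both
directions; stacked slices are resampled to a common vertex count, aligned
by nearest start vertex and joined by triangle strips.

The uniform-thickness null model offsets the signed-distance field of the
EDJ and extracts the d-level contour; a raster path (Euclidean distance
transform of the rasterised solid, half-pixel-corrected, thresholded with
subpixel interpolation) exists purely as a cross-check and agrees within
about two raster pixels.

## Numerical and protocol choices

Matched-regime comparisons use a matched-thickness protocol: a run stops
when the mean front-to-EDJ distance reaches a target (0.10 for the cusp
excess run, 0.08 over the crown surface for vertical runs), so fronts are
compared at the same mean matrix thickness, echoing how simulations are
matched to empirical enamel thickness. The diffusion-limited reference run
is a fixed 800 steps, ending while the ridge/valley ratio is still rising
and the front is clear of the domain walls. Ratio monotonicity is judged
with a tolerance propagated from the h/2 single-thickness measurement
resolution, over the steps where the valley thickness exceeds 1.5h.
Simulation sizes (node_density 129, a few hundred to ~1500 steps,
1024-pixel rasters for box counting) keep each reference experiment in the
tens-of-seconds range on one CPU.

Known limitations: the solver is first-order in the interface position
(O(h) flux localisation), the Gibbs–Thomson clamp at u ≥ 0 makes tension
one-sided in concavities, thin-fissure interiors below the mesh scale
pinch off rather than fill, the raster-rotation step of the box-counting
protocol carries a small negative bias, and the 30-vs-75 complexity
ordering margin on the vertical reference (~0.005–0.01 in D_B) is modest.
The exact weak form, reinitialisation schedule and per-figure iteration
counts of the original formulation are not recoverable from the available
text; where they were open, the choices above are this package's own and
are exposed as configuration.
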