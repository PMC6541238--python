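# enamelsim

Simulation of tooth enamel matrix secretion as a diffusion-limited free
boundary problem.

## The problem

Enamel is laid down by a front of ameloblast cells that detaches from the
enamel–dentine junction (EDJ) and secretes matrix outward. The finished
enamel surface is *not* a uniform-thickness copy of the dentine template:
convex EDJ ridges end up under thick enamel, concave valleys under thin
enamel and deep fissures. `enamelsim` is for developmental biologists and
dental morphologists who want a mechanistic, predictive account of that
mapping: given an EDJ cross-section (a digitised contour, or a synthetic
shape), it simulates the advancing secretory front and compares the result
with the uniform-thickness null model.

## The model

The ameloblast layer is a moving interface Γ(t), the zero level set of a
signed-distance field φ on a regular triangular mesh over the unit square
(φ < 0 inside dentine + deposited matrix). Growth consumes a diffusing
nutrient field u on the exterior:

    u_t = D Δu + f                     (exterior region)
    u|_Γ = max(0, u* + σκ)             (Gibbs–Thomson interface value)
    V_n  = min( (D/λ) ∂u/∂n |_Γ⁺ , V_max )   (Stefan condition, capped)

with D the diffusion rate, f a uniform background production, λ the
nutrient mass needed per unit area of matrix, σ the interfacial tension of
the cell layer (κ the front curvature, positive at convex ridges), and
V_max the intrinsic maximum secretion speed of the cells. All parameters
are dimensionless. The equations are discretised with P1 finite elements
(implicit Euler, lumped mass) and the front is tracked with an upwind
level-set scheme with geometric reinitialisation.

Two regimes emerge from the production level alone. At low f the front is
**diffusion-limited**: protruding ridges screen the valleys and the
ridge/valley thickness ratio grows steadily (the pattern recorded by
incremental lines in real enamel). At high f nutrients saturate the front's
secretion capacity and the matrix advances **uniformly**, reproducing the
geometric-extrapolation null model (morphological dilation of the EDJ by a
disk). Low σ produces a crenulated front; high σ smooths it.

## Worked example

The `demo` subcommand runs a seeded synthetic four-lobe cusp end-to-end:
a diffusion-limited simulation, thickness measurements at ridge/valley
landmarks, and the matched uniform-thickness extrapolation:

```
$ enamelsim demo --outdir demo_out
final enamel area 0.0209, perimeter 1.2810
mean thickness 0.0139; distance to uniform-thickness null: mean 0.0045, Hausdorff 0.0154
ridge/valley thickness ratio at end: 1.14
```

Here the simulated front already deviates from the dilation by a Hausdorff
distance comparable to the mean thickness itself, and the ridges are 14%
thicker than the valleys after only 160 steps — the diffusion-limited
divergence in its early phase. `demo_out/` contains the recorded fronts
(`fronts.csv`), per-landmark thickness series (`thickness.csv`), the
extrapolated contour, a rendered PNG of the final state, and a JSON
manifest that reproduces the run exactly.

Longer experiments use the library directly:

```python
import enamelsim as es
from enamelsim import reference as ref

edj = ref.reference_cusp()                       # synthetic 4-lobe EDJ
dl  = ref.run_to_mean_thickness(edj, ref.cusp_params(f=30.0))    # screened
ex  = ref.run_to_mean_thickness(edj, ref.cusp_params(f=160.0),
                                target=0.10)                      # uniform
```

Other subcommands: `simulate` (arbitrary XY contour files or synthetic
shapes), `extrapolate` (the null model), `stack` (per-slice runs combined
into an OBJ surface), `boxcount` (surface-complexity estimate), `shapes`
(emit synthetic EDJ contours).

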