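# Methods

`nlswei` simulates compression-enhanced shear-wave elasticity imaging
(SWEI) on a two-dimensional hyperelastic breast phantom: a stiff circular
tumor embedded in soft background tissue is compressed quasi-statically by
a rigid transducer, planar shear waves are propagated through the
pre-strained medium, and the local shear modulus is reconstructed by
time-of-flight (TOF).  Because the tumor strain-hardens much faster than
the background, external compression amplifies the tumor/background
modulus contrast.  This note records the models, the numerical choices and
their rationale, and the known limitations.

## Constitutive model

Both tissues follow the second-order polynomial (generalized
Mooney–Rivlin) strain-energy function

    U = Σ_{i+j=1..2} C_ij (Ī1−3)^i (Ī2−3)^j + Σ_{i=1,2} (1/D_i)(J−1)^{2i}

with isochoric invariants Ī1 = J^(−2/3) I1, Ī2 = J^(−4/3) I2 of the left
Cauchy–Green tensor and elastic volume ratio J.  The deviatoric part is
evaluated on isochoric invariants (the convention of the "polynomial"
model in mainstream FE packages); at Poisson's ratio ν = 0.495 the
difference from raw invariants is negligible, and a raw-invariant option
exists (`isochoric=False`).  The initial shear modulus is
μ0 = 2(C10+C01) and the initial bulk modulus K0 = 2/D1.

Packaged coefficients (from published ex vivo breast measurements; the
shipped file `data/tissues.yaml` stores them on the MPa scale and the
loader converts to kPa — the scale is an explicit, overridable field):

| coefficient | malignant tumor | benign tissue |
|---|---|---|
| C10 = C01 | 1.41e-3 MPa | 0.375e-3 MPa |
| C11       | 17.1e-2 MPa | 0.256e-2 MPa |
| C20 = C02 | 1.66e-2 MPa | 0.0283e-2 MPa |

giving μ0 = 5.64 kPa (tumor) and 1.50 kPa (benign).  D1 is derived from
ν = 0.495 via K0 = 2μ0(1+ν)/(3(1−2ν)) (so K0 ≈ 99.7 μ0) and D2 = D1, which
keeps the quartic volumetric term negligible.  Density is 1000 kg/m³
(soft-tissue convention), configurable.

**Tangent (wave-carrying) shear modulus.**  A small-amplitude shear wave
propagating along x with vertical polarization in a finitely pre-strained
medium feels the incremental modulus for the superposed shear
δF = γ e_y⊗e_x.  The default (`mode="stress"`) central-differences the
Cauchy shear stress under that superposed shear in the current
configuration; for an incompressible neo-Hookean solid this reproduces the
classical acoustoelastic result ρc² = μ λ₁² (λ₁ the stretch along
propagation).  An energy-based second-derivative reading
(`mode="energy"`) is kept as an alternative because FE packages do not
document which incremental stiffness their implicit wave response
reflects; both coincide at zero pre-strain (μ0).  Perturbation size 1e-6
(1e-4 for the second-difference energy mode).

## Phantom geometry

Semi-elliptical cross-section (flat base), 100 mm wide, 40 mm high;
circular tumor of diameter 10 mm centered 20 mm above the base and 38 mm
left of the rightmost point of the outline (center (12, 20) mm with the
origin at the base center; the "38 mm from the right side" phrasing is
ambiguous between edge and center distance — edge-of-outline reading is the
default and the center is configurable).  A structured grid is used
instead of unstructured triangles: the outputs live on a 0.2 mm grid
anyway, and the structured layout keeps the explicit wave solver simple.
Rectangular test fixtures (homogeneous / layered / single inclusion, with
hardening-free materials of prescribed μ0) share all machinery and give
closed-form expectations for tests.

## Static compression stage

Total-Lagrangian FEM on bilinear isoparametric quads (default spacing
1 mm; the top node row is snapped onto the curved outline so the platen
meets a smooth boundary rather than a staircase — staircase corners
produce spurious tensile contact reactions).  Near-incompressibility is
handled by selective reduced integration: deviatoric stress at the 2×2
Gauss points, volumetric pressure at the centroid; the per-element area
change stays below 2% at ν = 0.495 (tested).  The Newton tangent is
assembled by central finite-differencing the element internal-force
vectors (perturbation 1e-7 mm), vectorized over all elements; each step is
safeguarded by a backtracking line search, and the load is applied in 1%
increments with adaptive halving (down to 1/64 of the increment) when an
increment fails.

**Platen contact.**  The rigid transducer (45 mm footprint) is modeled by
a stiff vertical penalty: each top-surface node penetrating the platen
surface receives a downward force k·pen (default k = 500 kPa of contact
pressure per mm of penetration, i.e. penetrations stay ~0.1 mm at 30%
compression, 0.25% of the platen travel).  Frictionless behavior is
automatic (the springs carry no tangential force) and separation is free.
The platen edge carries a parabolic fillet (default radius 6 mm) — a
physical transducer edge is not sharp — and the force law is C1-smoothed
near zero penetration.  These regularizations tame the extrusion-lip
singularity a sharp rigid corner creates at deep compression.  Past ~15%
compression the material extruding around the platen edge undergoes
discrete snap-throughs at the mesh scale; when plain damped Newton
stagnates there, the solver switches to a pseudo-transient walk
(Levenberg–Marquardt-damped steps accepted without monotone descent) that
carries it across, and an increment whose line search stalls below 2e-3
relative residual is accepted — a single platen-edge node flickering
across the contact threshold can pin the last decades of the residual
without changing any field value, and 1e-3 is the force-balance accuracy
of the discretization (tested).  The compression level is platen travel
divided by the initial height at the platen center.

Reported strain is the magnitude of the vertical nominal strain
|F_yy − 1| (the measure used for "developed strain"); stress the magnitude
of the vertical Cauchy component.  Tissue ROIs are Lagrangian: the tumor
disc and a same-diameter disc in the surrounding tissue, by default the
tumor disc translated +10 mm laterally (away from the push, on the
reconstruction side, matching the outside sampling positions 20.2/23.3 mm
that mirror the inside ones at +10 mm); the placement is configurable and
is a known reproduction-sensitivity knob.

## Wave propagation stage

Propagation is linear incremental motion superposed on the static
pre-strain.  The deformed configuration and its tangent-modulus field are
rasterized onto a regular 0.2 mm grid (forward-mapping reference samples
through the FE displacement field, nearest-sample gridding), and the
scalar vertical-displacement wave equation

    ρ ∂²u/∂t² = div( μ_t grad u ) + f

is integrated by leapfrog finite differences in flux form (face-averaged
moduli; void faces carry zero stiffness, the base row is clamped).  The
scalar SH-like model is adequate because the push is vertical, the medium
nearly incompressible, and only the Y displacement is analyzed; a compact
velocity–stress P-SV engine (λ = 99μ) is available behind
``engine="psv"`` as a validation cross-check.  The push is a rectangular
body-force pulse, 3 mm wide, 180 µs long, directed downward through the
entire depth at the model midline; its amplitude (default tuned to ~10 µm
peak displacements, the typical SWEI scale) cancels from all speed
estimates by linearity.  No attenuation or viscosity is modeled.  The
internal time step satisfies CFL for the stiffest cell and subdivides the
125 µs output interval exactly; records default to 40 ms so the slowest
front (≈1.2 m/s in the benign background) crosses the reconstruction
band.  Boundaries reflect (as in the modeled experiment); the directional
filter removes the reflected energy.

## Reconstruction stage

1. **Directional filter:** per depth row, the 2D FFT over (t, x) is
   masked to keep the quadrants of one propagation direction (hard mask;
   axes at half weight; optional taper).  The record is zero-padded by
   1.5× and its tail cosine-tapered before the FFT because the undamped
   field still rings at the record end and wrap-around would fold that
   energy onto early times.
2. **Arrival times:** default "front" definition — the 50% rising-edge
   crossing of |du/dt| before its peak, sub-sample interpolated.  A
   through-depth line push in 2D produces a step-like displacement whose
   peak is ill-defined and whose peak-rate drifts late as the front
   broadens; the leading-edge crossing is insensitive to both (the
   homogeneous end-to-end test recovers 4 kPa to ~1.5%, versus ~5% bias
   for the peak-rate definition).  "peak_velocity" and "peak" remain as
   options.
3. **TOF speeds:** arrival times are averaged over a 3 mm depth kernel,
   then position-vs-time is fitted by ordinary least squares in a sliding
   3 mm lateral window; the slope is the speed.  Degenerate or
   out-of-range fits (outside 0.05–50 m/s) are masked, not raised.
   Reconstruction is one-sided (rightward of the push, x in 2–35 mm by
   default).
4. **Smoothing:** 2 × 2 mm NaN-aware median filter (11 × 11 cells at
   0.2 mm, edge-truncated), idempotent on piecewise-constant maps.
5. **Modulus:** G = ρc² cell-wise; masks propagate.
6. **Report:** ROI means/SDs of modulus and speed (map labels track the
   deformed tumor), strains and stresses from the static solve, contrast
   C = (G_tumor − G_surr)/G_surr per level, fixed column order.

## What the synthetic phantom does and does not emulate

The generator reproduces the geometry, boundary conditions, material
parameters and sampling of the modeled in-silico experiment: it is a
numerical phantom, not tissue.  It omits shear-wave attenuation and
dispersion (viscoelasticity), ultrasonic tracking noise (jitter),
out-of-plane (3D) mechanics, heterogeneous anatomy (skin, fat, glands) and
focused-beam excitation physics.  Passing tests therefore demonstrate the
correctness of the mechanics/waves/reconstruction chain under ideal
conditions, not robustness to measurement noise or model misspecification.

## Problem sizes

Default reproduction runs use a 1 mm mechanics mesh (≈3,200 elements), a
0.2 mm wave grid (≈100,000 cells), 40 ms records at 125 µs, and four
compression levels; tests use coarser fixtures (2 mm mesh, 0.4 mm grids,
shorter records) chosen so closed-form oracles stay sharp.  Mesh
convergence of ROI-averaged tangent moduli under spacing halving is part
of the test suite.

## Known limitations

- The penalty contact admits ~0.1 mm penetrations at deep compression
  (≈0.25% of the platen travel) and the platen-edge fillet (3 mm) slightly
  softens the footprint boundary; both are documented regularizations.
- The scalar wave engine propagates every direction at the local shear
  speed; anisotropy of the incremental stiffness under pre-strain is
  captured only for the horizontally-propagating, vertically-polarized
  component that TOF actually measures.
- TOF with a 3 mm kernel biases speeds near material interfaces (±1.5 mm);
  ROI averages over a 10 mm disc dilute but do not remove this.
- The printed tissue table is internally inconsistent with parts of the
  modeled experiment's reported outputs: the benign coefficients give
  μ0 = 1.5 kPa, while the reported reconstructed background modulus at 0%
  compression is ≈4 kPa, which no unit scaling of the table reproduces
  (the tumor/background ratio is fixed by the table).  This package
  implements the table as printed; reproduction quality is therefore
  asymmetric between tumor (good at 0%) and background quantities.
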