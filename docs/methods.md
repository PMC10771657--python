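# Methods

`dlmfem` simulates how the residual volume of a discoid lateral meniscus
(DLM) after partial meniscectomy changes tibiofemoral stress, on a fully
synthetic, parametric knee.  This note records the model, its assumptions,
the numerical choices, and what the synthetic study can and cannot say about
a real joint.

## The model in one paragraph

A parametric tibiofemoral joint in full extension carries a 1150 N axial
compressive load through two compartments: rigid femur and tibia, elastic
articular cartilage (isotropic, E = 15 MPa, ν = 0.3), a discoid lateral
meniscus covering the whole lateral plateau and a C-shaped medial meniscus
(both transversely isotropic: circumferential modulus 140 MPa, radial/axial
20 MPa), plus ligament fiber bundles (cruciates Neo-Hookean, ACL C1 = 5.08
MPa, PCL C1 = 6.06 MPa; collaterals and the patellar/quadriceps path linear,
E = 60 MPa, all tension-only).  The discoid meniscus is partitioned into
five concentric zones of 15/15/15/15/40 % of its volume (innermost first)
and split by an equal-volume plane perpendicular to the anterior–posterior
axis; removing whole inner zones per side generates the 15-model family
named `<ant>a<post>p` (e.g. `85a70p` = 85 % anterior, 70 % posterior
residual).  Each model is solved as a small-strain frictionless contact
problem and post-processed for the peak Tresca stress (stress intensity
σ₁ − σ₃, the shear readout) and the peak compressive stress (magnitude of
the minimum principal stress) in six regions: medial/lateral femoral
cartilage (MFC/LFC), menisci (MM/LM), tibial cartilage (MTC/LTC).

## Synthetic geometry

Coordinates: x = medial→lateral, y = posterior→anterior, z = up; origin at
the tibial plateau centroid; units mm, MPa, N.

* Each femoral condyle is a convex bi-radius (paraboloid) surface with
  sagittal radius 35 mm and frontal radius 22 mm; each tibial plateau
  compartment is an elliptic patch of 15 × 17.5 mm semi-axes, centered
  ±17 mm from the midline.
* Cartilage layers are extruded from these surfaces.  Cartilage thickness
  is 2 mm at the compartment center and **tapers 25 % toward the anterior
  edge** (thinner anteriorly).  The taper is the mechanism that concentrates
  contact pressure in the anterior horn region in extension — a stiffer
  anterior load column takes more pressure — matching where stance-phase
  lateral-meniscus contact peaks.  It replaces the uniform-thickness
  idealization because some anterior–posterior asymmetry is required for
  anterior- and posterior-sided resections to differ at all.
* The meniscus is a wedge-profiled disc, 4 mm high at the periphery
  tapering to 2 mm centrally, symmetric in y.  Its superior and inferior
  surfaces are constructed *conforming*: offset 0.02 mm from the femoral
  cartilage bottom and tibial cartilage top, with the tibial dish shape
  derived from condyle-minus-thickness.  The unloaded joint therefore has a
  uniform 0.02 mm gap everywhere — contact engages over the whole facing
  area, as it does in a meniscus-filled compartment.
* `discoid_coverage = 1.0` gives a solid disc (complete DLM); the medial
  meniscus is an annulus with inner radius half the outer (the C-shape
  idealization).
* Ligament attachment coordinates are idealized; each ligament is 3 fibers
  of 40/3 mm² with small patches added to the bone surfaces at the
  attachment points.
* The patella is omitted; the patellar/quadriceps path is a fiber anchored
  to a fixed virtual point.  No patellofemoral quantity is reported.

Everything is generated deterministically from `GeometryConfig`; the same
configuration reproduces bit-identical meshes.

## Meshing

All solids are meshed parametrically: structured elliptic-polar grids are
extruded between the analytic surfaces and each prism splits into three
tetrahedra (TET4/C3D4).  Diagonals follow a lowest-coordinate-rank rule,
which is conforming and **mirror-equivariant**: geometries reflected in the
anterior–posterior axis mesh into exactly reflected elements.  That matters
because the study compares mirror-image resection pairs (85a70p vs 70a85p);
with an index-based diagonal rule the pair differences were dominated by
triangulation noise at the resection junction rather than by physics.

Default resolution: ~1.5 mm in-plane, two elements through each layer
(≈60 k elements, ≈31 k unknowns per model).  This is the study's working
resolution; the 1.0 mm reference element size is one parameter away
(`MeshSizes(in_plane=1.0)`) at roughly 10× the runtime.

## Resection family

Ring boundaries are found by bisection on realized mesh volumes, so the
five zones hit 15/15/15/15/40 % exactly at mesh level; the equal-volume
split plane is found by bisection with exact tet-plane clipping (for the
symmetric default it falls on the symmetry plane).  `resect` removes inner
zones innermost-first and refines each side's cut radius by bisection so
the residual per side matches the named fraction; between the two side
radii the cut wall follows the split plane.  Models with unequal sides are
smoothed: the inner-margin radius blends over a 3 mm C1 smoothstep band
around each junction, with the blend centers slid along the rim (bisection)
to keep the resected volume — realized residual fractions land within
0.15 % of (a+p)/2, well inside the 1.5 % bookkeeping tolerance.

The peripheral 40 % rim is never fully removed; the worst case (40a40p)
keeps a rim of ≈3 mm radial width.

## Materials

Voigt order (11, 22, 33, 23, 13, 12), engineering shears.

| Tissue | Model | Parameters |
|---|---|---|
| bone | rigid | — |
| articular cartilage | isotropic | E = 15 MPa, ν = 0.3 |
| meniscus | transversely isotropic | E_circ = 140, E_radial = E_axial = 20 MPa, ν_in-plane = 0.2, ν_out-of-plane = 0.3 |
| ACL / PCL | Neo-Hookean fibers | C1 = 5.08 / 6.06 MPa, D1 = 0.00683 / 0.0041 MPa⁻¹ |
| MCL, LCL, patellar | linear fibers | E = 60 MPa, ν = 0.3 |

The meniscus shear moduli are not independently specified by the sources
the parameter set follows: the in-plane shear modulus is fixed by isotropy
of the radial–axial plane (E/(2(1+ν)) = 8.33 MPa) and the out-of-plane
(fiber) shear modulus defaults to 57.7 MPa, a conventional value in
meniscus finite-element work; both are configuration parameters.  The
circumferential direction of each element comes from the level-set tangent
of the in-plane distance to the outer margin (azimuthal fallback at the
disc center); the local stiffness tensor is rotated into that frame.

Cruciate ligaments are fiber bundles with the incompressible uniaxial
Neo-Hookean response σ = 2C1(λ² − λ⁻¹), tension-only; the full
compressible energy W = C1(Ī₁ − 3) + (1/D1)(J − 1)² is implemented at the
material-point API so D1 is housed and testable, but the volumetric term
does not enter the uniaxial fiber idealization.

## Boundary conditions, contact, solver

* Tibia fixed (tibial cartilage bottom nodes).  Femur rigid with exactly
  three free DOFs — medial–lateral translation, axial translation, and
  varus/valgus rotation — loaded by 1150 N along −z; flexion,
  anterior–posterior translation and internal–external rotation are fixed.
  Femoral cartilage top nodes are rigidly bonded to the femur (linearized
  rigid map, eliminated by a transformation matrix).
* Each meniscus is anchored at the outer-rim ring of its inferior surface
  by compliant ground springs, 5000 N/mm total per meniscus (the scale of
  published meniscal horn-attachment stiffnesses, ≈2000 N/mm per horn, plus
  capsule).  A rigid clamp instead puts the reported stress peak at the
  fixation boundary — a Dirichlet artifact.
* Contact: frictionless node-to-surface penalty, pairing fixed at
  initialization (limited sliding).  Six pair sets per knee: femoral
  cartilage ↔ meniscus, femoral ↔ tibial cartilage, meniscus ↔ tibial
  cartilage, per compartment.  Penalty 50·E/h (E = 15 MPa cartilage,
  h = element size); automatic ×10 escalation (up to 3×) if the 0.02 mm
  penetration limit is violated — never triggered at default settings
  (max penetration ≈0.008 mm).
* Small-strain bulk kinematics (cartilage strains are a few percent under
  stance load); finite stretch for ligament fibers.  The only
  nonlinearities are the contact active set and tension-only fibers, so the
  response is nearly linear: 1-, 2- and 5-increment load ramps converge to
  identical peak tables.  The default study uses a 2-increment ramp with
  Newton iterations to a relative residual of 1e-6 and a 0.5 mm step cap
  (which keeps rigid bodies from overshooting first contact).
* Linear algebra: the reduced tangent is symmetric positive definite; it is
  factorized by sparse LU in symmetric mode with diagonal pivoting and the
  factorization is cached across Newton iterations as a CG preconditioner,
  refactoring only when CG stalls.  Assembly ordering is fixed; repeated
  runs are bit-identical.
* A tiny stabilization spring (1e-3 N/mm) on rigid-body DOFs regularizes
  the first iteration before contact engages; its force at equilibrium is
  microscopic (< 1e-3 N).

Global equilibrium (|applied − tibial reaction| / applied) closes to ~1e-6
in every converged run, against the 0.5 % requirement.

## Stress post-processing

Element-constant stresses (σ = C·B·u per TET4), no nodal averaging.
"Tresca" is the stress intensity σ₁ − σ₃ (twice the maximum shear stress);
"compressive stress" is max(0, −σ₃).  Per-region peaks are maxima over
elements with a lowest-element-id tie-break.  Both conventions follow the
commercial-solver outputs that knee FE studies usually report.

## Verification

* Patch test: constant-strain field reproduced to ~1e-15 (requirement 1e-8).
* Single TET4 stiffness vs a hand-assembled closed-form oracle: ≤1e-10.
* Principal/Tresca values vs characteristic-polynomial root-finding on 1000
  random tensors: ≤1e-10.
* Transversely isotropic tensor rotation vs brute-force 4th-order rotation;
  isotropic degeneration ≤1e-9.
* Rigid plate on a block: uniaxial strain p/E to <1e-5.
* Rigid sphere (R = 20 mm, F = 100 N) on an E = 15 MPa, ν = 0.3 block:
  peak contact pressure within 4.1 % of the Hertz closed form
  p₀ = (6FE*²/π³R²)^(1/3) (requirement 5 %), on a contact-zone mesh of
  0.75 mm in plane with a 0.5 mm first surface layer.  The peak is
  estimated by linear regression of p² on r² over the active nodes (the
  exact linearization of the Hertz profile), which filters the apex
  overshoot of the raw nodal maximum — a penalty-method artifact on linear
  tets that does not converge away under refinement; the fitted contact
  radius (4.45 mm vs 4.50 mm analytic) confirms the field is Hertzian.

## What the synthetic study shows — and what it does not

On the default study the large, robust effects reproduce the qualitative
findings: LM peak shear rises monotonically along the equal-ratio series
100→85→70→55→40 % (3.32 → 8.94 MPa, +169 %), with the 55→40 % step the
largest single increment; LM peak compressive stress rises +175 %; LFC
peaks rise several-fold; models whose posterior half is cut to 40 %
(70a40p, 55a40p, 40a40p) exceed their 55 %-posterior counterparts in both
LM readouts; the medial compartment barely changes.  These trends are
stable between the 1.5 and 2.0 mm resolutions.

The *pair* comparison (same total volume, unequal anterior/posterior
split) is not robust in this geometry.  Mirror pairs differ only through
the anterior cartilage taper (the meshes are exact mirrors otherwise), and
the resulting LM-peak differences are small (≈2–4 %) with a sign that
depends on mesh resolution: at 2.0 mm the anterior-preserving member is
lower in all four groups A–D; at the 1.5 mm default it is lower only in
group B.  Mechanistically, the taper concentrates pressure on *preserved*
anterior tissue, so keeping more anterior tissue can slightly raise the LM
peak at its junction — whereas in the patient-specific geometry the damage
localizes at the *resected margin* of the high-pressure region, which is
the mechanism that makes anterior preservation protective.  A synthetic
bi-paraboloid joint with a uniform-gap contact cannot discriminate between
these two mechanisms at this effect size; treat the pair-series output as
descriptive, not confirmatory.

Other limitations: one static stance pose (full extension) only; no
friction, finite sliding, or poroelasticity; ligaments as a few discrete
fibers; absolute stress values depend on the idealized geometry and are
only order-of-magnitude comparable with patient-specific reports (the
report-only literature table flags anything outside [0.5×min, 2×max] of
three published studies).

## Problem sizes and runtime

Default study: 15 models × ≈31 k unknowns, ≈7 s per model after a ≈30 s
partition/family build; the full study runs in ≈2.5 minutes on one CPU.
The Hertz benchmark adds ≈30 s.
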