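# Methods

`tibfrac` simulates the postoperative mechanics of a split-depression
(Schatzker II) tibial plateau fracture stabilized with a medio-lateral
cancellous screw, with or without PMMA cement augmentation, at three bone
healing states, under the peak load of gait.  This note records the model,
its assumptions, the phantom design, the numerical choices, and what the
tests do and do not establish.

## The synthetic phantom

No patient image ships with the package; the pipeline's input is a
parametric voxel phantom (`tibfrac.phantom`) that emulates what a segmented
postoperative CT provides:

* a **labeled image** with regions for the diaphysis, the proximal plateau,
  the depressed articular fragment, the separated lateral wedge, the screw,
  the optional cement, and (for the short screw) the bone occupying the
  unused part of the screw track;
* a co-registered **density image** in arbitrary scanner units, related to
  g/cm3 through a hidden affine map so that the calibration stage is
  genuinely exercised;
* spherical **calibration inserts** of known density (0.0-1.6 g/cm3),
  emulating a CT density phantom scanned with the same protocol.

Geometry is idealized: the proximal tibia is a capped elliptical cylinder
(default 70 mm wide medio-laterally — it must host the 70 mm bi-cortical
screw — and 30 mm deep anteroposteriorly) on a 28 mm metaphyseal flare and a
short distal shaft.  The depressed fragment is a block under the articular
surface with the nominal 1.78 mm residual gap beneath it (its basal
apposition surface, which is also the minimum fragment-parent distance);
around its medial and AP faces the impaction defect is wider (5 mm), as
around a fragment raised by balloon reduction.  The separated wedge is
offset by the 3.5 mm split gap and cleared from the bone below by an
evacuation void slightly larger than the split gap.  The screw (diameter 6.5 mm) runs medio-laterally under the depressed
fragment, grazing its inferior surface; the 70 mm variant anchors the far
(lateral) cortex, the 50 mm variant ends inside the wedge and the remaining
20 mm of the track is trabecular bone at 0.94 g/cm3, the most frequent
plateau density reported for the clinical case.  Cement, when present, is a
sleeve around the screw (outer radius 10.5 mm) filling the void between
screw and fragment and bonding both.

The three healing states: *mobile* and *bonded* share one geometry (only
the interface condition differs); *fused* merges the fragments into the
plateau and fills the gaps with trabecular-density bone.

Phantom parameters that carry the study conditions are fixed at the stated
values: gaps 1.78/3.5 mm, screw 6.5 x 70/40 or 50/20 mm (length/thread),
body mass 80 kg, load 2.59 x body weight split 37/63% lateral/medial over
403/374 mm2 condylar patches.  Parameters the study does not state are
design choices, the two that matter most being:

* **Trabecular interior density, 0.40 g/cm3.**  The phantom's interior is
  drawn as a *uniform* field plus noise, unlike real metaphyseal bone whose
  density spans roughly 0.1-1.0 g/cm3 with dense subchondral regions.  A
  uniform field at the reported histogram mode (0.94) would make the
  idealized phantom much stiffer and stronger than the heterogeneous
  original everywhere at once; 0.40 g/cm3, a typical metaphyseal-core
  value, keeps the phantom in the mechanical regime the study describes —
  cement augmentation spreads the fragment load safely below trabecular
  strength while a bare screw's line bearing locally exceeds it.
* **Anteroposterior half-depth, 15/35 of the half-width.**  Chosen so the
  screw axis lies on a plane of the default 3 mm mesh lattice; an
  off-lattice axis meshes into an asymmetric screw cross-section that gives
  the wedge a spurious anteroposterior tilt mode.

A Gaussian noise field (sd 0.02 g/cm3) is applied in density units before
mapping to raw units; all randomness derives from a single seed and a fixed
seed reproduces the phantom byte for byte.

## Calibration and material mapping

Insert ROI means are regressed against known densities by ordinary least
squares (a linear response is the standard assumption for this phantom
class) and the fitted affine map is applied voxelwise, clamping negative
densities at zero.  Element density is the mean over bone-labeled voxels
whose centers fall inside the element (hardware sentinels and air are
excluded, otherwise partial-volume bleeding softens every boundary
element), with trilinear interpolation at the centroid as the fallback for
elements smaller than a voxel, and a floor of 0.01 g/cm3 for solver
conditioning.

Material laws (N-mm-MPa units): cortical bone E = 3890 rho^2.39 with yield
141.6 MPa; trabecular bone E = 6570 rho^1.37 with log10(yield) = 1.38 +
1.91 log10(rho); nu = 0.3 for bone.  The classification threshold 1.68
g/cm3 is the intersection of the two modulus laws (the package recomputes
it to ~1.6797).  The yield law's logarithm is base 10: at rho = 1 it gives
~24 MPa, a physiologic trabecular strength, where a natural log would give
~4 MPa.  Titanium (E 110 GPa, yield 930 MPa) and PMMA (E 2163 MPa, nu
0.375, yield 93 MPa) are label-driven constants.

## Meshing

The mesher fills the image with a uniform cube lattice (default edge 3 mm),
splits each cube into six Kuhn tetrahedra, labels each tetrahedron from the
voxel under its centroid, and promotes kept elements to straight-sided
TET10.  Two accuracy guards matter at desk scale:

* a bone tetrahedron whose corners reach into an interfragmentary gap (or
  into the first exterior voxels where a gap meets the cortex) is dropped,
  so fracture surfaces retreat to lattice planes instead of grazing the
  opposing side;
* lattice vertices shared between a fragment and the parent bone are
  duplicated, so the two surfaces are topologically disconnected while
  hardware (screw, cement, screw-void bone) keeps shared nodes — the
  "contacts including screw or cement are bonded" rule.

Interface pairs project each fragment surface node onto the nearest
admissible parent facet (a facet is admissible when its normal opposes the
node's outward surface normal, which prevents coplanar side walls from
capturing pairings); pairs beyond twice the nominal gap are discarded.
Mesh-level gaps are the nominal gaps rounded up to the lattice pitch, so at
the default element size the median depressed-interface gap is ~3 mm for a
nominal 1.78 mm; strains computed against per-pair gaps inherit that scale.

The default element size of 3 mm (against the original workflow's 0.64 mm)
and the phantom's overall size are the package's problem-size choice for a
single-CPU desk run; a convergence harness (element count ~8x per uniform
refinement, displacement stability on refinement) is exercised in the test
suite on reduced problems.

## Solver

Standard TET10 small-strain elasticity, 4-point Gauss quadrature (exact for
straight-sided elements), assembled into a symmetric sparse operator and
factorized with SuperLU under COLAMD ordering.  Distal support nodes are
fully fixed.  Patch loads are applied as uniform pressure through
consistent TRI6 nodal forces; the facet set is accumulated by distance from
the patch center until the nominal area (403/374 mm2) is reached, and the
pressure uses the achieved area so the applied force equals the prescribed
2.59 x body-weight share exactly.

Interfaces:

* **bonded** — pairs tied in all three directions by penalty springs
  between nearest nodes (node-to-facet ties roughly double the
  factorization fill for no accuracy gain on matched lattice surfaces).
  Tie stiffness defaults to *callus scale* — the contact penalty divided by
  1000, about the stiffness of a tissue layer bridging the gap — and is
  weighted by each pair's tributary surface area.  Rigid ties would act as
  struts much stiffer than the bone itself and concentrate the interface
  transfer into the fragment's edge columns, manufacturing yield volume
  where a glued continuum interface shows none.
* **frictionless** — node-to-surface, normal-only, compression-only penalty
  contact with an active-set loop: pairs start active only where surfaces
  touch, pairs penetrating beyond tolerance (1e-3 mm) are activated,
  tensile pairs released, until the set is a fixed point (oscillation and
  iteration caps raise errors).  Because the active sets are small in the
  small-displacement regime (total displacements are orders of magnitude
  below the gap sizes), each iteration reuses the base factorization
  through a Woodbury low-rank update, falling back to a direct
  factorization when the base operator alone cannot support a body.

Pairing in the scenario pipeline is restricted to apposition surfaces: the
basal interface under the depressed fragment (its lateral/AP surroundings
are a wider impaction defect by phantom design) and the split face of the
wedge (cutoff 1.3x the nominal gap, which excludes the evacuation void
under the wedge).  The contact penalty default is 100 x (mean interface
modulus x tributary area / element size).  The contract checks:
equilibrium residual < 1e-6, active pairs compressive, inactive pairs
within penetration tolerance, and penalty insensitivity (10x stiffness
changes peak displacement < 1%).

Element stresses are volume-averaged (centroid evaluation), a deliberate
choice for the yield-volume metric: nodal extrapolation overshoots at the
screw-bone corners and would make the yield volume a mesh artifact.

## Outcome metrics and verdict

Per scenario: maximum von Mises stress per material; yield volume (bone
elements whose stress exceeds their local, density-dependent strength;
hardware excluded); reduction loss (distal-proximal displacement of the
depressed fragment; medial-lateral opening of the wedge relative to its
paired parent points); interfragmentary strain (magnitude of the 3-D
relative displacement per pair over its initial gap, maximum per fragment —
the resultant rather than the normal component, since interfragmentary
movement in the healing literature includes shear); and hardware stress as
a fraction of material yield.  A scenario is *stable* when the yield volume
is zero and every interfragmentary strain is below 10%, the cited threshold
for secondary healing.  Fused scenarios have no interfaces and report no
strain entries.

## What the phantom does and does not establish

The twelve-scenario matrix reproduces the study's *directional* findings on
the phantom: cemented mobile scenarios show zero yield volume while
uncemented mobile scenarios yield near the screw; cement lowers mobile
interfragmentary strains; and bonded strains are far below mobile strains.
The bi- versus uni-cortical difference in wedge opening measures a few
hundredths of a millimetre — small against the ~0.3 mm peak displacement,
though above the 0.02 mm negligibility threshold fixed at design time, so
the reporter flags that check rather than calling it negligible.  The
bonded interface band sits close to the yield boundary: a single marginal
element (a few mm3) can cross it depending on the noise seed, which is why
an uncemented-bonded scenario occasionally reports a small nonzero yield
volume where the original study printed zero.  The
patient-specific magnitudes (strain percentages, yield volumes in mm3, peak
stresses) are *not* reproducible from an idealized phantom at desk
resolution and are not claimed; the phantom's values live on the same order
of magnitude but differ numerically.  Features of real data the phantom
does not emulate: heterogeneous trabecular density fields, real fragment
shapes and interdigitating fracture surfaces, screw threads, the fibula
(omitted entirely — the load path of interest runs through the
fracture/hardware region), soft tissue, and dynamic loading.

## Degenerate inputs and tie-breaks

Zero-gap pairs (coincident split nodes at grazing corners) are excluded
from strain denominators with a warning and may participate in contact;
empty labels, empty insert ROIs, fewer than two distinct insert densities,
re-calibration of an already calibrated image, unknown region labels,
unconstrained systems, and contact oscillation all raise errors rather than
degrade silently.  Patch-area mismatches beyond 15% of nominal warn but do
not stop the run.
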