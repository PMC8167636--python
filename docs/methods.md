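# Methods

## Problem and model

Nocturnal bruxism loads the mandibular dentition far beyond normal chewing.
A removable occlusal splint is meant to lower the total bite force (by
breaking the myotatic reflex) and to spread what remains evenly over the
arch. This package models that mechanism as a chain of three linear-elastic
static analyses driven by clinically measured force distributions:

* **Option 1** — no splint. Each tooth carries its own measured occlusal
  force on its crown top. With the outer PDL surface fixed and no contact
  between teeth, the arch decomposes into fourteen independent
  substructures; this decoupling is asserted in the tests.
* **Option 2** — splint as manufactured. The (smaller) measured total acts
  on the splint's occlusal surface and flows to the teeth through bonded
  splint–crown interfaces.
* **Option 3** — splint after corrective grinding. Identical mechanics to
  option 2 with the post-correction measurement. Grinding is represented
  *only* by the changed measurement — the splint geometry is not altered,
  because the measured redistribution is the quantity of interest and the
  local geometry changes are not observable from the available data.

All materials are isotropic homogeneous linear elastic (tooth
E = 20 300 MPa, ν = 0.26; PDL E = 68.9 MPa, ν = 0.45; PMMA splint
E = 2200 MPa, ν = 0.35). Geometry is in mm, forces in N, moduli in MPa; the
mm–N–MPa system is consistent (1 N/mm² = 1 MPa), so handbook constants are
used verbatim.

## Force calibration

The T-Scan sensor yields a dimensionless raw sum and integer per-tooth
percentage shares. Calibration is linear: F = 0.021·raw + 8.022 (N). Design
choices that matter for reproducing clinical tables:

* Internal arithmetic is never rounded; one-decimal **half-up** rounding is
  applied only at report emission. Per-tooth forces are share/100 of the
  *unrounded* total — this reproduces every per-tooth Newton value of the
  packaged measurements, which rounding the total first would not.
* Shares are used as recorded, with no renormalisation when the printed
  integers do not sum to exactly 100 (validation accepts 95–105 %).
* Side/group shares can be formed either from the exact distribution or
  from the one-decimal reported forces; the two differ by up to ~0.1
  percentage point (e.g. a 50.0 % vs 50.1 % left-side split) and both
  routes are exposed.

## Synthetic dentition

The generator replaces an unavailable patient CT with a deterministic
parametric arch; every quantity below is a `DentitionSpec` field.

* **Teeth.** Axisymmetric solids: cylindrical crown (radius 0.55–0.95 mm,
  height 1.6–1.9 mm by tooth class) over a tapered root frustum (length
  2.4–3.0 mm, cervical radius 0.85× crown, tip 0.25×). Fourteen teeth are
  placed along a parabolic arch (sagittal depth 0.55× half-span) with
  0.40 mm crown clearance, positioned by arc-length so spacing is uniform
  in the curve metric. The arch is a miniature — about one-fifth anatomical
  scale — chosen so the default mesh lands in the tens-of-thousands-of-
  elements range that one CPU solves in seconds; because conclusions are
  property-based (decoupling, redistribution, equilibrium, stress-peak
  location), anatomical fidelity is deliberately not a goal. Crowns are
  cylindrical because a tapered crown rasterized on a background grid grows
  staircase notches whose artificial stress concentrations mask the
  physical peak at the root.
* **PDL.** An equidistant shell of thickness 0.25 mm around the *root*
  surface only (lateral frustum + apex cap, exact point-to-surface distance
  in the axisymmetric plane). Construction fails loudly if the shell would
  reach a neighbouring tooth.
* **Splint.** A band following the arch polyline (half-width = largest
  crown radius + thickness, default thickness 0.40 mm) from mid-crown
  height to crown top + thickness, with the teeth subtracted — its inner
  surface therefore coincides with the crown surfaces (zero gap), and
  meshing verifies it is one connected component.
* **Phantom.** The arch rasterizes to a 0.20 mm voxel grid: tooth interior
  ~N(2900, 50) HU clipped to [2600, 3000]; a bone slab fills the root
  region outside teeth and PDL, drawn uniformly from 200–900 HU (the lower
  part of the 150–1800 HU bone band, so that the raised 1000 HU threshold
  alone isolates the teeth — the interactive mask editing a real scan needs
  is not emulated); everything else is soft tissue below 150 HU. Given a
  seed the phantom is bit-reproducible. Segmentation thresholds to
  [1000, 3000] HU and labels 26-connected components.

What the phantom does **not** emulate: partial-volume blur, beam hardening,
metal artifacts, cortical bone overlapping the tooth window, anatomical
root curvature and crowding. Passing segmentation tests therefore show the
thresholding/labelling machinery is correct, not that real CTs segment this
cleanly.

## Meshing

All regions are meshed on one regular background grid: a grid cube whose
centre lies inside a solid is kept with that region label and split into
the six-tetrahedron Kuhn pattern (all six tets share the cube diagonal, so
translated copies tile space conformally and every tet has positive volume
by construction). Consequences:

* Meshes of adjacent regions are node-conforming at interfaces, so bonded
  contact is node sharing — no constraint equations in the default path.
* The default cell size equals the PDL thickness (0.25 mm). A band of
  width t ≥ h crossing any grid column must contain at least one cell
  centre, so the one-cell-thick ligament layer is captured everywhere and
  every tooth is verifiably attached to its shell (meshing raises
  otherwise).
* A per-region maximum-edge request maps to cell = min(edge)/√3 (the
  longest Kuhn edge is the cube body diagonal); one shared grid means the
  finest region governs.

Node sets are extracted from mesh topology: `occlusal_<FDI>` /
`occlusal_splint` are the upward faces (outward normal within 30° of +z) on
the topmost layer of the *region* surface, so a crown top stays occlusal
even under the splint; `pdl_outer` is the exterior surface of the shells;
`crown_outer_<FDI>` / `splint_inner` are the shared tooth–splint interface
nodes.

## Solver

Standard CST tet4: K_e = V·BᵀDB with element-constant B; sparse global
assembly; Dirichlet (zero or prescribed) and tied-pair constraints
eliminated through a reduction operator T, the reduced system solved by
sparse LU with a Jacobi-preconditioned CG fallback (target relative
residual 1e-10; the solve raises above 1e-8). Reactions are recovered as
Ku − f on constrained DOF and must balance the applied load to 1e-6
relative (asserted on every scenario). Verification: symbolic element
matrix, rigid-body modes, patch test to 1e-8, axial bar to δ = FL/EA within
1e-6, monotone cantilever convergence toward Euler–Bernoulli, and
displacement agreement to 1e-9 with an independent dense solver on small
meshes.

Loads: the measured total acts as a **uniform occlusal pressure**, i.e.
consistent (area-weighted) nodal forces on the occlusal face set. An
exactly even per-node split (also provided, as `apply_occlusal_load`)
over-weights rim nodes relative to their tributary area and pins the
stress maximum to artificial spikes under the load points; the consistent
form is the FE-faithful realization of the same evenly distributed load
and lets the physical stress concentration — at the root attachment, where
fixation begins — emerge, which it does for all fourteen teeth in option 1.
The load direction is vertical (−z) by default and configurable, should an
oblique muscle-action line be of interest.

## Post-processing and safety

"Maximum displacement" is the max over a region's nodes of ‖u‖; "maximum
stress" is the max over its elements of the element-constant von Mises
value with **no nodal averaging** (averaging changes maxima, so the
convention is pinned here). Each stress peak is classified by node-set
membership of its element: `root_attachment` (touches the tooth–PDL
interface), `crown_contact` (touches the splint interface), else `body`.
Between-option comparisons are per-region ratios; a zero denominator yields
NaN rather than an exception.

Safety thresholds: tooth mobility 0.03 mm; dentin checked against the
conservative lower tensile bound 44.40 MPa (the published range runs to
97.80 MPa tensile / 297.20 MPa compressive; both configurable); PDL limits
by tooth class — incisors 1.50, canines 1.60, premolars 1.40, molars
1.20 MPa (lower ends of the published bands); PMMA static fracture
32.00 MPa. Verdicts use strict inequality: observed equal to the limit is
reported unsafe with margin 1.0. Fatigue life of the splint is out of
scope (only the static PMMA check is made).

Because the arch is miniature, absolute stress and displacement magnitudes
are not patient statements; they are the quantities the property suite
reasons about. At the default scale and measured loads all safety checks
happen to pass, reproducing the qualitative clinical conclusion, but the
meaningful outputs are the mechanism results: decoupling without the
splint, redistribution with it, the 1.5× total-force drop, and stress
peaks at the root attachment.

## Numerical choices and degenerate inputs

* Half-up decimal rounding via `decimal` on the shortest float repr, so
  binary artifacts cannot flip a tie.
* Meshing raises on: empty regions, disconnected splint, a tooth not
  attached to its PDL shell, non-positive tet volume.
* The solver raises with an explicit message when no node is constrained
  (singular system) and on degenerate (zero/negative-volume) tets.
* Zero applied load is legal and yields identically zero fields; a zero
  denominator in ratios yields NaN.
* Determinism: geometry and meshing are pure functions of the spec; the
  only randomness (phantom noise) is seeded.

## Problem sizes

Default runs use: 14-tooth arch at 0.25 mm cells — about 38 000 elements
without the splint and 75 000 with it (solved in seconds by sparse LU);
phantom at 0.25 mm voxels (~10⁶ voxels); solver benchmarks on boxes of
24–30 000 elements. Three-tooth toy arches back the fast unit tests.
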