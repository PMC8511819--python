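# Methods

This note documents the models, parameters and numerical choices behind
`fracenv`, and what the synthetic phantom can and cannot say about real
patient data.

## The phantom and what it emulates

The phantom is an axis-aligned idealization of a nailed, fractured tibial
shaft in a calibrated CT scan.  It emulates the features every downstream
stage depends on — cortical/trabecular density contrast, a metal implant,
a soft fracture gap, and a six-rod density-calibration ladder following a
linear HU–density law with additive Gaussian noise — and deliberately omits
realistic anatomy (curved shaft, varying cross-section), imaging physics
(beam hardening, metal artifacts, partial-volume blur beyond rasterization),
and soft-tissue background structure.  Passing tests on the phantom
therefore demonstrate that the *chain* is correct (calibration recovers the
imposed law, segmentation recovers the imposed labels, the FE solve matches
closed forms); they do not certify segmentation quality on clinical CT,
where thresholds and morphology radii must be re-tuned per protocol.

Default geometry (all configurable, mm): 50 × 40 × 80 mm volume at
1.25 × 1.25 × 2.5 mm spacing; cortical outer/inner radius 11.5 / 8.5,
medullary canal radius 6.5; nail diameter 9 (or 8 for the failed-treatment
scenario) ending 5 mm short of each volume face; four 4 mm transverse
locking screws at z = 15, 25, 60, 70 mm; a 3 mm transverse fracture gap at
mid-shaft.  Densities: cortical 0.9, trabecular 0.25 g/cm³
(hydroxyapatite-equivalent); rod ladder 0.0–0.8 g/cm³; HU law
1000 HU/(g/cm³) with zero intercept and 5 HU noise; metal fixed at 3000 HU,
gap tissue at 20 HU (noise-free constants, so the implant/gap thresholds are
exercised, not the noise model).

Two geometric choices are load-bearing:

* **Nail–canal clearance.** The nail radius is at least one voxel smaller
  than the canal radius, and the marrow annulus between them is not meshed.
  The nail therefore connects to bone *only through its locking screws*,
  which is what gives the construct a finite axial/bending compliance and a
  clinically meaningful interfragmentary movement.  Had the nail been
  voxel-bonded to the canal wall, the construct would be orders of magnitude
  too stiff and the gap stimulus degenerate.
* **Gap definition.** The fracture gap is the slab ∩ (canal ≤ r ≤ cortical
  outer) — the region where bone used to be.  The canal portion of the slab
  remains (unmeshed) marrow, so gap tissue connects fragment to fragment but
  not to the nail surface.

Rasterization: a voxel belongs to a region iff its center does; overlaps
resolve implant > gap > bone > rod > background.  One seeded generator
drives all noise; the seed is recorded in the ground truth and every report.

## Calibration

Density is regressed on the per-rod **median** HU (ordinary least squares).
The median was chosen over the mean because rod-rim voxels suffer
partial-volume averaging in real scans; on the phantom both agree.  Rod
statistics use the sample (n−1) SD convention.  R² is reported and a warning
is logged below 0.99, but the fit is never gated on it.  Calibrated
densities are clamped at zero before the ash-density map, since ash density
must be non-negative.

## Segmentation

The bone threshold is stated in calibrated density units (default
0.15 g/cm³) and converted to HU per scan through the calibration model, so
the same parameter file works across scanner calibrations; the implant
threshold (2000 HU) sits far above any tissue.  The calibration-rod region
is excluded from the tissue masks (rod positions/labels are an input, as in
calibration).  Morphological structuring elements are Euclidean balls in
voxel units; connected components use 26-connectivity; closing is computed
on a padded grid so volume borders neither clip the dilation nor inflate
the erosion.

The default close radius is 0: at the default anisotropic spacing the
smallest nonzero ball already spans 2.5 mm axially and would seal the 3 mm
fracture gap itself.  Users with finer or isotropic scans should set it per
protocol; the operation is fully implemented and tested.

The fracture-gap mask is derived in two deterministic steps (replacing any
manual correction): (1) *locate* — the morphological close of the bone mask
with a radius spanning the gap, minus bone and implant, largest connected
component; (2) *fill between fragments* — within that component's axial
band, every non-bone/non-implant voxel whose axial column contains bone both
below and above is gap.  Step 2 exists because a closing cannot reach the
gap mouth at the cortical surface (the closing ball leaves a fillet there);
with it, the chain reproduces the phantom's ground-truth masks exactly
(Dice 1.0 per mask, transverse and 15°-oblique gaps, with and without
noise), comfortably above the 0.99/0.95 floors asserted in the tests.

## Meshing and materials

Each foreground voxel splits into six tetrahedra around the voxel's main
diagonal (Kuhn subdivision).  Using the same corner ordering everywhere
makes shared-face diagonals agree between neighbors, so the mesh is globally
conforming, and the subdivision is volume-exact (asserted).  TET10 elements
add midside nodes at straight-edge midpoints; geometry stays affine.

Materials are sampled once per element at the voxel containing its centroid
("one value per element").  The cortical/trabecular branch is selected by an
ash-density threshold, default 0.6 g/cm³.  Conveniently, the cortical power
law and the trabecular affine law cross almost exactly there
(3653.3 vs 3653.2 MPa), so the default mapping is continuous to within
0.1 MPa; with any other threshold the jump between the two published laws is
real and is not blended away — it is asserted, documented behavior.

## Finite elements

Consistent units mm / N / MPa.  TET4 uses the 1-point rule, TET10 the
4-point Gauss rule; both are exact for affine elements.  Strain/stress are
integration-point averages per element, in Voigt order (xx, yy, zz, xy, yz,
zx) with engineering shears.  Dirichlet conditions (optionally
inhomogeneous, for patch tests) are applied by reduction.  The direct sparse
factorization handles up to 2·10⁵ free unknowns; beyond that a
Jacobi-preconditioned CG with relative tolerance 1e-8 takes over.  Every
solve verifies the relative residual and global equilibrium (reaction sum
balancing the applied load to 1e-6 relative, scaled by total reaction
magnitude when no external force is applied).

Verification: a TET10 bar under work-consistent uniform end traction
reproduces u = FL/EA to ~1e-12 relative; TET4/TET10 patch tests reproduce
uniform-strain fields to machine precision; against a non-polynomial
analytic displacement field (quadratic fields are nodally exact on this
lattice), TET4 converges at observed order ≈ 1.8–1.9 in the max norm.
Equal nodal-force load distribution (the default for the blunt proximal
face load) is also available as `distribution="consistent"` with
tributary-area weights when exactness matters.

## Load case

The default load is a gait-peak surrogate: 2.5 × body weight (default
73 kg → ≈ 1790 N), compressive, inclined 10° from the shaft axis, spread
over the proximal-face nodes, with the distal face fully fixed.  The
inclination matters: the knee joint reaction during stance is never purely
axial, and the resulting shear engages nail bending over the working length
between the screws nearest the gap — the mode that concentrates implant
stress above the proximal distal-locking screw and differentiates nail
diameters.  A purely axial load on this symmetric construct produces an
almost uniform, percent-level gap stimulus and no diameter contrast; it
remains available by setting `load_angle_deg: 0` or an explicit
`force_vector`.  These loads are configuration surrogates, not
patient-derived values; absolute stresses scale linearly with the chosen
force.

## Healing-zone rule

The default rule encodes the strain/pressure tissue-differentiation limits
commonly quoted in the fracture-mechanobiology literature: intramembranous
(bony) formation for γ_oct ≤ 5% and |p| ≤ 0.15 MPa; endochondral formation
for compressive p > 0.15 MPa and γ_oct ≤ 15%; everything beyond is
connective-tissue excess.  An optional low-stimulus band (γ_oct ≤ 0.5%,
|p| ≤ 0.05 MPa) flags elements between resorption and formation; it is off
by default.  Zones are matched first-to-last, the last zone is a mandatory
catch-all, and every report echoes the rule used.  Headline percentages are
rounded to integers; exact fractions are always stored.  Pressure is
compression-positive throughout.

Note one subtlety: under proportional load scaling all stimuli scale
linearly, but zone membership is *not* totally ordered — an element in the
fibrous catch-all can enter the endochondral box when compression crosses
its threshold.  Monotone progression holds along pressure-free distortion
rays, and that is what the property tests assert.

Interfragmentary movement is the difference of mean interface-node
displacements (bone nodes shared with gap elements, split by the side of
the fracture plane), decomposed along the plane normal (axial, absolute)
and tangentially (shear magnitude).

## Scenario comparison and problem sizes

The committed pair shares phantom, screws and load and differs only in nail
diameter (8 vs 9 mm).  At the default resolution each scenario meshes
≈ 40–42 k TET4 elements (≈ 27 k free unknowns, direct solve, ≈ 7 s per
scenario on one CPU); these sizes were chosen so the full pair plus the
whole test suite runs comfortably on a laptop while keeping ≥ 2000 gap
elements for stable zone fractions.  TET4 is the pipeline default at this
resolution; TET10 (`element_order: 2`) is fully supported and carries the
analytic verification, but at the default mesh it exceeds the direct-solver
range.  Implant peak stress is compared against configurable Ti-alloy
strength minima (yield 860, tensile 930 MPa) as advisory reporting only.

## Known limitations

* Linear elasticity with everything rigidly bonded: no screw-hole clearance,
  no nail–bone contact or sliding, no geometric nonlinearity — construct
  stiffness is an upper bound and absolute IFM values are conservative.
* Single-time-point stimulus classification; no iterative tissue
  differentiation or callus evolution over the healing course.
* The phantom's idealized geometry supports method verification and
  *directional* treatment comparisons (smaller nail ⇒ higher implant stress
  and more over-strained gap tissue), not reproduction of any specific
  patient's absolute stresses or zone percentages.
* Zone limits are literature defaults; real tissue-level thresholds remain
  uncertain and should be treated as sensitivity parameters.
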