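# Methods

This note documents the geometric model, the conventions behind every
measured quantity, the synthetic phantom and its error models, and the design
decisions taken where more than one reasonable convention exists. All lengths
are millimeters and all angles degrees; STL files carry no units, so the
millimeter convention is a documented contract of the package.

## Anatomic coordinate frame

The frame is constructed purely from landmarks (`build_frame`):

- **y-axis**: unit vector from TMCP to TMCA (posterior → anterior along the
  medial plateau).
- **plateau plane**: spanned by y and the MMPP→MLPP line; its normal, oriented
  proximally, is the **z-axis**. The proximal cue is TKC−MMAL when the
  malleolus landmark is present (TKC−IFT as fallback); without any distal
  landmark the declared side (LEFT/RIGHT) disambiguates the normal.
- **x-axis** = y × z (right-handed). Its anatomical direction (medial vs
  lateral) therefore differs between sides; all reported angles are
  *side-normalized*, so mirror-image specimens yield identical values.
- **origin**: the tibial knee center TKC.

The frame is equivariant under rigid motion, which makes every downstream
angle pose-invariant (verified to 1e-6° in the tests).

## Angle definitions

- **Anatomical axis**: the line through the area centroids of the shaft
  cross-sections at ⅓ and ⅔ of shaft length below the plateau plane
  (frame-z = 0), oriented proximally. Cross-sections are taken perpendicular
  to the frame z-axis; the largest closed contour wins (distal slices can
  clip a malleolus bump), and an open contour falls back to the polyline
  vertex centroid with a warning. Shaft length is the distance from the
  plateau plane to the distal-most vertex along frame z.
- **MPTA**: both the joint line (MMPP→MLPP, medial to lateral) and the axis
  direction are projected into the coronal (x–z) plane; MPTA is the angle
  between the projections. This equals the clinically reported medial-side
  angle: a varus joint line gives < 90°, and a medial opening wedge increases
  MPTA by exactly the opening angle (rotation about the frame y-axis acts as
  an in-plane rotation of the projected axis).
- **Slopes**: 90° minus the angle between the plateau's posterior→anterior
  line (TMCP→TMCA medially, TLCP→TLCA laterally) and the 3D axis direction;
  positive when the plateau dips posteriorly-distally (orthopedic
  convention). Measured against the 3D axis rather than a sagittal
  projection; this keeps the slope a single well-defined lift angle.
- **Torsion**: the dorsal plateau tangent (PMC→PLC) and the distal
  malleolus→incisura line, both taken medial→lateral, are projected into the
  axial (x–y) plane; torsion is the signed angle between the projections,
  external rotation positive, with a side factor so left and right specimens
  report equal values.

Projection degeneracies (a projected line shorter than 1e-6 of its 3D
length) raise a dedicated error rather than returning an ill-conditioned
angle.

## Biplanar opening-wedge plan

With W = ‖MMPP−MLPP‖ (plateau width):

- **Ascending (frontal) cut**: plane with normal y through the point 10 mm
  posterior of the tuberosity apex TTV.
- **Medial entry**: the medial cortex point at the level W/2 below the medial
  plateau (MMPP), found by casting a horizontal medial ray from the frame
  axis; the outermost crossing is the cortex.
- **Main cut**: the plane containing the medial slope direction (TMCA→TMCP)
  through the entry point and the aim point 15 mm distal (frame z) of the
  lateral plateau (MLPP). "Parallel to the medial slope" is implemented as
  the cut containing that direction; its remaining freedom is fixed by the
  entry and aim points.
- **Hinge**: the most lateral vertex of the cut contour (on the lateral
  cortex), hinge axis along frame y. The in-bone cut terminates 15 mm medial
  of the hinge (the intact lateral bridge).
- **Opening angle**: solved by bisection on (0°, 30°) so that rotating the
  most medial cut-contour point about the hinge displaces it by the gap
  target along frame z (default 8 mm), to 1e-6 mm; the rotation sense is the
  one that opens the gap medially.

## Execution model

The bone is split by three planes: the main cut, the ascending plane
(anterior flange → distal fragment, so the tuberosity travels with the
shaft), and a bridge plane through the cut end perpendicular to the cut's
medial–lateral direction. The lateral bridge — which in reality deforms
plastically — is cut through in the virtual model and assigned, undeformed,
to the fixed proximal fragment; this idealization is what makes the distal
motion exactly rigid. The distal fragment rotates about the hinge by the
solved opening angle; the realized gap is re-measured from matching cut-
contour vertices of the two fragments (agreement with the target is a test
criterion at ±0.05 mm). Landmarks are classified by signed distance to the
main cut with the flange rule; a landmark within 0.5 mm of the cut is
assigned by sign and flagged.

With the hinge along frame y the correction is coronal-only: MPTA changes by
the opening angle (±0.1°), slopes are preserved to a few hundredths of a
degree, and torsion to < 0.2°. The residual torsion shift is not an error
but the axial-projection shortening sin τ·cos τ·(sec θ − 1) ≈ 0.19° at
τ = 35°, θ ≈ 6.8°; it grows quadratically with the opening angle, so
substantially larger gaps would visibly couple into measured torsion even
with a perfect hinge.

## Plan-vs-result evaluation

- **Registration** (`best_fit_register`): candidate pre-alignments (keep
  pose, centroid shift, centroid + principal axes) are scored by initial RMS
  and the best is refined by iterative closest-point minimization of the
  mean squared point-to-surface distance (deterministic vertex subsample of
  up to 2000 points, Kabsch solve per iteration). Convergence: RMS
  improvement < 1e-6 mm or 100 iterations; non-convergence returns the best
  transform with a warning (in practice this fires when the RMS is already
  at the sub-micrometer discretization floor). Registration is estimated on
  the proximal region — the part the osteotomy does not change — cropped 60
  mm below the plateau by default, and then applied to the whole realized
  anatomy.
- **Deviation map**: for every realized vertex, the signed perpendicular
  distance to the planned surface; the sign comes from the planned face
  normal at the closest point (positive = outside/above the plan). Closest
  points are exact: a k-nearest-centroid candidate search over a KD-tree is
  verified by a ball query at radius best + r_max that covers every triangle
  whose bound could still win.
- **Bands and grade**: |d| is binned into [0, 0.6), [0.6, 1.2), [1.2, 1.7),
  [1.7, ∞) mm. The specimen grade is the band containing the 95th percentile
  of |d| — a deliberate package-level rule: published deviation tables label
  specimens qualitatively without stating a numeric rule, and the 95th
  percentile ignores isolated segmentation spikes while still failing a
  genuinely displaced fragment.
- **Cohort statistics**: per-angle absolute deviations per specimen, with
  absolute mean and sample SD (n−1), rounded to two decimals for reporting.
  A packaged 13-specimen cadaveric reference table
  (`data/reference_cohort.csv`) serves as the worked example for these
  statistics.

## Synthetic phantom

The phantom (`generate_tibia`) is a stylized, watertight proximal tibia —
not an anthropomorphic model; its purpose is internal consistency, i.e.
analytically known landmarks and exactly realized target angles:

- Elliptical cross-sections along z: plateau half-width 37.5 / half-depth 25
  (defaults W = 75, depth 50), blending over a 115 mm metaphysis to a 13 mm
  shaft (smoothstep, so the taper vanishes at both ends — the axis slice
  levels sit in the taper-free shaft), with a small distal flare
  (malleolus_offset) in the last 30 mm.
- A plateau surface tilted by a coronal parameter and x-interpolated
  sagittal slopes; an anterior tuberosity bump whose apex protrudes 12 mm
  beyond the plateau rim (so the ascending cut plane, 10 mm behind the apex,
  clears the plateau); a distal twist ramping to the torsion parameter below
  the osteotomy region.
- Landmarks are evaluated from the same closed-form surface function that
  builds the mesh, on meridians/levels that are exact mesh vertices (the
  circumferential resolution must be a multiple of 24 for this reason).
- Because the measured angles are defined through the landmark-derived frame
  — itself tilted by the plateau parameters — the raw tilt/twist parameters
  are solved numerically (hybrid Newton on the closed-form landmark → angle
  map, residual < 1e-8) so that the *measured definitions* hit the requested
  targets. The returned ground truth therefore equals the targets, and the
  mesh-based measurement recovers them to < 0.01° at default resolution.
- The incisura landmark level is solved so the malleolus–incisura line lies
  in the frame's axial plane; otherwise any coronal hinge rotation would
  couple its z-component into measured torsion and the coronal-only property
  above could not hold at the stated tolerance.

What the phantom does **not** emulate: real cortical geometry, the fibula,
soft tissue, segmentation noise, or plastic hinge deformation. Passing tests
therefore demonstrate the correctness of the geometry pipeline, not clinical
accuracy on real bones.

### Error models

`simulate_surgical_error` re-executes the fragment motion with three
interpretable knobs: a multiplicative opening-angle scale (general
under-correction, e.g. gap settling after wedge removal), an axial hinge
tilt (hinge-obliquity slope hazard: 20° of tilt couples > 0.5° into the
slope), and an anterior sag (extra rotation about the in-cut medial–lateral
axis that closes the anterior gap by a prescribed millimeter amount —
wedges supported posteriorly only). `jitter_landmarks` adds isotropic
zero-mean Gaussian noise per landmark, reproducible per seed; with equal
noise on all landmarks, torsion is by far the least reliable angle (its
defining landmarks are the farthest apart in projection but the shortest
lever in the axial plane), reproducing the known reliability ordering.

### Cohort simulation conditions

The default synthetic cohort (`run_pipeline`) draws 13 specimens: MPTA
U(84, 90), slopes U(4, 10), torsion U(25, 45), random side; execution errors
with opening-angle scale N(1, 0.1) clipped to (0.6, 1.4), hinge tilt
N(0, 4°), anterior sag |N(0, 0.8)| mm, and 1.0 mm observer landmark noise on
the realized measurement. These values were chosen once as plausible
magnitudes for guided osteotomies and are configuration, not calibration; no
acceptance quantity depends on them.

## Numerical choices

- Duplicate-vertex merge at 1e-6 mm on STL read (STL is a triangle soup);
  binary STL stores float32, which bounds any round-trip to ~3e-5 mm at
  360 mm coordinates.
- Degenerate (zero-area) faces are dropped on construction; an empty result
  is an error.
- Frame construction rejects defining landmarks collinear within 1°.
- Bisection tolerances: 1e-6 mm on the opening-angle gap residual.
- Cut-contour membership at 1e-6 mm from the plane; landmark-ambiguity band
  at 0.5 mm.
- Percentiles by linear interpolation (numpy default).
- Mesh resolution: default 48 × 180 (circumferential × longitudinal);
  multi-specimen tests use 24 × 100, which changes measured angles by
  < 0.01°. Both satisfy the documented minimum of 24 × 60.

## Known limitations

- The lateral bridge is modeled as cut through; post-release elastic or
  plastic behavior of a real hinge (and hence systematic under-correction
  mechanisms) is out of scope.
- The specimen-level grade rule (95th-percentile band) is a package decision;
  other sites may prefer worst-band or area-fraction rules, which
  `BandSummary` also exposes.
- `cross_section_centroid` assumes the largest contour is the shaft; exotic
  geometries with multiple comparable contours at the slice levels would
  need explicit level selection.
- Landmarks are inputs; automatic landmark detection and interactive picking
  are out of scope.
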