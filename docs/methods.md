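# Methods

## Problem

A transseptal puncture (TSP) gives catheters access to the left atrium (LA)
through the fossa ovalis (FO), the thin window in the interatrial septum.
Where the needle crosses matters: the puncture site becomes the pivot for
every subsequent catheter maneuver, so a poorly placed site can leave parts
of the LA (e.g. the right pulmonary veins) effectively out of reach.  This
package quantifies that effect.  It scores every candidate site on an FO
mesh by the global isotropy index (GII) of a catheter pivoting there, maps
which LA regions a given pivot can reach, and computes the statistics used
to evaluate operator performance on a TSP training phantom: puncture-point
distances, time correlations, dimensional-accuracy agreement and
questionnaire descriptives.

## Catheter model

The inserted catheter segment is modelled as a single circular arc of
constant curvature launched tangentially along the pivot axis — the inward
FO normal.  A configuration is

    u = (phi, theta, s),

where `phi` ∈ [−π, π] is the bending-plane angle about the axis, `theta` =
κℓ ∈ [0, theta_max] the total bend angle, and `s` = ℓ/ℓ_max the normalized
insertion length.  In pivot-frame coordinates (z along the axis, x along the
`phi = 0` reference) the tip sits at

    tip(u) = ℓ · ( a(θ) cos φ,  a(θ) sin φ,  b(θ) ),
    a(θ) = (1 − cos θ)/θ,   b(θ) = sin θ / θ.

Both arc terms are evaluated by Taylor series below θ = 10⁻⁶ rad (and
`1 − cos θ` as `2 sin²(θ/2)` above it) so the straight-catheter limit
θ → 0 is continuous to better than 10⁻⁹ mm.

The inverse kinematics is closed-form: for a local target (x, y, z) with
r = √(x² + y²), the unique arc through the origin tangent to the axis has

    φ = atan2(y, x),   κ = 2r / (r² + z²),
    θ = atan2(zκ, 1 − rκ)  taken in [0, 2π),   ℓ = θ/κ,

with the straight-insertion branch (κ < 10⁻⁹ mm⁻¹) reachable only for
z > 0.  Targets behind the pivot plane require θ > π and are therefore
unreachable under the no-looping limit.

### Why u = (phi, theta, s)

A singular-value ratio is only meaningful when the Jacobian's columns are
commensurate.  With angles in radians and a dimensionless insertion, all
three columns of J = ∂tip/∂u carry mm per unit control.  The alternative
parameterization (φ, κ, ℓ) mixes mm/(mm⁻¹) and mm/mm columns and is exposed
(`parameterization="phi_kappa_ell"`) for sensitivity checks only.

### Kinematic limits

Defaults encode "simple configurations, no looping": theta_max = π,
ℓ ∈ [5, 100] mm, κ_max = 0.1 mm⁻¹ (10 mm minimum bend radius, typical of an
ablation catheter).  All are overridable via `KinematicLimits` or the run
config.  Reachability is tip-only — no shaft–wall collision test is applied,
a known limitation: a configuration counted reachable may sweep the shaft
through the atrial wall.

## GII scoring

For a single configuration, GII(J) = σ_min(J)/σ_max(J) ∈ [0, 1]: 1 means
the tip responds equally in every direction, 0 means a direction of motion
is lost.  A per-site score must aggregate over the whole workspace; two
conventions are implemented because the choice is genuinely open:

* `global` (default): min over reachable configurations of σ_min divided by
  max over reachable configurations of σ_max, where the configurations are
  the IK solutions of every reachable LA sample point.  This is a worst-case
  isotropy over the workspace and is systematically small (the φ-column of J
  vanishes as θ → 0, so near-axis targets depress σ_min).
* `local`: the single-configuration ratio at the configuration reaching the
  LA sample centroid.

A pivot that reaches no sample point scores 0 rather than NaN, keeping the
argmax total.  Reports name the mode used.  Histograms use fixed 0.01-wide
bins on [0, 1]; the modal bin is reported by its center with ties resolved
to the lowest bin, and the argmax candidate by lowest index on exact ties.

The LA interior is discretized on an axis-aligned grid (default spacing
2.5 mm, configurable) filtered by a ray-parity strictly-inside test
(vectorized Möller–Trumbore crossings along a fixed irrational direction,
which avoids edge/vertex degeneracies on symmetric meshes).  A grid rather
than rejection sampling keeps the discretization deterministic; identical
inputs give bitwise-identical score arrays.

## Statistics

* Distances are 3D chordal Euclidean (not geodesic on the FO), per
  participant, mean ± sample SD to two references: the max-GII site and the
  FO centroid — defined throughout as the *thinnest* point of the FO, not
  the geometric mean.
* Pearson correlations use the two-sided t-distribution p-value with n − 2
  df.  Because it is ambiguous whether the published time correlation was
  computed on time or log-time, the pipeline reports both.
* Bland–Altman limits of agreement are bias ± 1.96 × sample SD (ddof = 1);
  the percentage-within statistic is counted on the same pairs (~95%
  expected under normal differences).
* Kruskal–Wallis uses the tie-corrected H with a χ²(k−1) p-value; the fully
  degenerate all-identical case is defined as H = 0, p = 1.
* Likert tables report mean ± population SD (ddof = 0), which reproduces
  published two-value splits such as {4, 5} → 4.50 ± 0.50; a ddof switch is
  provided.  No multiple-testing correction is applied; p-values are raw.

## Synthetic study generator

The study's patient geometry and raw participant recordings are not public,
so `fossa_gii.synthetic` generates every input with known ground truth.  It
emulates:

* **Geometry** — a closed LA ellipsoid (semi-axes 24 × 20 × 16 mm, a
  realistic blood-pool scale giving ≈2000 interior samples at the default
  spacing) and a circular FO disc of diameter 18.46 mm in the tangent plane
  of the septal wall, with radially parabolic thickness from 0.65 mm at the
  center to 1.75 mm at the rim — the dimensions of the fabricated FO insert.
* **Punctures** — five operators (a trainee plus cardiologists with 10, 10,
  14 and 25 years of experience), 4 trials each (the middle of the 3–5
  range), scattering isotropically in the FO plane around the midpoint of
  the centroid and the max-GII site.  Dispersions default to 8.0 mm for the
  trainee (scatter spanning most of the fossa, clamped to the insert) and
  2.5/2.5/2.0/1.5 mm for the experienced operators; this separation makes
  the trainee's mean distances the largest in ≥95% of seeds at the study's
  trial counts, the qualitative experience ordering the pipeline is expected
  to recover.
* **Times** — linear in the puncture's GII and centroid distance plus
  Gaussian noise, mean 120 s, overall SD 20 s.  The two coefficients and the
  noise SD are solved from the covariate covariance measured on a large
  (n = 4000) calibration cohort so the *population* correlations equal the
  configured targets (defaults 0.656 and 0.566).  The calibration stream is
  seeded independently of the master seed so the generating correlations are
  a property of the configuration, not of the draw; each output table
  otherwise has its own stream derived from the master seed, so adding a
  table never perturbs the others.
* **Measurements** — 3 researchers × 50 shared features, uniform 2–60 mm
  (wall thicknesses to chamber dimensions); the physical value reads
  smaller than the STL truth by 0.03 mm on average with 0.2 mm Gaussian
  noise.
* **Questionnaire** — integer 1–5 scores from a two-point floor/ceil mixture
  matching the target mean exactly in expectation, 5 participants.

What the generator does **not** emulate: pulmonary veins and appendage
anatomy (so "unreachable region" maps are geometric, not anatomically
labelled), non-Gaussian or anisotropic operator scatter, EM-tracker
registration error, and learning effects across trials.  Passing recovery
tests therefore demonstrate correctness of the estimators and the pipeline
under the stated model, not robustness to real-data artifacts.

## Numerical choices

* θ-series switch 10⁻⁶ rad; IK straight-branch curvature tolerance
  10⁻⁹ mm⁻¹; frame orthonormality tolerance 10⁻⁹.
* Reachability placement tolerance 1.0 mm (order of EM-tracking precision).
* Tie-breaks are always lowest index (thinnest-point centroid, field argmax)
  or lowest bin (histogram mode); quadrant labels resolve exact zero offsets
  toward superior and posterior.
* Normal orientation: STL carries no canonical normal sense, so FO normals
  are flipped as a patch to point at a supplied LA-side reference point.
* Degenerate inputs are errors, not NaNs: non-positive thickness, empty
  sample sets, zero-variance correlation inputs, out-of-range Likert scores.

## Problem sizes

Default runs score ~193 FO candidates against ~2000 LA samples; the
brute-force reachability oracle in the test suite grids (θ, ℓ) at
1° × 0.5 mm with the bending plane resolved analytically; statistical
recovery tests use 1000 seeded cohorts of 20 punctures, 150 measurement
pairs, and 2000 null replicates for the rank-test calibration.  These sizes
were chosen to make every sampling distribution visible while keeping a full
run on a single CPU in well under a minute per stage.

## Known limitations

* Tip-only reachability (no shaft collision or contact mechanics).
* Single-arc constant curvature; no piecewise arcs or torsion.
* The `global` GII aggregation is one defensible reading of a
  workspace-level isotropy index; absolute score magnitudes are not
  comparable across aggregation modes, only rankings within a mode.
* The synthetic FO is planar; on a strongly curved septum the tangent-plane
  scatter model and the disc's in-plane frame would need generalizing.
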