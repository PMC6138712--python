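# Methods

This note documents the models, numerical choices and limitations behind
`tendontwist` — a finite-element pipeline for studying how helical fascicle
twist shapes stress distribution and rupture strength in the free Achilles
tendon. Units are fixed package-wide: mm, N, MPa.

## Constitutive model

The tendon is a transversely isotropic hyperelastic solid: a neo-Hookean
ground-substance matrix reinforced by one family of collagen fibers,

W = C1/2 (Ī₁ − 3) + F₂(λ̄) + κ/2 (ln J)²,

with Ī₁ the first invariant of the isochoric right Cauchy–Green tensor and
λ̄ the isochoric fiber stretch. The fiber law is the classical three-branch
uncrimping form

λ ∂F₂/∂λ = 0 (λ ≤ 1); C3[e^{C4(λ−1)} − 1] (1 ≤ λ ≤ λ\*); C5 λ + C6 (λ ≥ λ\*),

with C6 = C3(e^{C4(λ\*−1)} − 1) − C5 λ\* enforced at construction so the law
is continuous at the uncrimping stretch λ\*; `MaterialParams` rejects any
inconsistent C6. F₂ is integrated in closed form per branch (the
exponential branch yields an exponential-integral term), with constants
chosen so F₂(1) = 0 and F₂ is C¹ at λ\*.

Parameter meanings and defaults:

| symbol | meaning                              | typical value  |
|--------|--------------------------------------|----------------|
| C1     | ground-substance shear modulus       | 15–165 MPa     |
| C3     | exponential fiber stress scale       | 2–37 MPa       |
| C4     | fiber uncrimping rate                | 3–155          |
| C5     | straightened-collagen modulus        | ~0.6–1.5 GPa   |
| λ\*    | uncrimping stretch                   | 1.03 (default) |
| κ      | volumetric penalty                   | 1000·C1        |

λ\* is not reported in the calibration literature this model follows; 1.03
is a mid-range toe-region endpoint (3% strain) and is configurable — it is
held fixed during calibration and recorded in every result. The material
is treated as nearly incompressible through a penalty U(J) = κ/2 (ln J)²
with κ = 1000·C1 by default; this makes incompressible closed forms valid
oracles (single-element uniaxial agreement is ~0.4% at κ = 1000·C1). The
fiber contribution acts on the isochoric stretch for consistency of the
volumetric split. Viscoelasticity, damage and poroelasticity are out of
scope.

## Geometry and discretization

The free tendon (60 mm) is lofted through elliptical cross-sections given
at axial stations (0/20/40/60 mm by default, the distal insertion plus
planes mirroring 2/4/6 cm ultrasound sections). Sections are meshed with a
butterfly O-grid — a square core plus circumferential ring layers — and
extruded axially into trilinear hexahedra; there is no degenerate center
node. The in-plane grid is scaled so the discrete boundary polygon area
equals πab exactly (area-preserving sizing), so the discrete CSA matches
the profile at any resolution and mesh volume converges to the lofted
solid with the axial discretization.

Coordinates: x = medial(+)/lateral(−), y = anterior(+)/posterior(−),
z = distal(0) → proximal(+).

Labels:
- Compartments: elements are medial or lateral by the sign of their
  centroid's x-offset from the section centroid.
- Sub-tendons (soleus / medial gastrocnemius / lateral gastrocnemius):
  angular sectors of the section, walked anticlockwise from the medial
  axis with the soleus sector centred medially. Default area fractions are
  6:2:1; the synthetic cohort instead uses anatomical sub-tendon area
  shares (52:35:13) — see "Load split vs area split" below.
- The two-way (soleus/gastrocnemius) split used by the sliding model
  assigns an outer-ring arc centred posteriorly (~1/3 of the area) to the
  gastrocnemius so that the interface follows mesh facets exactly.

Free-form CSA morphing scales in-plane coordinates about the section
centroid by 1 + (√s − 1)·sin²(πt) (t the axial fraction), multiplying the
mid-section area by s while leaving the ends untouched; element inversion
or a detJ ratio below 0.25 raises an error.

## Fascicle twist as a continuum field

Twist is parameterized by a total angle distributed linearly from distal
to proximal (the minimal assumption given only a total angle is
specified). A material point at in-plane offset r from the centroid
carries the helical tangent ê_z + (Θ/L)(ê_z × r), normalized; handedness
flips the sign (counterclockwise in the right limb convention).

The field-fitting pipeline mirrors continuum fiber fitting: a uniform data
cloud (4×4×4 points per element) carries the per-point rotation taking
straight to twisted directions; that rotation is expressed in the *local
cylindrical material frame* (radial, circumferential, axial) and
decomposed into Z–Y–Z Euler angles, which are then fitted as a trilinear
nodal field by regularized least squares and re-applied at Gauss points.
The local frame matters: in a single global frame the first Euler angle
wraps by 2π around the tendon axis and cannot be interpolated. Gimbal
configurations (β ≈ 0) pin the redundant angle to zero for determinism.
Round-trip accuracy (cloud → fit → evaluate vs the analytic helix) is
~0.01° RMS at default density, far inside the 2° acceptance bound; the
studies therefore evaluate the analytic helix directly at Gauss points by
default, with `fitted=True` running the full fitting path (used by the
embedded-twist comparisons and validated by the round-trip tests).

## Finite-element solver

Total-Lagrangian, trilinear hexahedra, 2×2×2 Gauss quadrature. Volumetric
locking is avoided by a mean-dilatation treatment: the volumetric stress
at each Gauss point is driven by the element-averaged volume ratio J̄.
The consistent tangent is assembled by column-wise central differencing of
the element internal force (all 48 perturbed states evaluated in one
batched constitutive call), which captures the mean-dilatation coupling
exactly. Equilibrium uses Newton–Raphson with:

- relative force-residual tolerance 1e-8 (max 50 iterations per step);
- incremental load stepping with automatic bisection (floor 1/256 of the
  ramp interval), where warm-started incremental loops resume the ramp
  from the previous level's fraction rather than zero;
- an incremental linear predictor for prescribed-displacement steps (the
  interior is moved consistently with the boundary increment before the
  exponentially stiff material is evaluated — without it, the displacement
  jump crushes the first element layer and Newton stalls); and
- a backtracking line search with an element-inversion guard.

Non-convergence raises, carrying the last converged load fraction; the
converged flag is never silently false.

Sub-tendon interfaces are node-to-node ties on conforming duplicated
surfaces (small sliding): bonded mode ties all three components and
reproduces the monolithic solution to machine precision; frictionless
sliding ties only the facet-normal component(s), leaving tangential motion
free. Seam nodes whose adjacent facet normals disagree by more than 30°
carry multiple normal constraints (sliding only along the seam), and
duplicated nodes of clamped sections inherit the clamp. Constraints are
eliminated through a transformation u = T q + g.

Surface markers (six, equidistant along the posterior surface line) are
located by inverse trilinear mapping and convected with the displacement
field. Transverse rotation is measured from the second-moment principal
axis of the deformed boundary node ring of the proximal vs distal
sections; for deformed aspect ratios below 1.05 the principal axis is
degenerate and the mean azimuthal node rotation is used instead.

## Synthetic cohort

The generator replaces the cadaver inputs. Subject draws (log-normal for
positive quantities, exact first two moments):

- CSA 70 ± 15 mm²; aspect ratio 2:1 (medial-lateral wider); mild taper
  (1.08/0.96/0.92/1.00 of the drawn CSA at the four stations, narrowest
  2–4 cm above the insertion); the mid-section centroid bows 1.2 mm
  laterally — the geometric asymmetry that concentrates stress medially
  under load.
- C1 45 ± 15 MPa, C3 10 ± 4 MPa, C4 40 ± 12 (spanning the ranges observed
  in published per-subject calibrations); C5 1000 ± 250 MPa.
- Twist 37 ± 14°, clamped to [0°, 90°] (anatomical surveys report
  11–65°).

Simulated experiments clamp the distal section, ramp an axial force at the
proximal end over 10 levels and record the markers with 0.1 mm i.i.d.
Gaussian noise (the order of published marker-fit residuals). The peak is
found the way a lab runs the test: a displacement-controlled pre-run to 8%
end-to-end strain reads the peak force off the machine reaction, which
guarantees every subject's record samples the post-uncrimping linear
regime needed for the C5 gradient.

What the generator does *not* emulate: real cross-section irregularity
(sections are ellipses), curved subject-specific tendon axes beyond the
single lateral bow, inter-fascicle sliding within sub-tendons, and
viscoelastic/cyclic history. Passing tests therefore demonstrate the
pipeline's correctness and the qualitative mechanics of this model class,
not quantitative agreement with any cadaver.

## Calibration

C5 comes from the gradient of the record's stress/strain curve: true
stress F·λ/A_eff (incompressible area correction, series-effective CSA
over the marker span) against the stretch of the clamp-free marker span
(markers 2–6; the most distal marker sits in the clamp's boundary layer).
The window is selected by stretch (λ ≥ λ\* + 0.02) rather than by force:
force-windowed samples just past the uncrimping transition still mix
exponential-branch material and inflate the slope by ~10%. The
ground-substance tangent C1(2λ + 1/λ²) is subtracted.

(C1, C3, C4) minimize the marker-position RMS between forward FE runs of
the recorded force levels and the record, via trust-region least squares
on the log-parameters with seeded multistart (bounds C1 ∈ [1, 300] MPa,
C3 ∈ [0.1, 60] MPa, C4 ∈ [1, 200], covering published per-subject
ranges); ties resolve toward the smallest C4. C6 is recomputed from
continuity at every evaluation.

Because the C5 gradient needs C1, the self-contained path imposes the
measured gradient as a constraint c5(c1) = S − c1(2λ̄ + 1/λ̄²) inside the
optimization, removing the near-degenerate C1/C5 trade-off. Accuracy on
noiseless synthetic records: with C5 fixed at its true value the optimizer
recovers C1, C3, C4 to machine precision; the self-contained path recovers
C1 to ~2% and C5 to ~1%, but C3/C4 absorb the residual C5 error at roughly
seven-fold amplification (~10%). This weak C3/C4 identifiability matches
the large per-subject scatter seen in published calibrations of this
material model, and is why parameter-recovery claims here are stated for
the C5-fixed contract.

## In-silico studies

**Rupture.** Distal clamp; total force climbs in 100 N increments, split
6:2:1 (soleus : MG : LG, the triceps-surae PCSA ratio) over each
sub-tendon's proximal nodes with tributary-area weights. After each step
the longest run of consecutive Gauss points with von Mises stress above
100 MPa is measured along every axial Gauss column (fixed in-plane Gauss
position, stacked distal→proximal); a run of ≥ 15 points is rupture. The
physical length of a 15-point run depends on the axial resolution and is
recorded per result (~28 mm at the cohort's n_axial = 16; the original
criterion corresponds to ~3 mm on a much finer mesh). A 10 kN cap yields
an explicit no-rupture outcome; solver failure reports the last converged
load.

**Load split vs area split.** If sub-tendon cross-section areas equal the
6:2:1 load fractions, the differential load is uniform per unit area and
nothing concentrates. The cohort therefore uses anatomical sub-tendon
area shares (52:35:13) with the 6:2:1 *load* split, so the soleus region
is overloaded by ~1.4× — which reproduces a large (≈50–60%)
medial-lateral stress gap at 0° twist.

**What twist does and does not do here.** Increasing twist reduces the
medial-lateral gap (the cohort acceptance run measures ≈49.3% at 0° vs
≈48.1% at 15°, with the decline continuing toward 60°), the direction of
the published compartment analysis. It does
*not* raise the rupture load in this model class: the entry concentration
decays within ~20 mm by matrix shear (C1 ~ 30–45 MPa), a 15° total twist
tilts fibers only ~2° at the outer radius (negligible azimuthal load
transport), and the untwisting torque under axial load adds a small shear
that slightly raises peak von Mises stress. Cohort rupture loads tie at
the 100 N increment between 0° and 15°. The corresponding published
gain (tens of percent at 15°) evidently depends on the cadaver-specific
geometries and host-mesh implementation, which are unavailable; the
acceptance test states the published direction and is allowed to fail.

**Sliding.** The four-case comparison (straight/twisted ×
bonded/frictionless) applies displacement-controlled stretch to the
two-sub-tendon split model until the rupture run-length criterion is met;
nodal von Mises fields at 10% stretch are compared by squared Pearson
correlation, including against the monolithic embedded-twist model (which
uses the fitted Euler field). The bonded straight case reproduces the
monolithic solve exactly (r² = 1.0); sliding vs embedded-twist
correlations land near 0.9 on the synthetic geometry (the published
comparison reports 0.8 on cadaver geometry).

**Sensitivity.** Twist angle, CSA (via the mid-section morph) and C5 are
perturbed ±1σ one-at-a-time about each subject's baseline; the rupture
load is re-measured and factors ranked by mean |% change|. σ values are
the population model's own spreads (the source study's σ came from
unpublished cadaver data). For budget, sensitivity runs use a 500 N
staircase on an n_axial = 8 mesh; the CSA ≥ twist ordering (measured
≈6.8% vs ≈2.1%) is robust to that quantization. The ANOVA is the
classical between/within mean-square ratio; all-identical groups are
flagged degenerate with F = 0, p = 1.

## Problem sizes

Chosen as the package's working resolutions: calibration meshes
n_axial = 4, n_circ = 8–12, n_radial = 1 (~250–750 dof); cohort rupture
meshes n_axial = 16, n_circ = 12 (~2.3 k dof); sliding meshes
n_axial = 8, n_circ = 8. Mesh-refinement checks show tip displacement
converging within 2% between successive refinements at these scales.

## Known limitations

- C3/C4 are weakly identifiable from marker data alone (see Calibration).
- The 15-point rupture run is resolution-dependent in physical length;
  results quote the run length in mm alongside the load.
- Small-sliding node-to-node interfaces assume conforming meshes; large
  sliding contact is out of scope.
- The rupture-load-vs-twist direction of the source analysis is not
  reproduced by this model class at these conditions (see above); the
  compartment-stress, sensitivity-ordering and sliding results are.
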