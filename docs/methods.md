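# Methods

## Overview

`hullmass` estimates whole-body mass and centre of mass (COM) for fossil
skeletons from segmented 3-D skeletal models, and analyses how those
properties scale and evolve across a taxon sample. The workflow is:

1. load per-segment meshes and landmarks into a standardised body frame;
2. compute each segment's minimal convex hull (volume + centroid);
3. expand hull volumes to soft-tissue volumes with extant-calibrated
   scaling models, with floor and exemption rules;
4. assign per-class tissue densities, assemble segment masses into
   whole-body mass, COM, and uncertainty bounds;
5. run sensitivity variants (densities, osteoderm exclusion, neck
   pitch);
6. normalise COMs and fit allometries by OLS and Brownian-motion PGLS,
   with ancestral-state reconstruction and phylomorphospace export.

## Coordinate frame and measurement pose

All quantities are expressed in a body frame with origin at the
mid-acetabular point, +x anterior, +z dorsal, and y mediolateral
(right-handed). Whole-body COM is therefore a displacement from the
acetabula, and the glenoid landmark gives the glenoacetabular (GA)
distance used to non-dimensionalise COM (0 = acetabulum, 1 = glenoid;
anteroposterior and dorsoventral components taken separately).

Hulls are measured once, in a reference pose with the axial skeleton
extended anteroposteriorly and limbs ventral. This is a standardised
measurement posture, not a life posture; posture sensitivity is handled
by the repose step, which rotates segment COMs (point masses) about
joint pivots rather than re-hulling meshes. Meshes need not be
watertight or manifold — only vertex clouds feed the hulling stage,
which suits incomplete, messy fossil scan data.

## Convex hulls

Each segment hull is computed with Qhull (via `scipy.spatial.ConvexHull`);
volume is accumulated as tetrahedra spanned by hull facets and an
interior reference point, and the centroid is the volume-weighted mean
of tetrahedral centroids. Degenerate (coplanar/collinear) segments are
a hard error naming the segment. A tolerance of 1e-12 on accumulated
simplex volume guards near-degenerate input; exact arithmetic is not
used. Under uniform within-segment density the hull centroid is the
segment COM, and the expansion step deliberately scales volume while
keeping each segment's centroid fixed.

## Hull-to-soft-tissue expansion

Minimal skeletal hulls underestimate live volume. Three correction
families are supported, selected by model-set name:

* **allometric** (`V = 10^(a + b·log10(V_hull))`), per segment class,
  calibrated on either non-avian sauropsids (NAS) or birds;
* **isometric** (`V = k·V_hull`), same two sources;
* **sellers21**: the classic uniform +21% whole-hull expansion.

Each model carries a mean absolute percentage prediction error (mPPE),
applied as symmetric multiplicative bounds `V·(1∓mPPE)`. Whole-body
bounds sum the segment-wise extremes simultaneously — a conservative
envelope that does not assume per-segment independence (root-sum-square
combination was the alternative; simultaneous summation is the
implemented contract).

Rules layered on top:

* **floor rule** — for classes whose hulls hug the skeleton tightly the
  hull volume is a hard minimum for the prediction (and its bounds).
  Default floor set: {neck, metatarsus}; configurable, since the full
  list is a judgement call rather than a fixed convention.
* **exemption** — ornaments, major osteoderms, and separately hulled
  sails are never expanded (dermal envelopes wrap them tightly); their
  mPPE is treated as zero.
* **bird tail redirect** — bird-source model sets use NAS tail factors,
  because extant bird torso hulls contain the reduced tail and no bird
  tail calibration exists. A manifest flagged `tail_in_torso` gets no
  separate tail expansion at all (tail segments keep hull volume).
* **preferred sets** — taxon-by-taxon source/mode choices are expressed
  as data (`(taxon, segment_class) → (source, mode)` overrides) on top
  of an NAS base, never as special-cased code.

The calibration coefficients themselves are **inputs**. The package
ships only a clearly labelled placeholder table
(`placeholder_factor_table`) with plausible magnitudes (isometric
factors 1.3–1.6, near-unity allometric exponents, mPPE 0.25–0.35) so the
pipeline is runnable and testable end to end; real analyses must load
the published extant-sauropsid coefficients via `load_factor_table`.

## Densities, masses and COM

Segment mass is `ρ(class) × V`, whole-body COM is `Σ mᵢxᵢ / Σ mᵢ`.
The primary heterogeneous scheme uses 1000 kg/m³ for head, tail and
limb segments, 800 for the neck and 850 for the torso (respiratory
structures), 2000 for ornaments/osteoderms (compact bone) and 1000 for
sails. Sensitivity presets: homogeneous whole-body extremes 731 and
1169 kg/m³ (plucked-bird literature extremes), a 500 kg/m³ low-density
neck for highly pneumatised necks, ornament-light (1000), and a dense
sail (2000). Mediolateral COM is computed but flagged — bilaterally
modelled bodies should have it at or negligibly off the sagittal plane.
Left and right limb segments are stored separately; class totals sum
both sides.

Sails, ornaments and osteoderms are ordinary segments with exempt
expansion and their own densities; alternative reconstructions (e.g. a
hump enveloping tall neural spines versus a separately hulled sail) are
expressed as two alternative manifests, not special-cased code.

## Posture sensitivity

`repose` rigidly rotates an ordered chain of segment COMs about a joint
pivot (Rodrigues rotation). The default axis is mediolateral with the
sign convention that positive angles pitch anterior structures dorsally.
Masses, volumes, and chain-to-pivot distances are conserved; successive
rotations about one pivot compose additively. The neck pivot ("base of
the neck") is not something geometry can infer, so manifests must supply
it in `joint_pivots`. COM shifts are reported as percentages of the AP
and DV glenoacetabular distances respectively.

## Comparative analyses

* **Normalisation**: COM by GA distance (signed; 0 = acetabulum,
  1 = glenoid) and by total mass^(1/3). DV-degenerate taxa (glenoid at
  acetabular height) are flagged and their DV-GA coordinate stored as
  NaN, to be dropped from DV regressions with a logged note.
* **Stylopodial comparison**: log-linear circumference equations
  (`mass = 10^(a + b·log10 C)`, femoral C for bipeds, humeral+femoral
  for quadrupeds) with mPPE bounds; coefficients are user-supplied
  config, and their absence is an explicit, directing error.
* **Spearman rank agreement** between model sets (mid-rank definition;
  `scipy.stats.spearmanr` underneath; constant vectors flagged NaN).
* **Regression**: OLS and Brownian PGLS fitted by Cholesky-whitened
  least squares with residual covariance σ²C (C = shared root-to-MRCA
  path lengths). σ² is the ML estimate; slope CIs are t-based (df =
  n−2); the pseudo-R² centres on the GLS mean, adjusted for sample
  size; AICc uses k = 3 (two coefficients + σ²). Base-10 logs
  throughout. No Pagel's λ or OU transforms — Brownian only, ML rather
  than REML. Isometry verdicts compare the 95% CI with a caller-supplied
  expectation (1 for mass–mass, 1/3 for length–mass). Group-wise fits
  and taxon-exclusion lists are driven by table columns, not code.
* **Ancestral states**: Brownian maximum-likelihood reconstruction in
  closed form as the GLS conditional expectation
  `μ̂ + Σ_anc,tip C⁻¹ (y − μ̂)` with μ̂ the GLS root mean; this equals the
  rerooted-GLS ("fast" ML) reconstruction, which the tests verify
  explicitly on 16-tip trees. Zero-length terminal branches are
  epsilon-substituted with a warning.
* **Phylomorphospace**: tips at observed traits, internal nodes at
  reconstructed states, edges following topology; optional matplotlib
  export.

## Synthetic data: what it emulates and what it does not

The generator provides the ground truth real fossils cannot:

* **Primitives** — boxes (exact hull volume/centroid), conical frusta
  emitted as two aligned regular m-gon rings (the hull is a polygonal
  frustum with exact closed-form volume `c·h(r1²+r1r2+r2²)/3`,
  `c=(m/2)sin(2π/m)`, converging to the smooth frustum as m grows;
  within 1% at m=64), and ellipsoids as deterministic Fibonacci surface
  clouds (hull volume below the ellipsoid volume by a stated empirical
  bound ~12·n^(−2/3)).
* **Body plans** — a box-built biped/quadruped stand-in (torso, two
  neck and two tail sub-segments, head, limb chains both sides) with
  acetabulum/glenoid landmarks and a neck pivot. Shapes are abstract
  volumetric stand-ins; no osteological realism is attempted.
* **Cohorts** — a pure-birth tree (general-sampling approach, so
  terminal branches are strictly positive and the Brownian covariance
  is non-singular), depth-scaled to 1. log10 body mass evolves by
  Brownian motion and is affinely rescaled to span 0.2 kg–60 t (an
  affine map of a Brownian sample is still Brownian). The measured
  trait is log10 torso length = intercept + slope·log10(mass) plus an
  independent Brownian deviation on the same tree — exactly the
  residual structure PGLS assumes, so recovery experiments are
  well-posed. Defaults: 53 taxa, slope 1/3, intercept log10(0.3)
  (torso ≈ 0.3·M^(1/3) m), deviation variance 0.0025 dex² per unit
  depth (≈12% scatter, a tight allometry). Each taxon's plan scale is
  solved (cubic) so analytic body volume equals mass/1000 kg m⁻³
  exactly, making volume a strictly monotone map of assigned mass.

Passing tests on these inputs demonstrate that the geometry, the mass
arithmetic, and the estimators are correct under their stated
assumptions. They do not show that the placeholder expansion factors,
the abstract body shapes, or the Brownian trait model describe real
dinosaurs — with real data, accuracy is bounded by the supplied
calibration coefficients and by the usual caveats of convex-hull
reconstruction (non-convex soft tissues, segment boundary choices,
shoulder-girdle placement).

All randomness flows from one integer seed through NumPy's PCG64
generator (and a seeded `random.Random` for tree shape); regeneration
is bit-identical for a given seed.

## Problem sizes and numerical choices

The bundled validation runs use a 14-segment reference skeleton, 16-taxon
cohorts for rank-agreement checks, and 200 replicate 64-tip cohorts for
the slope-recovery experiment (coverage checked against the nominal 95%
with binomial tolerance; observed ≈96.5% with |mean bias| < 0.001).
Monte-Carlo hull oracles use 10⁶ rejection samples and 3-SE tolerances.
Degenerate inputs fail loudly rather than silently: coplanar segments,
coincident landmarks, missing densities or factors, singular
covariances, and zero AP GA distances are all hard errors; near-zero DV
GA distances and zero-length terminal branches degrade gracefully with
warnings.

## Known limitations

* No mesh repair, articulation, or scan processing; the manifest's pose
  is taken as given, with posture provenance recorded as free text.
* No alpha-shape alternative to convex hulls.
* Expansion-factor refitting from extant CT data is out of scope; the
  factor table is a consumed input.
* Trees are consumed pre-dated (Newick with branch lengths); no
  time-scaling is performed.
* Reposing moves point masses, not meshes: hull shapes are frozen in
  the reference pose.
* PGLS offers Brownian covariance only; whole-body uncertainty bounds
  are simultaneous (conservative) rather than probabilistic.
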