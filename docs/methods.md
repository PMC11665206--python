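# Methods

## The analysis model

`svef3d` quantifies regional LV function from a closed, consistently
oriented triangulated endocardial surface tracked over one cardiac cycle.
The pipeline assumes (i) one cycle per input with a single systolic
extremum, (ii) a landmark initialisation of four mitral-annular points, an
apical point and a mid-septal point, and (iii) that the cavity is closed at
the mitral annulus.  It makes no assumption about cavity shape: volumes come
from a signed tetrahedral decomposition, not from an ellipsoid or Simpson
rule.

### Coordinates and the 17-segment partition

The long axis runs from the annulus centroid to the apex; `u ∈ [0,1]` is the
normalised projection onto it.  The circumferential angle θ is measured
right-handed about the axis and anchored on the mid-septal landmark, which
maps to θ = 270° by a fixed offset; under this convention the anterior wall
is centred on θ = 90°.  Longitudinal bands are equal thirds (basal
u < 1/3, mid < 2/3, apical < u_cap), with the apical cap above u_cap = 0.85 —
the 17-segment standard defines the cap only qualitatively, and a fixed
fraction keeps it non-empty at any resolution.  Basal and mid rings split
into six 60° sectors with boundaries on multiples of 60°; the apical ring
into four 90° sectors with boundaries at 45° + k·90°, which centres the
apical anterior segment on the anterior direction (centring was preferred
over boundary alignment with the six-sector grid; the two are mutually
exclusive and centring matches the standard display).  A face belongs to the
segment containing its centroid, which makes the 17 face sets an exact
partition of the surface; area-weighted boundary splitting is available
behind a flag but is not the default because the centroid rule keeps volume
bookkeeping exact.  Both the θ offset and u_cap are configurable arguments
for other display conventions.

### Volumes

Every surface triangle forms a signed tetrahedron with a common apex at the
long-axis midpoint; segment volumes are the per-segment sums and the cavity
volume their total, converted mm³ → mL.  For a closed surface the total is
apex-independent; placing the apex on the axis makes each segmental partial
sum the volume of cavity subtended between that wall patch and the axis, so
the values are individually meaningful and sum to the cavity volume to
machine precision by construction.  Meshes failing the closed/oriented check
(each directed edge matched by exactly one reverse edge) are rejected with
the offending edge named.  The annulus cap disc is apportioned to basal
segments by θ.

### SVEF and the cutoff

Per-segment EDV/ESV are the frame-wise max/min of that segment's own curve —
no common ED/ES instant is imposed and no smoothing is applied (an optional
moving-average flag exists but defaults off; "largest and smallest" is the
definition, and smoothing would silently change it).  Ties resolve to the
earliest frame.  The global EF uses the identical rule on the summed curve.

Lower SVEF means more abnormal, so the ROC machinery treats abnormal as the
positive class with sensitivity = P(score < c | abnormal) and specificity =
P(score ≥ c | normal), the same ≥/< split used to tag bull's-eye segments.
AUC is the Mann–Whitney statistic with midrank ties; the operating point
maximises Youden's J over midpoints of adjacent distinct scores (criterion
ties resolve toward higher specificity; a closest-to-corner criterion is
selectable).  The AUC interval uses the Hanley–McNeil standard error — a
deliberate, documented choice among the several asymptotic variants.

### Culprit-artery prediction

Abnormal patterns are matched against the typical ASE/EACVI territory
templates by Jaccard similarity |abnormal ∩ template| / |abnormal ∪
template|; the argmax is the prediction.  Jaccard replaces the human
reader's visual judgment with a symmetric rule that penalises both missed
and extra-territory segments; a coverage rule (|∩|/|abnormal|) is available.
Ties and empty abnormal sets return "indeterminate" rather than a forced
pick — genuine ambiguity concentrates at the apex and septum and should
surface as such.  Templates are configurable (JSON) for dominance variants.

### Agreement statistics

Cohen's κ carries Po and Pe as exact rationals until the final division; its
CI uses the full Fleiss–Cohen–Everitt asymptotic variance rather than the
agreement-only approximation.  The default ICC form is ICC(2,1) — two-way
random effects, absolute agreement, single measures — the conservative
choice for two observers measuring the same quantity; ICC(3,1) and ICC(1,1)
are selectable, with F-based intervals.  Bonferroni adjustment multiplies
raw pairwise p by the number of comparisons and caps at 1.

## The phantom

The generator emulates a 3D full-volume acquisition at the level the
pipeline consumes: a truncated prolate spheroid (half-ellipsoid, base radius
25 mm, long axis 80 mm) closed by a flat annulus disc, sampled at 17 frames
over a 1-second cycle (17 Hz, a typical full-volume frame rate), deforming
radially as `r(θ,z,t) = R(z)·(1 − A·s(θ,u)·g(t))`.

- `g(t)` is a half-sine over the cycle — patient volume curves are not
  specified beyond having one systolic extremum, so the simplest smooth
  waveform with g(0)=g(T)=0 and a single peak is used.  Because only radii
  scale, the uniform phantom obeys V(t) = V_ED·(1−A·g(t))² and the global EF
  has the closed form 1−(1−A)²; the default amplitude A = 0.30 gives EF = 51%,
  a plausible post-ischemic value.
- `s(θ,u)` is the severity field: `rwma_severity` on the configured
  territory's segments, 1 elsewhere.  The per-vertex field is eroded by one
  vertex (minimum over the 3×3 index neighbourhood) so border vertices move
  with the weaker side — the discrete analogue of infarct-border tethering.
  Without erosion, faces inside an akinetic segment share moving vertices
  with normal neighbours and the segment is never truly motionless; with it,
  a severity-0 territory's interior curves are constant to machine precision
  and the contamination burden falls on thin slivers of the *normal*
  neighbours instead.  A cosine taper (default 10° wide, configurable to 0
  for hard edges) additionally blends the field circumferentially; the taper
  is applied in θ only, since longitudinal band borders contribute an order
  less shear on this geometry.
- `noise_sd` adds Gaussian vertex jitter per frame.  The flagship recovery
  tests use 0.5 mm — sub-millimetre surface-tracking noise — so that seeds
  produce genuinely different meshes.
- Ring sampling is uniform in the ellipse's eccentric angle, keeping facet
  sizes even from base to apex; the ED cavity volume converges to the
  half-ellipsoid closed form (2/3)πLR² from below as resolution grows,
  reaching 0.35% at 48×32 and <0.1% at 96×64.

The SVEF population sampler draws from two Gaussians — 320 normal segments
at 52.7 ± 15.0% and 241 abnormal at 35.5 ± 14.4%, the packaged group
moments — truncated to [0, 100].  Under this binormal model the closed-form
AUC is Φ(17.2/√(15²+14.4²)) = 0.796 and the density-crossing (Youden)
threshold is 44.4%, which is what the simulation-based acceptance targets
recover.

### What the phantom does not emulate

No ultrasound physics: no speckle, dropout, trabeculation or endocardial
detection error beyond isotropic vertex jitter; no myocardial thickness
(endocardial surface only); no translation or torsion of the ventricle; no
beat-to-beat variability, arrhythmia or multi-vessel disease patterns.
Passing tests therefore demonstrate that the *analysis* is correct and
well-conditioned, not that real acquisitions of a given quality will reach
the same operating characteristics; patient-level sensitivities,
specificities and observer reliabilities cannot be reproduced from synthetic
data and are not asserted anywhere in the suite.

## Numerical choices and degenerate inputs

- Units: mm in, mL out (mm³/1000); scores in percent.
- Segment curves reuse the frame-0 facet map across the cycle (topology is
  guaranteed constant; the deformation never moves a centroid across a
  sector border by more than the taper width).
- Open or inconsistently oriented meshes, single-point traces, non-positive
  EDV, single-class ROC inputs, empty strata, zero between-item variance
  (ICC) and single-category κ tables all raise informative errors rather
  than returning NaN; an all-constant ANOVA returns F = 0.
- Candidate ROC cutoffs include sentinels below and above all scores, so
  "tag everything" and "tag nothing" are admissible operating points.
- Bull's-eye SVGs are byte-deterministic (pinned hash salt, no timestamp).

## Problem sizes

Tests run the phantom at 24–48 circumferential × 16–32 longitudinal
vertices and 17 frames (the geometry-oracle checks at 96×64, the
conservation sweep at coarse resolutions across 100 random configurations),
and the ROC simulation at the published class sizes (561 scores) over 20
seeds — sizes chosen so the full suite exercises every path in seconds
while the asymptotic checks still sit in their convergent regimes.

## Known limitations

- The segmental partition is an open reimplementation of the 17-segment
  standard on explicit meshes; proprietary workstation partitions differ in
  unpublished details, so patient-level numbers from such software will not
  be matched segment for segment.
- Sharp-edged (taper 0) severity fields still leak a thin sliver of motion
  across the mismatched θ-spans of apical vs basal/mid sectors; akinetic
  *border* segments read up to ~2% SVEF at default resolution (interior
  segments read exactly 0).
- κ confidence intervals are asymptotic and can be wide or boundary-clipped
  for the 3×3 tables typical of small cohorts; they are reported as
  computed, with no exact small-sample method.
- Model 2 (EF-normalised) scoring assumes global EF > 0 and inherits its
  instability for near-zero EF subjects.
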