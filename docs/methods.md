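# Methods

This note records the models the package implements, the defaults it
ships, and the design choices that were genuinely open — in enough
detail that a maintainer can tell which behaviours are clinical
convention, which are this package's own decisions, and what the
synthetic tests do and do not demonstrate about real data.

## Geometry and delineation

Volumes are 3D scalar grids of body-weight standardized uptake values
(SUV_bw, dimensionless), indexed `(x, y, z)` with 0-based indices; a
voxel's world coordinate is `origin + index * spacing` (mm). Masks and
label maps always live on the PET grid. In-plane spacing defaults to
4.07 mm (typical of the clinical reconstructions this emulates); slice
thickness is not fixed by convention, so the default is 3.0 mm,
configurable. NIfTI-1 is the interchange format, with a diagonal affine;
orientation rotations are not interpreted.

Delineation follows the semi-automated clinical procedure: threshold the
volume at SUV 3, take connected components, remove physiologic uptake,
insert lesions the threshold missed. Decisions made here:

* **Threshold comparison is inclusive (≥ 3).** The clinical description
  does not say; inclusive keeps boundary voxel sets stable on phantoms
  whose profiles cross the threshold at exact radii.
* **Connectivity defaults to 26** (full 3D neighbourhood), the usual
  choice for PET lesion counting; 6 and 18 are available.
* **Component labels are deterministic**: descending voxel count, ties
  broken by the lexicographically smallest member voxel. Nothing
  downstream may depend on library-internal label order.
* **Physiologic removal is component-wise**: a component is removed when
  ≥ 50% of its voxels (configurable fraction) fall inside the union of
  exclusion regions. A human editor erases organs as wholes; a voxelwise
  subtraction would leave rims.
* **No minimum lesion size by default** — the emulated procedure states
  none; a configurable voxel floor exists for noise-robustness
  experiments.
* An addition overlapping an exclusion is a hard error (the edit script
  contradicts itself), not a precedence rule.

## Lesion matching across timepoints

Clinically, "new lesion" is a reader judgement with no published
algorithm, so the matching rule is this package's own. A baseline and a
follow-up lesion are match candidates when the follow-up lesion overlaps
the baseline lesion dilated by 1 voxel, *or* their centroids are within
10 mm; candidates are assigned greedily by descending overlap (ties:
smaller centroid distance, then smaller label pair). Follow-up lesions
left unassigned are new. The dilation absorbs growth/shrinkage and
sub-voxel repositioning; the 10 mm gate (about two in-plane voxels)
rescues near-misses without ever bridging anatomically distinct sites,
which are tens of millimetres apart. Timepoints are assumed rigidly
co-registered in world coordinates — the generator guarantees this, and
registration of real scan pairs is out of scope. Disappeared baseline
lesions do not influence the classification; only ΔTTV and new lesions
do.

## RECIP rule engine

TTV is delineated voxel count × voxel volume; ΔTTV = 100 ×
(follow-up − baseline)/baseline. Edge cases: baseline 0 → follow-up 0 is
0%; baseline 0 with positive follow-up is *undefined* and flagged, and
treated downstream as exceeding any positive cutoff (every lesion is
new, so such patients classify PD). Published statements of the rule table and the
accompanying counts disagree about boundary strictness at +20% and −30%;
the counts imply inclusive boundaries, which are the default
(`RecipPolicy` exposes both). Classification always uses unrounded
values; presentation rounds volumes to 2 dp and percentages to 1 dp.

## Survival statistics

Kaplan–Meier, the unstratified 1-df log-rank test, and the univariate
Cox partial-likelihood fit are delegated to lifelines; the input
contract is months since the follow-up scan, event = 1 for death. Tie
handling is Efron (the default of the software this field uses); CIs and
p-values are Wald. "Median OS not reached" is a first-class value
(`math.inf`), since heavily censored cohorts rarely reach S(t) = 0.5.
Harrell's C is implemented directly from the pairwise definition (a pair
is comparable when the shorter observed time ended in death; risk ties
count ½) and cross-checked against lifelines in the tests. Degenerate
fits — constant covariate, an eventless covariate level (monotone
likelihood), non-convergence — raise diagnostic errors rather than
returning implausible numbers; the cutoff sweep records such errors per
row and continues.

## Agreement statistics

Cohen's κ on the 2×2 PD table uses the closed form with marginal-product
chance agreement; interpretation bands are upper-inclusive at 0.20 /
0.40 / 0.60 / 0.80. Percent agreement is reported overall and
conditioned on each of rater 1's classes (overall is their row-weighted
mean). Spearman correlation uses mid-ranks. The ΔTTV threshold sweep
dichotomises at {0, 10, 20, 30, 40, 50}%: cutoff 0 means *any* increase
(strict > 0), all others are inclusive ≥, and undefined ΔTTV exceeds
every cutoff; per-cutoff κ compares the two raters' dichotomisations of
ΔTTV alone (not the full RECIP class).

## The synthetic cohort

The generator's defaults are the study conditions, not tuning knobs:
199 patients, scans a median 6 months apart, 13.1% intended RECIP-PD
prevalence, true hazard ratio 3.78 for progressors, administrative
censoring at 75.4 months.

* **Phantoms.** 96×96×128 voxels at 4.07×4.07×3.0 mm. Background is
  clipped Gaussian noise (mean 0.4, SD 0.12 SUV) — far below threshold,
  so delineation noise comes only from lesion geometry. Lesions are
  isotropic Gaussian peaks whose SUV-3 isocontour sits exactly at the
  specified radius, composited by voxelwise maximum; a supra-threshold
  lesion's thresholded voxel set therefore equals its geometric sphere,
  which makes target volumes constructible by brute-force voxel counting
  (`radius_for_volume`). Sub-threshold lesions (peak < 3) exist in the
  truth but are invisible to thresholding. Organs (bladder, kidneys) are
  bright distractor blobs with known exclusion spheres.
* **Evolution.** Each lesion's volume is scaled by its growth factor
  between scans (radius by the cube root); factor 0 removes it;
  follow-up-only lesions implement new disease. Intended classes are
  realised with margins that dominate voxelisation error: PD growth
  ×1.5–3.0 plus one new lesion; SD ×0.8–1.1; PR ×0.35–0.55; CR removes
  everything. About a third of progression-defining new lesions are
  sub-threshold — the mechanism by which an automated reader can miss
  progression.
* **Observers.** The *manual* reader is emulated mechanically: threshold
  + organ exclusions + insertion of sub-threshold truth lesions. The
  *degraded* observer drops sub-threshold lesions with probability 0.85,
  optionally jitters boundaries (default off — a one-voxel shell is a
  large volume fraction at this resolution and would dominate the
  intended failure mode), and adds Poisson(0.15) small false-positive
  foci per scan.
* **Survival.** Exponential proportional hazards: hazard λ₀ = ln 2 /
  236.3 months for non-progressors — chosen so the progressor arm's
  marginal median OS is 62.5 months under HR 3.78 — times 3.78 for
  progressors; censoring uniform on (58.0, 75.4) months, giving a median
  follow-up near 67 months and heavy (~75–80%) censoring. Survival is
  keyed to *intended* classes, so estimator recovery can be checked
  against known truth. The Cox model is semi-parametric, so any
  proportional-hazards generator is a fair recovery target.
* **Determinism.** All randomness flows from one run seed through
  spawned child sequences; patients are streamed (rendered, classified,
  discarded) so a full cohort fits comfortably in memory.

What the phantoms do *not* model: PET physics (scatter, partial-volume,
reconstruction texture), inter-scan misregistration, treatment effects
between scans, or reader variability beyond the step miss/false-positive
model. Passing tests therefore demonstrate the correctness and
calibration of the *analysis* — not segmentation performance on real
scans.

## Problem sizes and numerics

The default test suite runs one full 199-patient, two-rater cohort
(about three minutes on one CPU), 2000 null replicates for log-rank
type-I calibration, and 500 replicates for hazard-ratio recovery; unit
tests use ≤ 64³ grids. Cox convergence failures surface as diagnostic
errors; the mean *fitted* HR over replicates sits slightly above the
generator value (Jensen's inequality on exp of an approximately unbiased
log-HR), well within the 10% recovery tolerance at this event count.
Small cohorts can legitimately draw zero progressors under the binomial
prevalence; the generator flags this as a degenerate draw instead of
silently producing a single-group cohort.

## Known limitations

* The lesion-matching rule is principled but unvalidated against reader
  behaviour; its parameters (1-voxel dilation, 10 mm gate) are exposed.
* The manual-reader emulation is mechanical and error-free by
  construction; real readers disagree with themselves.
* The exponential outcome model has constant hazards; recovery checks
  would not detect misspecification sensitivity of real-world Cox fits.
* NIfTI orientation matrices beyond axis-aligned diagonal affines are
  not supported.
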