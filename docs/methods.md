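# Methods

This note documents the models, the defaults and the numerical choices, and
what the synthetic validation does and does not establish.

## Volumes and grids

All volumes live on one axis-aligned RAS grid (`VolumeGrid`): world
coordinates are `origin + index * spacing`, x > 0 is the right hemisphere.
NIfTI-1 I/O goes through nibabel; masks are stored as uint8 0/1, scalar
maps as float32. Grids are compared with tolerances of 1e-6 mm on spacing
and 1e-3 mm on origin (float-header round-trip noise); shapes must match
exactly. Inputs with non-diagonal affines are rejected rather than
resampled — registration is out of scope, inputs must already share a grid.
Hemisphere masks exclude voxels whose centre lies within half a voxel of
x = 0, so left and right are disjoint by construction and the midline band
belongs to neither. Gaussian smoothing uses per-axis sigma
`fwhm / (2·sqrt(2·ln2)) / spacing` with reflective boundaries: deterministic
and near-mass-conserving away from edges.

## Figure scoring

The whole-figure score sums presence, shape and placement points over 15
units plus presence and shape for the middle square (maximum 47). The
global/local decomposition grades presence only: 6 global features, 14
local features, each score expressed as a percentage of its maximum before
modelling, because the maxima differ.

The two schemes overlap non-trivially: 16 scoreable units versus 20
global/local features. The shipped registry (`data/figure_registry.yaml`)
resolves this by letting each unit own 1–3 features; the left double-bars
unit and the right triangle unit own a global whole-feature plus two local
sub-features, and those rows are flagged `ambiguous` in the data rather
than silently merged. Feature presences are recorded independently (a rater
may credit the triangle's sides without crediting the triangle as a global
shape); unit-level credit for the 47-point score is read from the unit's
primary feature. The registry is data, re-validated at load (16 units,
15 + 1 scoring split, 6/14 feature split, maximum 47), so alternative
mappings can be supplied without touching code.

## Lesion delineation

Per voxel, the patient value is compared to the control sample with the
Crawford–Howell single-case t (df = n−1), which inflates the denominator by
`sqrt((n+1)/n)` to account for the control sample being small; a naive z
against the sample sd is anti-conservative at n ≈ 20. Degenerate voxels
(control sd below 1e-6 of the mean sd) report t = 0 and are counted in the
delineation report rather than silently passed through.

The binarization threshold is configuration, not a constant: the default is
the one-tailed critical t at p = .01 with df = n−1, hypointense tail
(ischemic tissue is dark on CT; a two-sided option exists). An optional
connected-component filter (26-connectivity, default off) removes
speckle-sized detections; at high lesion contrast the residual errors of
delineation are exactly such isolated false positives, so the calibration
studies enable it at 10 voxels.

## Synthetic cohorts

The generator emulates the structure the inference assumes, not CT physics:

* **Controls** — one shared smooth "anatomy" field (mean ≈ 100 a.u.,
  sd ≈ 8, strictly positive) plus per-subject i.i.d. Gaussian noise
  (sd 2 by default).
* **Lesions** — sharp hypointense ellipsoids (semi-axes uniform in
  8–24 mm, intensity drop 20 a.u.), one per patient, centred near a
  randomly chosen tract's centerline with 3 mm jitter; half the patients
  (configurable) are aimed at the designated effect tracts. Sharp edges
  buy an analytic volume for testing; real lesions have partial-volume
  gradients the delineator would blur over.
* **Tracts** — Gaussian tubes around polyline centerlines, value
  `peak · exp(−d²/(2(r/2)²))`, peak 0.9, nominal radius 10 mm; six
  mirrored association-pathway pairs at distinct lateral/axial stations.
  The canonical 16-pathway inventory remains the Bonferroni reference
  regardless of how many maps a synthetic cohort carries.
* **Behaviour** — per outcome,
  `score = clip(baseline − Σ w_t·disc_t − 0.15·lesion_cc − 0.08·(age−72) + ε, 0, 100)`
  with ε ~ N(0, noise_sd²), ages N(72, 13²), baselines 88% (global) and
  86% (local) — anchored to the demographics and score means typical of
  sub-acute stroke cohorts on this task. The default dissociation puts
  weight 8 on the left IFOF for the local score and 8/6 on the right
  SLF III / right long perisylvian segment for the global score
  (%-points per cm³). Weights were fixed from an a-priori power sketch
  targeting |t| ≈ 5 for a designated tract at n = 60, noise sd 5.
* **Randomness** — one stream per subject derived from
  (seed, stream-kind, index), so adding patients never perturbs existing
  ones; everything is a pure function of the spec and seed.

Ground-truth disconnections are computed by the disconnection module itself
on the true masks, so generator truth and measured overlap agree
voxel-exactly by construction — the tests exploit this to pin the
delineation-induced error separately.

## Disconnection and track-wise inference

Tract maps are normalized to [0,1] at load (files on a percent scale are
divided by 100, detected by max > 1) and thresholded **inclusively** at 50%
to the anatomical core. Overlap is in cm³; "disconnected" for descriptive
percentages means any shared voxel (a configurable minimum exists).

Per tract, OLS of the outcome on [disconnection, lesion volume, age], with
a control model adding both visual-field miss counts. The reported
coefficient is the standardized β = slope·sd(x)/sd(y) of the disconnection
predictor, with the two-sided t-test p. Significance is the strict
inequality p < 0.05/16 = 0.003125 — the unrounded threshold, so a p
printing as .003 passes. Tract columns with zero overlap variance are
skipped with a reason, not fitted, and still count toward the family (the
test count is the atlas inventory, not the number of converged models).
Rows with missing cells are dropped listwise. Note the sign convention:
with deficit coded as a percentage score (higher = better), deficit
predictors carry negative β.

**Per-hemisphere sample restriction.** Each hemisphere's run is restricted
to patients with damage in that hemisphere (laterality columns computed
from the lesion masks). This is not cosmetic: in a cohort mixing left- and
right-lesioned patients, overlap with a right tract is a proxy for *not*
being left-lesioned, which predicts better local scores and manufactures
strongly significant "protective" cross-hemisphere associations. Restriction
removes the mixture artifact; the calibration study verifies crossed flags
then sit at chance. A related, weaker artifact survives *within* a
hemisphere: overlapping a ventral tract implies the lesion spared the
dorsal effect tract, which can produce positive-β (protective-sign) flags
for anatomically complementary tracts. These are genuine associations of
the lesion-anatomy mixture, not false positives of the test; readers of
per-tract tables should interpret positive-β flags accordingly.

## Voxel-wise GLM

The mass-univariate fit is closed-form vectorized OLS (β = (XᵀX)⁻¹XᵀY per
voxel; t = cᵀβ / sqrt(s²·cᵀ(XᵀX)⁻¹c)); a per-voxel statsmodels loop is kept
as the test oracle. Inputs for synthetic runs are the 12-mm-smoothed binary
lesion maps — a lesion-density stand-in for segmented grey matter that
preserves the inference structure without a segmentation model. The design
is intercept + global % + local % + age + sex (M=1) + handedness (R=1) +
lesion volume, checked full rank; contrasts are one-sided in the deficit
direction by default (sign −1 on a score column).

Clusters form at the one-sided critical t of voxel p = .001 and survive at
≥ 800 mm³ (100 voxels on the 2 mm grid); connectivity defaults to 26.
Cluster-level correction is by Freedman–Lane permutation: the nuisance-only
model is fitted once, its residuals are row-shuffled and added back to the
nuisance fit, and each observed cluster's corrected p is
`(1 + #{perm max cluster ≥ observed}) / (1 + n_perm)` — exact under
exchangeability, smallest attainable p = 1/(1+n_perm), deterministic given
the seed. This replaces random-field-theory cluster p-values, whose
smoothness estimation is deliberately out of scope.

## Calibration studies (what passing shows, and what it does not)

`hodomap.studies` packages four seeded simulation studies, shared by the
analysis drivers, the test suite and `scripts/acceptance.py`:

* **Lesion recovery** — a 10-control-sd ellipsoid at 20 controls, noise
  sd 1: Dice ≥ 0.8 demanded, ≈ 0.99 observed; a lesion-free patient's
  two-sided |t| exceedance at p = .01 sits inside binomial bounds of 1%.
* **Track-wise null calibration** — 200 effect-free cohorts whose nuisance
  structure (overlaps feeding lesion volume, lesion volume and age feeding
  the outcome) exercises the covariate adjustment: pooled rejection rate at
  0.003125 within binomial 95% bounds.
* **Lateralized recovery** — 50 replicates of the default cohort: each
  designated tract flagged for its own outcome in ≥ 90% of replicates
  (≈ 98–100% observed), crossed hemisphere/outcome flags at chance.
* **Permutation validity/power** — pure-noise images give
  `P(min cluster p ≤ α) ≤ α`; a planted effect at 3× the noise sd, n = 40,
  200 permutations, is corrected-significant at p ≤ 0.01.

Passing these establishes internal statistical validity under the
generator's assumptions: sharp single lesions, Gaussian i.i.d. noise, a
linear deficit model, tracts that are smooth tubes, and perfect
registration. It does not establish performance on real CT (partial-volume
edges, scanner artifacts, registration error, multifocal damage) or for
atlases whose cores overlap each other substantially. The printed patient
statistics of any real cohort are likewise outside what the synthetic demo
can or does reproduce; the demo reproduces the qualitative lateralized
dissociation, by design.

## Study sizes and runtimes

Default problem sizes are desk-scale by design: a 40×48×40 grid at 2 mm
for cohorts, 32³ for the delineation study, 12³–16³ for permutation
studies; 50 recovery replicates, 200 null cohorts, 100–200 permutations.
The full test suite runs in about a minute and the acceptance script in
under one.
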