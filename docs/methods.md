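# Methods

`radpipe` implements a complete PET-radiomics outcome-modelling study as a
reusable pipeline: simulation of FDG-PET tumour phantoms and
outcome-linked cohorts, extraction of a 1404-dimensional radiomic feature
vector, intraclass-correlation (ICC) screening of feature robustness under
three perturbation factors, and prognostic logistic modelling of binarized
event-free survival (EFS) and overall survival (OS).  This note documents
the models, the conventions chosen where several defensible options exist,
and what the synthetic data can and cannot show.

## Image model and preprocessing

Volumes are 3D scalar grids with physical voxel spacing; axis order is
(x, y, z) and voxel (i, j, k) is centred at `origin + (i, j, k) * spacing`.
PET volumes carry standardized uptake values (SUV), CT volumes Hounsfield
units (HU).

Preprocessing follows the standard PET radiomics chain:

1. **Resampling** to cubic 5.5 mm voxels with trilinear interpolation.
   Output voxel centres are laid on the input centre lattice starting at
   the origin, so a volume already on a conforming grid passes through
   unchanged and linear fields are interpolated exactly.
2. **Mask resampling**: the 0/1 indicator is interpolated trilinearly and
   re-binarized at 0.5 (approximately volume preserving); nearest-neighbour
   is available via `ExtractionConfig.mask_interp`.  The binarization
   threshold is inclusive (`>= 0.5`).
3. **HU exclusion**: mask voxels whose (resampled) CT value falls outside
   −300..200 HU are removed, excluding lung-like and bone-like tissue.
   Both bounds are inclusive.
4. **Size gate**: regions smaller than 72 voxels after resampling and HU
   exclusion are excluded (wavelet-domain texture on smaller regions is
   not meaningful).  Gated-out cases produce an explicit exclusion record.
5. **Discretization**: fixed bin size of 0.25 SUV, bins anchored at SUV 0
   with left-closed intervals, i.e. bin index `floor(v / 0.25) + 1`.  A
   common anchor is what makes fixed-bin-size features comparable across
   patients.  Wavelet coefficients can be negative, so each subband is
   shifted by its ROI minimum before the same fixed-bin discretization.
   Negative SUV inside the ROI (possible only through interpolation) is
   clamped to bin 1 with a warning.

The order of operations — resample, then HU-exclude, then gate, then
discretize — is a package decision; the 72-voxel gate is defined on the
resampled grid.

## The 1404-feature roster

The feature vector concatenates 18 shape + 17 intensity + 137 texture
features on the SUV ROI, plus the same 17 + 137 on each of 8 undecimated
Haar subbands (8 × 154 = 1232), for 1404 in total.  Only the family
*counts* are normative; the exact rosters below are this package's
documented choice, IBSI-aligned in naming and definition.

**Shape (18)** — voxel count, voxel-counted volume, mesh surface area,
surface-to-volume ratio, sphericity, two compactness variants, spherical
disproportion, equivalent spherical diameter, maximum 3D diameter,
major/minor/least principal axis lengths, elongation, flatness, and the
three bounding-box extents.  The surface mesh is a marching-cubes surface
of the indicator anti-aliased with a half-voxel Gaussian: the mesh of a
*binary* mask overestimates the area of a digital ball by roughly 8 % at
any radius (staircase facets), which would cap sphericity near 0.92; with
the anti-aliased mesh, sphericity of digital balls approaches 1 as the
radius grows.  Sphericity-type indices use the mesh volume; the volume
*feature* remains voxel-counted (`n × spacing³` exactly).  Masks too small
for the smoothed field to reach the 0.5 level fall back to the binary
mesh.  Degenerate single-voxel masks define elongation = flatness = 1.

**Intensity (17)** — mean, (population) variance, skewness, excess
kurtosis, median, minimum, maximum, range, 10th/90th percentiles,
interquartile range, energy, root-mean-square, mean absolute deviation,
histogram entropy and uniformity (on the 0.25-SUV fixed-bin histogram),
and coefficient of variation.  Constant ROIs define skewness, kurtosis and
CV as 0 rather than NaN.

**Texture (137)** — built on the discretized ROI over 26-connected 3D
neighbourhoods at distance 1 (13 unique directions):

| matrix | features | aggregation |
|---|---|---|
| GLCM | 25 | per-direction average **and** direction-merged (50) |
| GLRLM | 16 | per-direction average **and** direction-merged (32) |
| GLSZM | 16 | single (zones are direction-free) |
| GLDZM | 16 | single; zone distance = city-block distance to the ROI edge (edge voxels have distance 1; the image border counts as outside) |
| NGTDM | 5 | single |
| NGLDM | 18 | single; dependence counted at grey-level tolerance 0, matrix column k = dependence count + 1; the 18th feature is the mean dependence count |

Degenerate cases are defined, not NaN: a single-grey-level ROI has GLCM
joint entropy 0 and correlation 0; directions without any voxel pair are
skipped when averaging.  All matrices are probability-normalized before
feature evaluation.

**Wavelets** — one-level undecimated separable Haar transform; subband
labels give the per-axis filter in axis order (x, y, z), so "HHL" is
high-pass along x and y, low-pass along z.  The low-pass is normalized to
unit gain (taps ½, ½), making the LLL band of a constant volume that
constant and giving exact energy conservation across the 8-band bank under
periodic boundary handling; the default boundary mode is symmetric
reflection.  Because the transform is undecimated, subbands live on the
same grid as the input and reuse the ROI mask unchanged.

## Synthetic data

No public imaging accession backs the pipeline, so phantoms and cohorts
are simulated with known ground truth.

**Phantoms.**  An ellipsoidal tumour (default radii 24 × 21 × 18 mm,
~230 voxels at 5.5 mm — comfortably above the 72-voxel gate; a documented
"small" preset at 11 × 10 × 9 mm falls below it) on a uniform background
(SUV 0.4), on a 64 × 64 × 48 grid at 2.73 × 2.73 × 3.27 mm, mimicking
clinical PET reconstruction grids.  Tumour uptake is a Gaussian random
field (correlation length 12 mm) scaled to mean SUV 5 ± 1.5 and clipped at
0 — heterogeneous uptake is what gives texture and wavelet features
between-patient variance.  The CT assigns −700 HU outside the tumour
(lung), +40 HU inside (soft tissue) and a 9 mm bone-like ball (+700 HU) on
the mask boundary so the HU-exclusion rule is always exercised.
Everything is deterministic under the spec's seed.

**Perturbation factors.**  Three operators emulate the classic paired
robustness designs; real paired scans differ in ways no parametric
perturbation fully captures, so default magnitudes are calibrated only to
reproduce the qualitative family ordering (shape least stable under
re-delineation; wavelets least stable under attenuation bias and motion
blur), never any particular stability percentage:

* *Delineation*: three ROI definitions — the true mask with a seeded
  one-voxel dilation on a random half of its boundary (a proxy for a human
  re-contour), the 26-connected region above a per-patient threshold of
  27–41 % of SUVmax grown from the tumour centre, and a sphere at the
  radius of maximal mean SUV-gradient magnitude.
* *Attenuation*: a positive multiplicative bias field with a smooth
  large-scale component (25 mm) and a weaker fine-scale component (6 mm)
  standing in for the locally sharp errors MR-based attenuation correction
  makes near tissue boundaries; the field is re-centred to mean zero over
  the ROI so mean tumour uptake is preserved.
* *Motion*: anisotropic Gaussian blur, dominant along z, emulating
  free-breathing averaging; the unblurred volume plays the gated role.
  The blur is linear and mass preserving up to grid-boundary truncation.

In the robustness studies each patient draws its own threshold, bias field
and blur width — patient-specific perturbation is what moves the
*consistency* ICC forms, which are invariant to any common rescaling.

**Cohorts.**  Per patient a phantom with randomized radii, uptake and
heterogeneity is generated and its features extracted; the probability of
an event by the horizon is `logistic(intercept + Σ coeff × standardized
feature)` on named extractor features (default: wavelet
coefficient-of-variation and skewness features, mirroring the prognostic
role of uptake heterogeneity).  Event times are exponential with the rate
calibrated so `P(T ≤ horizon)` equals that probability — the simplest
model consistent with a binarized endpoint; censoring is an independent
exponential calibrated to the requested censoring fraction.  OS events are
generated from the same linear predictor with a −0.7 intercept shift
(deaths are rarer than events).  The cohort ground truth stores the linear
predictors and the *design AUC* — the exact pairwise probability that a
case's predictor exceeds a control's.

A fast **tabular generator** serves model-recovery studies where image
simulation would be needlessly slow: three latent standard-normal factors
drive a logistic outcome (per-factor log-odds 0.6125, giving an asymptotic
design AUC of 0.75), each factor expressed by a block of noisy copies.
Block sizes (6, 5, 4) and loadings (0.95, 0.90, 0.85) differ across
factors deliberately: equal blocks have nearly equal correlation
eigenvalues, and sample principal components then mix blocks, which is an
identifiability failure of the grouping step rather than of the generator.

What the synthetic data does *not* emulate: scanner physics (scatter,
reconstruction, partial volume), true respiratory waveforms, human
contouring behaviour, inter-scanner variation, or correlated clinical
covariates.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its qualitative behaviour matches the known
phenomenology — not that any particular clinical stability percentage or
AUC would be reproduced on real data.

## Robustness screening

For each feature, conditions play the role of raters in a subjects ×
raters ANOVA.  Three Shrout–Fleiss forms are implemented from their mean
squares (BMS/WMS/EMS = between-subject, within-subject, residual):

* ICC(1,1) = (BMS − WMS) / (BMS + (k−1) WMS) — one-way random;
* ICC(3,1) = (BMS − EMS) / (BMS + (k−1) EMS) — two-way mixed consistency;
* ICC(3,k) = (BMS − EMS) / BMS — average-measures consistency.

Study-to-form mapping (configurable): delineation → ICC(1,1) (methods as
random raters), attenuation → ICC(3,1), motion → ICC(3,k) with k = 2.
A feature is **stable** when ICC > 0.9, strictly.  Conventions: an
all-identical matrix is perfect agreement (ICC = 1, with a warning);
negative ICCs are kept as computed and simply fail stability; missing
cells are an error.  The robust set is the intersection of the three
stable sets; the report also gives all 7 Venn region counts, overall and
per family.

## Prognostic modelling

* **Binarization**: event at or before the horizon → case; event-free
  follow-up reaching the horizon → control; censored before the horizon →
  excluded from that endpoint (option: treat as non-event).  Horizons 12,
  18 and 24 months are supported for both EFS and OS.
* **Dimension reduction**: Horn's parallel analysis retains components
  whose correlation-matrix eigenvalues exceed the rank-matched 95th
  percentile of eigenvalues of standard-normal data of identical shape
  (counted consecutively from the top; eigenvalues are computed through
  the smaller Gram matrix, so p ≫ n is cheap).  Each feature is assigned
  to the retained component with which it correlates most strongly
  (absolute correlation of the feature with the component score);
  zero-variance features go to a sentinel group and are excluded with a
  warning.
* **Univariable screening**: per group, the feature with the largest
  oriented Mann–Whitney AUC is the group surrogate (ties broken
  lexicographically); it becomes a candidate only if the Wald p-value of
  its single-feature logistic regression is < 0.05.  The Wald test is used
  because it matches the downstream logistic framework; under
  (near-)separation the Wald statistic collapses (Hauck–Donner), so
  standardized coefficients beyond ±10 are scored as maximally
  significant.
* **Backward AIC**: maximum-likelihood logistic regression on standardized
  candidates; the variable whose removal most decreases AIC
  (= 2k − 2 log L) is dropped until no removal decreases it.  Complete
  separation falls back to a ridge-penalized fit (flagged on the model).
  An empty candidate set yields the intercept-only model.
* **Cross-validation**: stratified 5-fold (seeded); the *entire* selection
  chain — parallel analysis, grouping, screening, backward AIC — is re-run
  inside each training fold to avoid selection leakage; the reported model
  is refit on the full training cohort.
* **Model choice**: best trade-off = maximize `cv_mean − λ · cv_range`
  with λ = 0.5 (configurable); ties fall to the higher mean, then
  lexicographic order.
* **External validation**: the frozen model's probabilities are scored on
  the validation cohort; the 95 % CI uses DeLong's method.
* **Risk stratification**: patients split at the training-cohort median
  predicted probability (the cutoff is reused verbatim on validation);
  Kaplan–Meier per group with right-censoring; group median survival is
  the first time the KM estimate drops to ≤ 0.5; the two-sample test is
  the Harrington–Fleming G-rho family (weights S(t)^rho), rho = 0 (the
  log-rank test) by default.
* **Prognostic overlap**: features with oriented univariable AUC > 0.6 in
  both cohorts, reported with the percentage stable against each factor
  separately; an empty prognostic set is flagged rather than divided by.

## Orchestration and reproducibility

`RunConfig` holds one master seed; every stage derives its own seed by
hashing `"{seed}:{stage}"` (SHA-256, truncated below 2³¹), so stages are
independently re-runnable and two runs with the same config produce
byte-identical outputs.  Every output file is accompanied by a
`.meta.json` sidecar carrying the config hash, the full config and the
package version.  Default problem sizes (10 robustness patients, 40 + 20
cohort patients, 100 parallel-analysis replicates inside the pipeline,
1000 when the function is called directly) are chosen so a full run
completes in minutes on one CPU while keeping every stage's statistics
meaningful; they are configuration, not constants.

## Known limitations

* The texture roster is a documented stand-in constrained to the printed
  family counts; other IBSI-compliant rosters of the same size exist.
* ICC confidence intervals and the absolute-agreement forms ICC(2,·) are
  out of scope.
* The ICC of a feature whose between-patient variance happens to be small
  in a 9–12 patient study is itself noisy; per-family stability
  percentages at this cohort size carry sampling error of several
  percentage points.
* Cox modelling, clinical covariates and calibration analysis are
  deliberately out of scope; endpoints are binarized.
* `dependence_count_percentage` is identically 1 under the package's
  dependence convention (every ROI voxel has a dependence count); it is
  kept for roster compatibility and flagged stable by the all-identical
  convention.
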