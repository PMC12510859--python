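# Methods

This note documents the modelling assumptions, parameter defaults and
numerical choices behind `deltazone`, and what the synthetic validation does
and does not demonstrate.

## Problem setting

Grade ≥2 radiation pneumonitis (RP) is modelled as a binary outcome of
thoracic radiotherapy. The predictive information is drawn from three
sources: (i) the longitudinal change of CT texture inside dose-gradient
lung zones between the planning scan CT₁ and a mid-treatment resetting scan
CT₂; (ii) clinical covariates, chiefly tumor location (upper vs
middle/lower lobe); (iii) blood-count inflammation indices over six weekly
timepoints. The pipeline mirrors a realistic clinical workflow: rigid
registration, dose-zone ROI construction, feature extraction and change
computation, reproducibility filtering, sparse per-zone signature fitting,
univariate screening, cross-learner stability selection, and nested
logistic models with ROC, calibration and decision-curve evaluation.

## Dose zones and dosimetry

Zones are lung voxels binned by planned dose on the half-open intervals
[0,5), [5,10), [10,15), [15,20), [20,30), [30,40), [40,50), [50,55) and the
closed top interval [55,60] Gy; dose above 60 Gy is assigned to no zone
(the prescription is treated as a ceiling). Zones are intersected with the
lung mask — RP is a lung toxicity and all dosimetric metrics here are
lung-based — and the planning target volume is *not* subtracted, so the two
highest zones may partially overlap it. Zones under 0.5 cm³ are dropped
and reported rather than fed to texture code, where they would produce
unstable matrices. DVH metrics are MLD (mean lung dose), Vxx (percent of
lung volume receiving ≥ xx Gy, xx ∈ {5,20,30,40}) and the PTV-to-lung
volume ratio.

Registration is intensity-based rigid (Euler angles + translation),
mean-squares metric, three-level multi-resolution gradient descent
(SimpleITK). The accuracy contract — residuals ≤ 1 mm for true shifts up
to 10 mm — is enforced by tests on phantoms with known displacements;
convergence failure raises an error carrying the final metric value,
judged relative to the fixed image's variance because the mean-squares
metric is in squared intensity units. Dose and CT₂ are resampled to the
CT₁ grid (trilinear; nearest-neighbour for masks) before zoning, since
features are computed on CT voxels.

## Feature extraction

Intensities are z-normalized over the lungs and rescaled by 100 before
discretization, so the fixed bin width of 25 spans the intensity
distribution with a realistic number of grey levels (z-scores alone cover
only a few units). Discretization is per-ROI fixed bin width anchored at
the ROI minimum: `level = floor((v − min)/25) + 1`.

Seven classes of original-image features (~107 features) follow IBSI
conventions: first-order statistics on the raw normalized intensities
(entropy/uniformity on the discretized histogram); GLCM (symmetric,
distance 1, 13 unique 3-D directions, features averaged over directions);
GLRLM (same 13 directions, averaged); GLSZM (26-connected zones); NGTDM
and GLDM (26-neighbourhood, GLDM dependence tolerance α = 0, dependence
counted as 1 + matching neighbours); and voxel-based shape descriptors
(volume, exposed-face surface area, sphericity, PCA axis lengths,
convex-hull maximum diameter). Wavelet/Laplacian filter banks are not
applied: the downstream analysis is feature-count-agnostic, and the
original-image set already exercises every code path. Degenerate flat ROIs
yield zero for entropy- and contrast-type features and are flagged rather
than erroring; GLCM correlation on a zero-variance ROI is defined as 1.

Every matrix-class feature is verified to 1e-9 against an independent
brute-force enumeration oracle (explicit loops transcribing the
definitions) on small ROIs — this is the package's strongest correctness
guarantee for the texture code.

The change feature is ΔRF = (RF₂ − RF₁)/RF₁ × 100. Entries whose baseline
magnitude is below 1e-12 cannot be expressed as a percent change; they are
flagged undefined and the feature column is excluded from the zone's
matrix (never imputed). Shape features are excluded from ΔRF by default
(a dose zone's shape barely changes between scans); a config flag restores
them.

## Reproducibility filter

Feature agreement between two delineations is measured by ICC(2,1) —
two-way random effects, absolute agreement, single rater — computed from
the two-way ANOVA mean squares and vectorized across features; features
with ICC > 0.8 are retained. In the synthetic pipeline the second rater is
emulated by dilating each zone ROI by one voxel inside the lung. The ICC
form is configurable in the sense that the estimator function is exposed
directly; the pipeline default is ICC(2,1), the common choice when a study
reports only "the ICC". The estimator is cross-checked in the tests
against `pingouin.intraclass_corr`.

## Markers and screening

Indices: PLR = P/L, NLR = N/L, LMR = L/M, SII = P·N/L from neutrophil (N),
lymphocyte (L), monocyte (M) and platelet (P) counts at baseline and weeks
1–5. The week-w change is the *difference* value(w) − value(baseline);
observed clinical tables of these quantities (baseline lymphocytes ≈ 1.6,
week-4 ≈ 0.7, change ≈ −0.9) are consistent with differences, not ratios,
so difference is the default and ratio semantics are available via
`compute_markers(..., change="ratio")`. Zero denominators yield flagged
missing values.

Screening is per-variable at α = 0.1: continuous variables are routed by a
per-group Shapiro-Wilk check at 0.05 (normal in both groups → Welch
t-test, else Mann-Whitney U); categorical variables use chi-square without
continuity correction, with Fisher's exact test when any expected cell is
below 5. No multiplicity correction is applied at this stage — the screen
is deliberately permissive, and the stability selection downstream is the
guard against false inclusions. Type-I calibration (≈10% selection under
the null) is verified by simulation.

## Signatures and models

Per zone, an L1-penalized logistic regression over the ICC-retained,
complete ΔRF columns is fit on a 50-point geometric penalty path from the
data-derived λ_max (the smallest penalty that zeroes every coefficient)
down to 1e-3·λ_max. Columns are standardized internally and coefficients
reported on the original scale. The penalty is chosen at the minimum of
the 10-fold cross-validated deviance (folds stratified by outcome — with a
~30% event rate unstratified folds are unstable; fold count is reduced to
the minority-class size when necessary). The signature is the weighted sum
of selected features *without* intercept; the downstream logistic model
supplies it. A zone where the penalty removes every feature yields "no
signature" rather than a constant.

Signature and combined models use maximum-likelihood logistic regression
with a small ridge grid (0, 0.01, 0.1, 1.0) chosen by cross-validated
log-loss; perfect separation drops the unpenalized candidate with a
warning. AUCs carry DeLong variance (placement values) and Wald intervals;
paired model comparisons use the paired DeLong test. Confusion metrics are
reported at the Youden-optimal threshold *of the training split*, reused
unchanged on validation. Calibration is quantile-binned observed vs
predicted risk plus a logistic recalibration intercept/slope; empty or
duplicate bins merge, and constant probability vectors collapse to a
single bin with undefined slope. Decision curves report
NB(p_t) = TP/n − FP/n·p_t/(1−p_t) against treat-all and treat-none over
thresholds 0.01–0.99.

Stability selection fits four learners per CV fold — random forest (200
trees, min leaf 2), gradient boosting (100 depth-2 trees), a 5-unit
single-hidden-layer network (importance = input-weight magnitude), and a
depth-4 decision tree — ranks variables per learner-fold (average ranks on
ties), aggregates by mean rank (median available), and returns the top 3.
Exact invariance to candidate column order is not achievable (the
network's weight initialization and the forest's feature subsampling are
position-dependent); the tests assert that the selected set is
order-invariant and aggregate ranks move only marginally. Impurity-based
importances are known to favour continuous variables over binary ones,
which occasionally costs the binary location variable its top-3 slot in
the recovery study below.

## Synthetic data

No public dataset exists for this problem, so the generator is first-class
tested code. The phantom is a two-ellipsoid lung (heterogeneous
parenchyma: −700 HU plus a Gaussian-correlated texture field, SD 60 HU,
correlation 3 voxels) with a 10 mm spherical target, 40 HU soft-tissue
background, and additive white acquisition noise (SD 20 HU). Dose falls
off as a radially symmetric sigmoid around the target (scale 7 mm, midpoint
18 mm beyond the target radius), which makes all nine zones nested shells
of workable volume on the default 64×64×48 grid at 2.5×2.5×3 mm. CT₂
equals CT₁ plus fresh noise; in affected subjects only, zones named in
`texture_effect` additionally receive a Gaussian-correlated field
(correlation 2 voxels) scaled so the zone's local intensity variance in
CT₂ is the stated multiple of its CT₁ value — the mean is untouched, so
the change is visible to variance/texture features only, and voxels
outside the named zones are distributionally identical between affected
and control subjects.

The cohort model draws RP from a logistic model with a tumor-location
odds multiplier (default 8, the scale of location effects reported in the clinical literature), a
latent severity term (SD 0.5), and a base prevalence of 0.30; the
intercept is solved by quadrature so the marginal rate equals the target.
Blood counts are log-normal with falling weekly trend factors (positivity
and right skew by construction); the week-4 neutrophil count of affected
subjects is raised by `nlr4w_effect × L₄w` so the week-4 NLR shifts
additively by exactly the stated amount (default 2.0, matching the scale
of week-4 NLR differences reported in the clinical literature). The 7:3 split takes
floor(0.7·n) training subjects — 112/49 at n = 161.

What the synthetic validation shows: that every stage implements its
contract, and that the pipeline as a whole localizes a zone-confined
texture change and recovers planted predictors at realistic effect sizes.
What it does not show: performance on real patients — real anatomy,
scanner drift, registration error, contouring variability and
outcome-adjudication noise are all absent, and the phantom's texture
model is far simpler than lung parenchyma.

## Recovery studies (desk scale)

* **Zone localization** — 25 replicates of a 40-subject cohort (28/12
  split) on a 48×48×40 grid, feature classes restricted to first-order +
  GLCM + NGTDM for speed (the config selects classes), texture change
  confined to the 50–55 Gy zone at multiplier 2.0. Success when that
  zone's signature attains the maximum validation AUC (ties at the maximum
  included — with 12 validation subjects the planted zone is routinely at
  AUC 1.0 and a noise zone occasionally ties it).
* **Stability recovery** — 25 replicates of the full 161-subject tabular
  cohort; candidates are the p < 0.1 screening survivors among a
  signature-like score (planted group shift 1.2 on SD 0.7), location,
  week-4 NLR, and seven null covariates. Success when the planted trio is
  exactly the top 3.
* **LASSO recall** — 5 informative columns (coefficient 1.0) among 100 at
  n = 200, 20 seeds.
* **ICC recovery** — subject variance 4, error variance 1, n = 200;
  closed-form target 0.8.

These sizes were fixed once as realistic desk-scale settings; the
acceptance script reruns all four studies from scratch.

## Known limitations

* Rigid registration only; deformable motion between scans is out of scope.
* The 1810-feature commercial inventory behind the original workflow is
  proprietary; the ~107 original-image IBSI features cover the seven
  classes without filter-bank expansion.
* Impurity-based importance biases the stability ranking toward continuous
  candidates; permutation importance would remove the bias at several
  times the cost.
* DICOM adapters handle axis-aligned CT series, RTDOSE scaling and planar
  RTSTRUCT contours; gantry-tilted geometry and holes in contours are not
  supported.
* The Youden threshold is training-derived and reused on validation; other
  threshold policies change the confusion metrics but not the AUCs.
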