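# Methods

This note documents the models, parameter choices and numerical details
behind `facesym`. Domain vocabulary follows common usage in geometric
morphometrics and neuroimaging.

## Pipeline model

### Dense correspondence

A base mesh with 22 named anthropometric landmarks defines the point
ordering. For each target face:

1. a thin-plate-spline (TPS) interpolant is anchored at the 22 landmark
   pairs (scipy `RBFInterpolator`, `thin_plate_spline` kernel, degree-1
   polynomial tail). It interpolates the landmarks exactly and
   reproduces any affine map, so rigid motion of the target moves every
   warped point rigidly;
2. each warped base vertex is projected to the closest point on the
   target surface (in-package kd-tree over triangle centroids plus an
   exact point–triangle distance routine; a brute-force all-triangles
   oracle backs it in the tests).

Projections farther than **10× the target's median edge length** keep
the warped position and are flagged (`off_surface`); if more than **5%**
of points fail projection the subject is rejected with an error. The cap
guards the PCA against boundary artifacts while tolerating local mesh
irregularities.

Mirrored forms are reflected about the lateral plane (x → −x), their
paired landmarks relabelled (left ↔ right) and triangle winding flipped,
*before* correspondence, so that point *i* is anatomically consistent
across originals and mirrors.

### Dense surface model

PCA by SVD over the corresponded points of all originals and mirrors,
centered on the joint mean, with variance divisor n − 1. The retained
mode count is the smallest k whose cumulative variance reaches the
coverage target (default **0.99**). Sign convention: each mode's
largest-|entry| coordinate is made positive, which fixes the otherwise
arbitrary SVD signs and makes saved models reproducible.

### Raw asymmetry and SAI

Raw asymmetry = reconstruct(project(original)) −
reconstruct(project(mirrored)) in the retained-mode space; equivalently
(and implemented for cohort-scale speed) `((orig − mirr) @ Vᵀ) @ V` with
V the retained modes. The SAI is the natural log of the signature weight
of this field, where the signature z-scores each point/axis against the
raw asymmetries of the subject's age/gender-matched controls
(self-excluded). The log is taken because the weight is a norm over
3M ≈ 3000+ approximately normal terms — tightly concentrated and
right-skewed — whose log is close to normal; for M points its magnitude
is of order ln √(3M).

Control matching: same gender, |Δage| ≤ 10 years, widened in 5-year
steps until at least `min_n` controls match; a subject is never its own
control.

### Asymmetry-encoding modes

Per retained mode, the Pearson correlation between the scores of
original faces and of their mirrored forms. Modes encoding a shared
asymmetry score strongly negative (reflection flips the asymmetric
component); symmetric modes score strongly positive. Entries below the
threshold (default −0.9) are flagged; the league table is sorted
ascending; zero-variance modes have no defined correlation and are
excluded.

### Brain measures and BASI

Long-format regional tables (one row per subject × region × hemisphere ×
measure kind) are adjusted per cell type by OLS on
`1 + icv + age + sex + scanner-dummies`; the adjusted value is the
residual plus the fit at covariate means, which keeps values on their
original positive scale. Rank-deficient dummies are dropped with a
warning, comparing the rank *gain* of each candidate column (a constant
core covariate must not knock out an informative scanner dummy).

QC flags cells with |z| ≥ 4.7 against the cohort distribution of the
same (region, hemisphere, measure). BASI = (L − R)/((L + R)/2), an
antisymmetric, scale-invariant index bounded in [−2, 2] for positive
measures. The default manifest has 51 paired regions (30 cortical
thicknesses, 8 subcortical volumes, 13 hippocampal subfields) plus two
hemispheric summaries (mean thickness, total surface area); it is a
package design choice and every routine accepts a user-supplied list.

### Repeated LASSO protocol

Features are centered and divided by the Euclidean norm of the centered
column once, on the full dataset (a `leak_free=True` option
re-normalizes inside each training split instead). Per repetition: fresh
random 80/20 split; 10-fold CV on the training set over a descending
13-point grid of powers of 2 (2⁻¹⁶ … 2⁻⁴) scored by the Pearson
correlation between pooled held-out predictions and the outcome, ties
resolved toward the larger (sparser) alpha; refit at the chosen alpha;
held-out Spearman rho (exactly 0 for intercept-only or constant
predictions) and MSE recorded, plus the nonzero-coefficient feature
names. Repetition streams come from `SeedSequence(seed).spawn(n_rep)`,
so results are bit-reproducible and independent of repetition order.

## Synthetic data generator

### What it emulates

* landmarked, symmetric triangulated face templates (≥ 500 vertices)
  with 22 anthropometric landmarks at plausible positions (nose length
  30–60 mm, palpebral fissures 20–35 mm);
* cohorts of faces built as template + Σ aᵢ·symmetric-modeᵢ +
  Σ bⱼ·antisymmetric-modeⱼ + capture noise, with per-group extra
  antisymmetric amplitude (the planted "lesion" effect);
* demographic metadata (age, gender, illness duration for cases, lesion
  side, facial-injury flag);
* regional brain tables in FreeSurfer-like long format with plausible
  baselines, scanner offsets, ICV/age/sex effects, an optional planted
  duration → thickness-asymmetry latent correlation (default −0.19) and
  an optional sparse BASI → SAI link at configurable SNR (default off).

### What it does not emulate

Photorealistic facial appearance, biomechanical growth coupling between
brain and face, capture-device artifacts (holes, specularity), manual
landmarking error structure, or actual neuroanatomy — regional values
are draws around plausible baselines, not segmentations.

### Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `mesh_resolution` (M) | 1000 | vertices | smallest size where retained-mode behavior is stable; minimum 500 enforced |
| `n_per_group` | CTRL 68, FS 61, FC 48, IGE 17 | subjects | default study-scale cohort proportions |
| `sym_mode_sds` | (2.0, 1.5, 1.0) | mm | dominant symmetric face-shape variation |
| `asym_mode_sds` | (0.5, 0.3) | mm | baseline fluctuating asymmetry, smaller than symmetric variation |
| `group_asym_amplitude` | FS = 1.0, others 0 | mm | planted group effect on the antisymmetric modes |
| `noise_sd` | 0.2 | mm | per-capture measurement + correspondence noise |
| `age_range` | 18–77 | years | adult cohort |
| SD floor | 0.01 | mm | prevents z-score blow-ups at near-zero-variance points |
| QC threshold | 4.7 | z | conservative outlier screen for regional measures |
| `duration_thickness_r` | −0.19 | — | planted latent correlation, sign: longer duration → more negative thickness BASI |

Mode fields are smooth random fields symmetrized (or antisymmetrized)
about the lateral plane and normalized to ‖field‖ = √(3M), so a
coefficient of a mm moves points by a mm RMS per coordinate and the
planted variances dominate the noise floor — at the defaults, 99%
coverage retains exactly the planted modes.

Capture noise is drawn **independently** for a subject's original and
mirrored corresponded forms. With exactly shared noise, every empirical
PC of a mirror-closed training set is exactly symmetric or antisymmetric
(the sample covariance commutes with the reflection operator), which
forces original-vs-reflected score correlations to exactly ±1 — even for
pure-noise modes. Independent per-form noise models separate captures
and yields the realistic near-±1 correlations the league table is meant
to grade.

Outlier injection (`inject_outlier`) solves for the measure value whose
*recomputed sample* z-score equals the requested value (Brent's method),
since adding a point shifts the cell mean and SD; values beyond the
sample-attainable bound |z| < (n−1)/√n are rejected.

## Numerical choices

* **SD floor 0.01 mm** in all signature references: raw-asymmetry fields
  of near-symmetric cohorts have tiny per-point variance; the floor
  bounds single-point z contributions without affecting well-conditioned
  points.
* **QC boundary guard**: the outlier comparison is
  |z| ≥ threshold·(1 − 1e-9). A value constructed to sit exactly at
  z = 4.7 recomputes an ulp below the threshold in floating point; the
  relative guard makes the inclusive boundary robust while remaining 7
  orders of magnitude away from distinguishing 4.69.
* **CV scoring of sparse alphas**: an alpha at which no CV fold selects
  any feature is a constant-prediction model and scores 0. Pooling the
  per-fold intercepts instead produces a strongly negative artifact
  correlation (each fold's intercept is the mean of the *other* folds),
  which would make the sparse end of the grid unselectable even on pure
  noise.
* **TPS singularity pre-check**: coincident source landmarks are
  detected explicitly, because the underlying solver does not reliably
  raise on duplicate anchors for larger systems.
* **PCA via SVD** (no covariance matrix formation), deterministic sign
  convention, float64 throughout.

## Limitations

* The generator's five-mode shape space is far simpler than real facial
  variation; power/type-I results transfer to real data only
  qualitatively.
* The landmark and region manifests are plausible design choices, not
  validated clinical instruments.
* Dataset-level feature normalization leaks scale information across the
  train/test split by construction (reproduced deliberately; a
  leak-free variant is provided).
* SAI values of different subjects share matched controls and are
  therefore weakly dependent; group tests treat them as independent, an
  approximation measured in the tests (type-I rate compatible with
  nominal at the tested sizes).
* At small n (≲ 60) with 51 features, the LASSO protocol's selection
  frequencies are dominated by dataset-level chance correlations; they
  stabilize only at larger cohort sizes or with planted signal.
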