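# Methods

## Scope and model

`sstrtex` quantifies intratumoral heterogeneity of somatostatin-receptor
PET uptake in segmented metastases and relates it to progression-free and
overall survival.  The pipeline takes decay-corrected activity volumes
(kBq/mL) with binary lesion masks as given — segmentation, scanner physics
and reconstruction are upstream concerns — converts them to body-weight
SUV, extracts per-lesion conventional and textural features, aggregates to
patient level, and runs a Cox / ROC-Youden / Kaplan-Meier stratification.

## SUV conversion

SUV = concentration (kBq/mL) x body weight (g) / injected activity (kBq),
dimensionless in the g/mL convention.  Input concentrations are assumed
decay-corrected to injection time by the scanner, the standard export
convention; no decay correction is applied in-package.  Conversion is
linear, refuses to run twice, and requires both physics values, which live
in a JSON sidecar rather than the image header so NIfTI round-trips are
exact on values and spacing.

## Lesion size filter

Lesions below 15 mm are excluded to limit partial-volume bias (PET
resolution is of that order).  Diameter is measured as the maximal
axis-aligned extent of the mask: per axis, (occupied index span + 1) x
spacing, taking the largest axis.  This mirrors how lesion size is read on
orthogonal image planes and has two desirable properties a pairwise
voxel-center convention lacks: a single voxel measures its largest spacing
component, and a digitized sphere measures its nominal diameter to within
one voxel — diagonal voxel pairs in a digitized sphere otherwise overshoot
the nominal diameter by up to ~15%, which would let nominally sub-threshold
lesions leak through the filter.  The threshold (`min_diameter_mm`, default
15) is configurable.

## Discretization

In-mask SUVs are binned into `n_levels` (Ng, default 64) equal-width levels
spanning the per-lesion [min, max]; the maximum maps to level Ng; a
constant lesion collapses to a single level.  Fixed-bin-number, per-lesion
min-max normalization is the most common radiomics convention and makes
the texture features invariant to multiplicative uptake scaling; the
alternative (a fixed SUV bin width shared across patients) couples texture
to absolute uptake and is deliberately not the default.  Ng=64 is a
compromise: small enough that typical lesions (hundreds to thousands of
voxels) populate the co-occurrence matrix, large enough to resolve
gradients.  Simulation studies in the test-suite run at the same default.

## Texture matrices

**GLCM** — co-occurrences of grey levels are accumulated over the 13 unique
3D nearest-neighbour directions at `glcm_distance` (default 1 voxel),
symmetric (both orderings), summed into a single matrix before
normalization; pairs with either end outside the mask are ignored.  A mask
with no valid pair (scattered single voxels) is a degenerate-texture error.
Features: entropy (bits), inverse-difference homogeneity, contrast and
correlation.  When a marginal standard deviation is zero, correlation is
reported as 0 with an explicit `correlation_degenerate` flag instead of
NaN, so constant lesions still yield complete, finite feature vectors.
The homogeneity variant (SUM p/(1+|i-j|)) is the canonical inverse
difference; vendor tools normalize differently, so absolute cut-off values
are not portable across implementations — the variant is part of this
documented interface.

**GLSZM** — maximal 26-connected (3D; 8-connected in 2D) zones of equal
level are counted by level and size.  Conservation (SUM s x Z(j,s) = mask
voxel count) is enforced as a test invariant.  Features: short-zone
emphasis, size variation (zone-size non-uniformity normalized by the zone
count), grey-level uniformity and intensity variation.  On a size-zone
matrix the latter two reduce to the same sum, (1/Nz) SUM_j (SUM_s Z)^2;
both names are kept because the field uses both, but neither belongs to
the default 8-feature analysis set (cov, skewness, entropy, homogeneity,
correlation, contrast, short-zone emphasis, size variation).

First-order features use population moments: cov = sigma/mu, skewness =
m3/sigma^3, reported as 0 with a degeneracy flag when sigma = 0.

## Aggregation

`per_patient`: arithmetic mean of each feature over all included lesions.
`per_system`: the largest lesion (by segmented volume, the natural measure
once "largest" must be made precise) per site class (liver, lymph node,
bone, lung, other) is kept, then features are averaged over the kept
lesions.  A patient with zero included lesions is flagged unanalyzable.
Note the TRE identity (TRE = volume x SUVmean) holds per lesion; after
averaging it does not, by construction of the mean.

## Survival statistics

**Cox** — the multivariable screen maximizes the Breslow-tie partial
likelihood by Newton iteration with step-halving, to a gradient max-norm
below 1e-8.  Covariates are z-scored by default, so hazard ratios are per
SD and comparable across features of very different scales (entropy spans
bits, contrast spans thousands).  Monotone likelihood (perfect separation)
is detected through the partial likelihood approaching its upper bound of
zero and raised as an error naming the covariate; the report builder
degrades to NaN Cox rows (with a warning) rather than blocking the
per-feature ROC/KM stages, which matters for small exploratory cohorts.
The implementation is cross-checked against lifelines on tie-free data
(where Breslow and Efron coincide) in the test-suite.

**ROC / Youden** — labels are event-within-follow-up vs censored; this
ignores censoring times (a patient censored early counts as a
non-event), a conventional simplification recorded in the result
metadata.  AUC is the tie-corrected Mann-Whitney statistic, oriented so
AUC >= 0.5 with the direction ('>' or '<=') naming the adverse side.
Candidate cut-offs are midpoints between consecutive distinct values; the
Youden-optimal cut-off breaks ties toward higher specificity (and then
toward the more specific side, for determinism).  The 95% CI uses the
Hanley-McNeil standard error with normal quantiles, truncated to [0,1];
significance means 0.5 outside the CI.  Exact binomial AUC intervals exist
but the normal approximation is accurate at the cohort sizes this pipeline
targets (n ~ 100+).

**Kaplan-Meier / log-rank** — product-limit curves per risk group with
number-at-risk bookkeeping; the two-group log-rank statistic
(O1-E1)^2/V with hypergeometric variance; per-group hazard ratios from the
observed/expected estimator HR_g = (O_g/E_g)/(O_other/E_other) with
log-scale CIs exp(log HR +/- 1.96 sqrt(1/E1+1/E2)) — the estimator that
produces the paired "HR per group" presentation common in clinical
reports.  Dichotomization places values exactly at a '<=' cut-off in the
high-risk group (the boundary belongs to the adverse side).

Raw p-values are reported by default; Holm or Bonferroni adjustment is
available (`correction`) but off, since the default 8-feature panel is
treated as a pre-specified family by the analysis design.

## Synthetic data

Phantoms are digitized spheres (voxel centers within diameter/2 of the
grid center, 2-voxel margin) carrying one of four texture models, each
chosen to hit an analytic limit of the feature formulas:

* `uniform` — entropy 0, contrast 0, homogeneity 1, cov 0;
* `smooth_gradient` — linear ramp along the first axis, slope
  proportional to the heterogeneity level h;
* `correlated_field` — Gaussian-smoothed white noise with smoothing
  length 0.5 + 4(1-h) mm and relative amplitude 0.05 + 0.35h, so both
  within-mask variance and co-occurrence entropy increase monotonically
  in h in [0, 1];
* `checker` — two alternating levels (correlation -1 and entropy 1 bit
  along a single offset).

Background is 5% of the mean lesion uptake, keeping SUVmax attributable to
the lesion.  Identical spec + seed reproduce volumes bit for bit.

Outcomes follow an exponential proportional-hazards model: hazard =
baseline_hazard x exp(beta x), with x the z-scored patient-level value of
the linked feature measured by the package's own extractor on the
phantoms (which carry no scanner noise, so measured equals true).  Random
censoring is an independent exponential time whose single global rate is
solved (Brent root-finding on the closed-form mean of mu/(lambda_i+mu)) so
the cohort-mean random-censoring probability equals `censor_rate`; a
per-patient calibration would make censoring probability identical for
everyone and sever the label-feature association the ROC step relies on.
An administrative horizon (default 60 months in the pipeline, a typical
follow-up window) truncates on top.  PFS- and OS-style outcomes are drawn
from the same latent predictor with independent noise; the OS baseline
hazard defaults to half the PFS one.

Default cohort conditions: correlated-field lesions of 18-40 mm at 3 mm
isotropic spacing (realistic post-filter NET metastases on a clinical PET
grid), heterogeneity 0.1-0.9 with a patient-level trait plus small
per-lesion jitter, 1-3 lesions per patient, liver-dominant site
prevalence, body weight ~ N(75, 12) kg and injected activity
~ N(124, 15) MBq.  Site does not modulate texture by default
(`site_modulates_texture` is exposed but off, since there is no established
quantitative site-texture model to emulate).

What the phantoms do **not** emulate: scanner point-spread blurring,
correlated reconstruction noise, respiratory motion, irregular lesion
shapes, and inter-feature correlation structures of real tumors.  Passing
tests therefore demonstrate that the *measurement and statistics chain* is
correct and calibrated — not that any particular feature is prognostic in
patients.

## Numerical choices and degenerate inputs

* Equal-width bin assignment is floor-based with the top edge closed.
* A mask voxel counts as inside iff its stored value is exactly 1.
* Constant lesions short-circuit to the analytic texture limits with
  degeneracy flags rather than running a 1x1 co-occurrence matrix.
* Youden ties: higher specificity first, then the more specific cut-off.
* Log-rank with zero variance (e.g. no events) returns chi2 = 0, p = 1.
* O/E hazard ratios with an expected count of zero are NaN.
* All observed survival times are clamped strictly positive (1e-9 floor).
* Derived RNG streams use integers below 2^31 drawn from the root seed.

## Problem sizes

The test-suite and acceptance script use scaled simulation studies chosen
as the package's own verification budget: 200 random grids (<= 5x5x5, <= 4
levels) for oracle equivalence, 2000 null cohorts (n=100) for log-rank
size, 200 replicates for Cox and O/E hazard-ratio recovery, and 100 (tests)
or 30 (acceptance script) synthetic cohorts per arm (n=150, 40% censoring,
beta = 0.8 per SD) for end-to-end discrimination.  These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands.

## Known limitations

* Texture feature values are implementation-specific (discretization,
  offsets, homogeneity variant); absolute cut-offs do not transfer between
  tools, only within a fixed configuration of this one.
* The ROC label ignores censoring time; time-dependent ROC is out of scope.
* No partial-volume correction beyond the size filter.
* No DICOM ingestion; volumes must arrive as NIfTI.
* Multiple-testing control is optional and off by default.
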