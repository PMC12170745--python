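# Methods

`gliosurv` re-implements, as a reusable and fully tested pipeline, a
survival-prognostication study design for IDH-mutant lower-grade glioma
(dLGG): radiomics features extracted zone-wise from two MRI sequences are
selected by a three-stage cascade, turned into LASSO-Cox survival models,
compared against clinical Cox models with Uno's IPCW concordance index,
and used to stratify patients into high/low-risk groups.  Because no
patient imaging is distributed with such studies, the package ships a
synthetic cohort generator with known ground truth; every stage is
validated against independent oracles on that generator.

## Study design

**Cohort and split.** A cohort of `n` patients (default 207) is divided
70:30 into training and test sets, stratified jointly on the event
indicator and tumor subtype with largest-remainder rounding, so the
training set has exactly `floor(0.7 n)` members (144/63 at n = 207) and
event/subtype fractions are preserved to integer resolution.

**Zones.** Four tumor-related volumetric zones are derived from the
segmentation by anisotropic Euclidean distance to the tumor boundary,
clipped to the brain mask: the tumor itself; the ±5 mm band straddling
the boundary (closed, `[-5, +5]`); and the 0–10 mm and 10–20 mm
peritumoral bands (half-open `(inner, outer]`, so the outside bands
partition `{0 < d ≤ 20}` with no double counting).  Distances are
voxel-center to voxel-center — deterministic and exactly checkable
against all-pairs brute force — rather than a sub-voxel surface model.
A zone emptied by brain clipping propagates as explicit missing feature
values, never as zeros.

**Radiomics.** Per zone: 9 shape features (voxel-count volume,
face-count surface area, sphericity `π^(1/3)(6V)^(2/3)/A`,
surface/volume ratio, equivalent sphere diameter, maximum 3D Feret
diameter over voxel centers, and per-plane maximum 2D diameters); per
(zone, sequence): 16 first-order statistics and the 16-feature IBSI
GLRLM run-length set (SRE, LRE, GLN, GLNN, RLN, RLNN, RP, GLV, RLV, RE,
LGLRE, HGLRE, SRLGLE, SRHGLE, LRLGLE, LRHGLE), computed per each of the
13 unique 3D directions on the discretized ROI and averaged with equal
weight.  Images are used unfiltered.  Gray levels use fixed-bin-count
discretization (32 bins) over the ROI range, top bin inclusive: the
synthetic intensities carry an arbitrary scale, so a fixed bin *width*
would be meaningless; the choice is isolated behind
`DiscretizationSpec`.  Total inventory: 4 × (9 + 2 × 32) = 292 columns.

Diameters use voxel centers (hull-accelerated but brute-force
equivalent) and surface area counts exposed voxel faces; face counting
overestimates a smooth surface, which only affects sphericity and the
surface/volume ratio and keeps both exactly oracle-checkable.

**Normalization and selection (training set only).**

1. *Variance filter*: features with raw-value variance < 0.01 are
   removed (strict `<`).  The filter runs on pre-z-score values: after
   z-scoring every non-constant column has variance exactly 1, which
   would make the threshold vacuous, so it is read as a near-constancy
   screen — the only reading that gives the stated threshold effect.
2. *Spearman redundancy prune*: one static correlation matrix; pairs
   with |ρ| ≥ 0.95 visited in descending |ρ|; from each pair the member
   with the higher mean |ρ| against all other original features is
   dropped (mean ties, including float-summation ties, drop the
   lexicographically later name, making the surviving set independent of
   column order).
3. *LASSO-Cox*: coordinate-descent L1 Cox path; the penalty is chosen by
   5-fold event-stratified cross-validation of the held-out partial
   log-likelihood (Verweij–van Houwelingen score `pll(all) −
   pll(without fold)`), taking the largest penalty within one standard
   error of the optimum (the `lambda.1se` convention).  The 1-SE rule is
   used because the cohorts of interest have few events (~35 at the
   default censoring level); the score-maximizing penalty routinely kept
   15+ features at 70 training events, and the parsimonious rule matches
   the signature sizes such studies report.  `penalty_rule="max"` is
   available.

Z-scoring is applied separately per set: the test set is normalized with
its own statistics (switchable to training statistics via
`StudyParams.test_zscore_stats="train"`; per-set statistics are the
package default because that is the stated study procedure, unusual as
it is — empirically the two differ negligibly at n ≈ 60).

**Models.** Nine Cox proportional-hazards models: preoperative clinical
(preoperative volume), full clinical (volume + extent of resection +
subtype), one LASSO-Cox model per zone (the penalized fit itself is the
model), combined preoperative and combined full (clinical covariates
plus the best radiomics zone's selected features, refit jointly and
unpenalized), and a sensitivity variant replacing extent of resection
with postoperative volume.  Extent of resection enters as two indicators
(partial, complete; biopsy reference); subtype as an astrocytoma
indicator.  Unpenalized fits use Efron tie handling and Newton
optimization with step-halving; a monotone partial likelihood is
reported through `converged=False` rather than an exception.  Risk is
the linear predictor β·x; no baseline hazard is needed for ranking,
concordance, or stratification.  Exact linear SHAP values
`φ_j = β_j (x_j − mean_background(x_j))` explain individual risks and
sum to the risk deviation from the background mean.

**Evaluation.**  Harrell's c and Uno's IPCW c, the latter optionally
truncated at τ = 5 years.  Conventions (the literature is not uniform):
usable pairs are `(i, j)` with `T_i < T_j`, `event_i = 1`, plus
event/censoring ties at the same recorded time (an event precedes a
censoring); event/event ties are unusable; risk ties count 1/2.  The
censoring survival curve Ĝ is the product-limit estimator with the
censoring indicator, estimated on the evaluation set itself, events
leaving the risk set before same-time censorings; pair weights use the
left limit `1/Ĝ(T_i−)²`.  These conventions reproduce
`sksurv.metrics.concordance_index_ipcw` to machine precision on
tie-free data, and the test suite additionally checks an explicit
brute-force IPCW double loop.  Bootstrap distributions (B = 1000)
resample test patients with replacement, applying the *same* resample
indices to every model so the distributions are paired; replicates on
which the c-index is undefined (no events in the resample) are skipped,
with more than 10% skips an error.  Models are compared by Wilcoxon
signed-rank on the paired distributions (zero differences dropped;
all-zero → p = 1).

**Risk groups.**  The best combined model's risk scores on the entire
cohort are dichotomized at the threshold maximizing the two-sample
log-rank χ², over midpoints of consecutive sorted unique scores, subject
to both groups holding ≥ 33% of the cohort (`ceil(0.33 n)`); χ² ties
take the smaller threshold; high risk means strictly above the
threshold.  Kaplan-Meier curves are reported overall and per subtype.

## Synthetic cohort generator

The generator emulates the *structure* of a surgical dLGG cohort, not
MRI physics:

* **Geometry** — tumors are ellipsoids (base radius uniform on
  15–32 mm; per-axis anisotropy factors uniform on 0.8–1.2 normalized
  so the base radius is the per-axis maximum) radially perturbed by a
  seed-drawn combination of degree-2/3 real spherical harmonics with
  amplitude `lobulation` (default 0.15) — smooth, connected, tunable
  irregularity.  The grid (64³ voxels at 2 mm) is validated to hold the
  largest tumor plus a 20 mm margin so the 10–20 mm zone is never
  clipped by the volume border; the brain mask is an inscribed
  ellipsoid.
* **Texture** — intratumoral intensity is piecewise constant on a
  nearest-seed (Voronoi) partition over Poisson-sampled centers with
  expected cell volume `blob_size³` (blob size uniform on 4–16 mm per
  patient), plus Gaussian noise (SD 2).  Cell size directly controls
  gray-level run lengths: long-run emphasis is monotone in blob size
  (verified by a sweep oracle).  The two sequences share the partition
  but draw independent cell intensities around different tumor/background
  contrasts (T1c 140/100, FLAIR 160/80, cell SD 20).
* **Clinical covariates** — preoperative volume is the exact
  segmentation volume; extent of resection is drawn with biopsy/partial/
  complete probabilities 0.087/0.710/0.203 (a typical surgical dLGG
  distribution) with consistent postoperative volume (complete → 0 ml);
  subtype is a fair coin and acts on survival *only* through its hazard
  effect — no imaging difference — so clinical-vs-radiomics information
  is cleanly separable in synergy experiments.
* **Survival** — event times are Weibull (shape 1.2, scale 12 years)
  with the hazard multiplied by `exp(β·x)`; continuous drivers
  (measured Feret diameter, texture heterogeneity `−log blob`) enter
  per SD, binary drivers (astrocytoma, resection indicators) as-is.
  Default per-SD log-hazard effects: diameter 0.8, heterogeneity 0.6,
  astrocytoma 0.6, partial −0.3, complete −0.7 — sizes that make
  imaging and clinical features comparably informative.  Censoring
  combines an administrative horizon, calibrated by bisection so the
  realized event fraction hits the target (default 0.25, i.e. ~75%
  censored, the regime typical of dLGG cohorts), with a 20% uniform
  dropout fraction.
* `strong_signal_config` is the preset for recovery and synergy checks:
  effects raised (diameter 1.0, heterogeneity 0.8, astrocytoma 0.8,
  resection −0.4/−0.9) and event fraction 0.5, so fitted-model
  concordance is dominated by signal rather than censoring noise.

**What passing tests do and do not show.**  The generator has no bias
fields, no registration error, no partial-volume effects, no
site/scanner variation, and its texture is stationary piecewise-constant
blobs rather than infiltrative gradients.  Tests passing on it establish
that the *pipeline machinery* is correct (zones, feature definitions,
selection logic, model fitting, IPCW evaluation, stratification) and
that the end-to-end chain loses little of a known signal; they say
nothing about how much prognostic signal real dLGG MRI carries.

**Oracle concordance.**  The ceiling any model can approach on a
generator configuration is estimated by Monte-Carlo: sample drivers
analytically at n = 20 000, draw uncensored event times, and evaluate
the true linear predictor's concordance through the Kendall-τ identity
c = (1 − τ)/2 (O(n log n)).  On strong-signal cohorts of 200 patients
the combined clinical+radiomics model's test-set Uno's c sits within
0.05 of this ceiling; at a 60-patient test set the comparison itself
carries sampling noise of roughly ±0.04, which dominates the residual
gap.

## Numerical choices and degenerate inputs

* Distance bands: center-to-center distances; closed ±5 mm band,
  half-open outside bands.
* Discretization: constant ROI maps to label 1; the ROI maximum lands in
  the top bin.
* First order: skewness/kurtosis of a constant ROI are reported as 0 by
  convention; entropy uses log₂ (bits).
* Constant feature columns: flagged and set to 0 by z-scoring (tolerance
  `1e-12·(|mean|+1)` so float-rounding constants count), never silently
  dropped.
* Cox fitting: convergence at relative partial-log-likelihood change
  < 1e-9 (library default); constant covariates are rejected by name;
  an empty covariate set yields the null model with risk ≡ 0.
* Concordance: Ĝ = 0 at an event time inside the evaluation window is
  an error naming the offending time; τ below the earliest event time is
  an error (no usable pairs).
* Cutpoint search: candidates are midpoints of consecutive unique
  scores; no admissible candidate (e.g. constant risks) is an error.
* Every random stage is seeded from one master seed via
  `numpy.random.SeedSequence` spawning; a study run is a pure function
  of (cohort, parameters), and result JSON is byte-identical across
  repeated runs.

## Problem sizes

Default problem sizes were chosen so that a full study (cohort
generation, feature extraction, selection, modelling, B = 1000
bootstrap) completes in a few minutes on one CPU: 64³ voxel grids at
2 mm spacing, 207 patients for the default study, 200 for the
strong-signal synergy check, 500 for effect-size recovery (10 seeds,
driver-level simulation), 20 000 for Monte-Carlo oracles.  Feature
extraction dominates at roughly 0.3 s per patient.

## Known limitations

* The feature inventory is a representative IBSI set (9 shape + 16
  first-order + 16 GLRLM); other texture families (GLCM, GLSZM, NGTDM),
  filtered images, and mesh-based shape are deliberately out of scope.
* The 2D diameters are reported per anatomical plane of the voxel grid;
  no registration or reorientation is modelled.
* Uno's estimator assumes censoring independent of covariates; Ĝ is
  estimated on the evaluation set itself (switch-able design point).
* The best radiomics zone is chosen by test-set point estimate before
  building combined models, mirroring the study design it implements;
  this is an optimistic selection step and is labelled as such.
* With per-set test z-scoring, radiomics model coefficients learned on
  training statistics are applied to test features normalized with test
  statistics — again the stated study procedure, kept behind a switch.
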