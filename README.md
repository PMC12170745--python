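# gliosurv

Zone-wise MRI radiomics and clinical survival modelling for IDH-mutant
adult-type diffuse lower-grade glioma (dLGG), exercised end-to-end on a
synthetic imaging–survival cohort generator with known ground truth.

Patients with dLGG have long but heterogeneous survival, and the timing
of postoperative oncological treatment hinges on prognosis.  This
package implements, as a reusable and fully tested pipeline, the
comparison of quantitative MRI (radiomics) survival models against the
clinical models used in practice:

* **zones** — four tumor-related volumetric zones from the segmentation
  by anisotropic Euclidean distance (tumor; ±5 mm boundary band;
  0–10 mm and 10–20 mm peritumoral bands), clipped to the brain mask;
* **radiomics** — IBSI-style shape, first-order, and GLRLM run-length
  features (the "heterogeneity" family: lengths of consecutive
  equal-gray-level runs along the 13 unique 3D directions) per zone and
  sequence, on unfiltered images, with fixed-bin-count discretization;
* **selection** — variance filter (< 0.01, raw values) → Spearman
  redundancy prune (|ρ| ≥ 0.95, drop the higher mean-correlation
  member) → cross-validated LASSO-Cox, training set only;
* **models** — Cox proportional hazards: preoperative clinical (tumor
  volume), full clinical (volume + extent of resection + subtype), one
  LASSO-Cox model per zone, combined clinical+radiomics refits, and a
  postoperative-volume sensitivity variant, with exact linear SHAP
  explanations of risk (risk = β·x);
* **evaluation** — Uno's IPCW concordance index (plain and truncated at
  τ = 5 years) and Harrell's c on the held-out test set, paired
  bootstrap distributions (shared resample indices), Wilcoxon
  signed-rank model comparisons;
* **stratification** — high/low-risk dichotomization maximizing the
  log-rank χ² subject to a 33% minimum group size, with Kaplan-Meier
  curves overall and per subtype.

Because patient MRI cohorts of this kind are not publicly deposited,
the `synthetic` module generates complete cohorts — segmented
two-sequence volumes with controllable size, lobulation, and run-length
texture; correlated clinical covariates; Weibull proportional-hazards
outcomes with calibrated censoring — so every stage is testable against
brute-force oracles and known effect sizes.  See `docs/methods.md` for
the model, assumptions, and limitations.

## Worked example

Simulate a 207-patient cohort (the default study size, ~75% censored)
and run the whole study from one master seed:

```bash
gliosurv run-all --out results/demo --seed 1 --n-patients 207
```

or in Python:

```python
from gliosurv import pipeline, synthetic

cfg = synthetic.SyntheticConfig(n_patients=207, seed=1)
cohort = synthetic.generate_cohort(cfg)
results = pipeline.run_study(cohort, pipeline.StudyParams(master_seed=1))
print(results["split"]["n_train"], results["split"]["n_test"])
print({m: round(e["uno_c"], 3) for m, e in results["models"].items()
       if e["uno_c"] is not None})
```

On this seed the run prints:

```
144 63
{'preop_clinical': 0.666, 'full_clinical': 0.682,
 'radiomics_tumor': 0.688, 'radiomics_band_pm5': 0.692,
 'radiomics_ptz_0_10': 0.654, 'radiomics_ptz_10_20': 0.655,
 'combined_preop': 0.743, 'combined_full': 0.786,
 'full_clinical_postop': 0.695}
```

Reading the numbers: the 207 patients split 144/63 (70:30, stratified
on event and subtype).  Test-set Uno's c ranks the models — clinical
volume alone reaches 0.67, the tumor-zone radiomics model 0.69, and the
combined full-clinical + radiomics model 0.79, the synergy the pipeline
is designed to measure.  The generating model's Monte-Carlo ceiling
(true effect sizes, n = 20 000, no censoring) is 0.739 on this
configuration, so the combined model sits at the ceiling to within
test-set sampling noise.  Stratifying the whole cohort on the combined
model's risk scores separates survival with log-rank χ² ≈ 50.7
(p ≈ 1e-12), with 69 of 207 patients in the high-risk group.

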