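# sstrtex

Intratumoral heterogeneity analysis for somatostatin-receptor (SSTR) PET.

Neuroendocrine-tumor patients scheduled for peptide receptor radionuclide
therapy (PRRT) are imaged with SSTR-PET/CT, but conventional uptake metrics
(SUVmax, SUVmean) are weak predictors of who will progress.  `sstrtex`
implements the alternative: quantify the *texture* of tracer uptake inside
each segmented metastasis, aggregate the per-lesion features to the patient
level, and test whether the resulting heterogeneity scores stratify
progression-free (PFS) and overall survival (OS).

It is aimed at imaging researchers who have PET volumes and lesion masks
(plus follow-up data) and want a reproducible, scriptable pipeline — and at
methodologists, via a synthetic phantom/cohort generator with known ground
truth that makes every stage testable without patient data.

## What it computes

**Per lesion** (after body-weight SUV conversion and a 15 mm minimum-size
filter against partial-volume effects):

* conventional: SUVmax, SUVmean, volume (mL), TRE = volume x SUVmean
  (the receptor-imaging analogue of total lesion glycolysis);
* first-order: coefficient of variation sigma/mu, skewness m3/sigma^3;
* second-order, from the grey-level co-occurrence matrix p(i,j) built on
  Ng equal-width grey levels over the 13 unique 3D neighbour directions:

  entropy = -SUM p log2 p, homogeneity = SUM p/(1+|i-j|),
  contrast = SUM (i-j)^2 p, correlation = SUM (i-mu_i)(j-mu_j) p / (sigma_i sigma_j);

* higher-order, from the grey-level size-zone matrix Z(j,s) of 26-connected
  equal-level zones (Nz zones in total):

  short-zone emphasis = (1/Nz) SUM Z(j,s)/s^2,
  size variation = (1/Nz) SUM_s (SUM_j Z(j,s))^2,
  grey-level uniformity / intensity variation = (1/Nz) SUM_j (SUM_s Z(j,s))^2.

**Per patient**: mean over all included lesions (`per_patient`), or mean
over the largest lesion per organ system (`per_system`).

**Survival stratification**: multivariable Cox regression (Breslow partial
likelihood, Newton iteration, z-scored covariates so hazard ratios are per
SD); per-feature ROC analysis of event-vs-censored labels with the Youden
index J = sensitivity + specificity - 1 picking the cut-off and a
Hanley-McNeil 95% CI on the AUC deciding significance (0.5 outside the CI);
Kaplan-Meier curves of the cut-off-defined low/high-risk groups compared by
the log-rank test, with per-group observed/expected hazard ratios.

## Worked example

```python
from dataclasses import replace
import sstrtex as sx

# a 28 mm textured sphere phantom, converted to SUV, features extracted
vol, mask = sx.generate_lesion_image(
    sx.PhantomSpec(diameter_mm=28, heterogeneity_level=0.8, mean_uptake=60.0, seed=7))
vol = replace(vol, patient_weight_kg=72.0, injected_activity_MBq=130.0)
fv = sx.extract_lesion(sx.to_suv(vol), mask)
```

prints (via `fv.as_dict()`):

```
suv_max                62.4653      entropy                10.6665
suv_mean               33.2308      homogeneity            0.1446
volume_ml              11.6640      correlation            0.0481
tre                    387.6037     contrast               275.7919
cov                    0.3178       short_zone_emphasis    0.8368
skewness               0.2633       size_variation         212.6296
```

SUVmean 33.2 = 60 kBq/mL x 72 000 g / 130 000 kBq; TRE 387.6 = 11.664 mL x
33.23; the high entropy and short-zone emphasis reflect the strong simulated
heterogeneity (level 0.8 of 1).

Stratifying a simulated 60-patient cohort whose PFS hazard rises with
entropy (log-HR 0.8 per SD, 40% censoring):

```python
cohort = sx.CohortSpec(n_patients=60)
surv = sx.SurvivalSpec(baseline_hazard=0.03, beta=0.8, linked_feature="entropy",
                       censor_rate=0.4, admin_censor_months=60.0)
_, table = sx.simulate_cohort(cohort, surv, seed=11)
roc = sx.roc_youden(table["true_entropy"], table["pfs_event"])
groups = sx.dichotomize(table["true_entropy"], roc)
km = sx.km_logrank(table["pfs_months"], table["pfs_event"].astype(bool), groups)
```

gives AUC 0.754 (95% CI 0.631-0.878, significant), Youden cut-off
entropy > 10.33 (sensitivity 70.0%, specificity 76.7%), and a clean KM
separation: log-rank chi2 = 17.80, p = 2.5e-5, HR 4.39 (2.07-9.30) for the
high-risk group versus 0.23 for the low-risk group — the simulated
entropy-survival link is recovered end to end.

## Command line

```bash
sstrtex all --seed 7 --outdir run1 --n-patients 50     # simulate -> report
sstrtex extract --config my.yaml --cohort-table cohort.csv
```

Stages: `simulate`, `extract`, `analyze`, `report` (or `all`).  Inputs are
NIfTI volumes/masks plus a one-row-per-lesion CSV (patient id, weight,
injected activity, PFS/OS times and event flags, lesion site and file
paths); outputs are feature CSVs, ROC and KM report tables
(`table2_analog.csv`, `table3_analog.csv`), KM plots with number-at-risk
annotations, and a `run_log.json` accounting for every excluded lesion.

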