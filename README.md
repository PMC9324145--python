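# strokepwi

Temporal radiomics of DSC-PWI perfusion MRI, fused with clinical
covariates and learned survival features, for multi-level prediction of
90-day functional outcome (modified Rankin Scale, mRS) after ischemic
stroke.

## What it does

Dynamic susceptibility contrast perfusion-weighted imaging (DSC-PWI)
tracks a contrast bolus through the brain as a 4D series: each voxel
carries a time–intensity curve *I(t)* whose transient dip encodes local
blood flow. In stroke, lesion tissue (LT) shows a smaller, delayed dip
than the mirrored contralateral normal tissue (NT). This package turns
that dynamic information into outcome predictions:

1. **Temporal radiomics** — the 4D series (50 timepoints) is decomposed
   into 3D volumes *S(n)*; nine radiomics classes (Shape, First-order,
   GLCM, GLRLM, GLSZM, NGTDM, GLDM, plus all non-shape classes on 5
   Laplacian-of-Gaussian images and 8 wavelet bands) give **1316 features
   per timepoint → 65,800 temporal features** per scan, named
   `<base>_<n>` (e.g. `log-sigma-1-0-mm-3D_firstorder_Skewness_17`).
2. **Significance filter** — features are range-normalized,
   `F* = (F − F̄)/(Fmax − Fmin)`, and kept when a Levene-gated two-sample
   t-test separates LT from NT rows at p < 0.05.
3. **13 feature selectors** — MIM, MIFS, MRMR, JMI, CMIM (mutual
   information), Fisher, Laplacian score, ReliefF (similarity), F-score,
   T-score (statistics), MCFS, alpha investing, Lasso (sparse/streaming);
   Lasso keeps coefficients |β| > 0.02, the rest keep normalized scores
   > 0.9, at most 20 features each.
4. **Composite-score benchmark** — each selected set is scored by ten
   classifier families under stratified tenfold cross-validation on five
   indexes (Pre, Acc, Auc, F1, Recall); the composite score is the grand
   mean, `CS = (1/KM) Σ_{k,m} index(k, model(m, F))` with K = 5, M = 10,
   and the best-CS method selects the mRS radiomics features (mRSRF).
5. **Survival fusion (SurvF)** — a feed-forward Cox scorer (negative log
   partial likelihood, Breslow ties) is trained on clinical covariates +
   mRSRF with **age as event time** and poor outcome (mRS ≥ 3) as the
   event; its range-normalized risk is one learned feature per patient.
6. **Outcome evaluation** — seven feature groups (CTI, mRSRF, SurvF and
   their fusions) × ten models × three label granularities (2-, 4-,
   7-category mRS) on a stratified 70/30 split.

A synthetic-data module generates perfusion series with gamma-variate
bolus curves, Table-1-style clinical covariates and plantable outcome
effects, so the entire pipeline is testable without patient data.

## Worked example

```python
import numpy as np
from strokepwi import (SynthConfig, generate_cohort, FeatureConfig, build_table,
                       filter_significant, select_features, regroup_mrs)

cfg = SynthConfig(n_patients=40, n_timepoints=30, volume_shape=(6, 16, 16), seed=0)
cohort = generate_cohort(cfg)
table = build_table(cohort.series, cohort.rois,
                    FeatureConfig(enabled_classes=("First-order",)), smooth=True)
print("feature table:", table.values.shape)
sig, reduced = filter_significant(table)
print("significant features:", reduced.shape[1])
fs = select_features("MRMR", reduced, table.row_meta["tissue"])
print("MRMR picks:", fs.features[:3])
print("mRS_2 counts:", np.bincount(regroup_mrs(cohort.mrs7, 2)))
```

prints

```
feature table: (80, 540)
significant features: 154
MRMR picks: ['original_firstorder_Maximum_17']
mRS_2 counts: [22 18]
```

Forty scans give 80 rows (one LT and one NT row each) × 540 temporal
first-order features; 154 separate lesion from normal tissue, and the
top MRMR pick sits at timepoint 17 — inside the bolus transit, where the
planted LT/NT contrast lives. The 7-level labels regroup into 22 good
(mRS 0–2) and 18 poor (mRS 3–6) outcomes.

The same flow runs from the shell:

```bash
strokepwi run --seed 1 --outdir runs/demo            # all stages
strokepwi synth --seed 1 --outdir runs/cohort        # NIfTI + CSV cohort
strokepwi extract --series s.nii.gz --lt-mask m.nii.gz --outdir runs/x
```

`run` writes per-stage artifacts (`features.csv`, `significance.csv`,
`featureset_<method>.json`, `benchmark_report.json`,
`survf_mRS_*.csv`, `prediction_report.csv`) plus a `manifest.json` with
seeds and content hashes; reruns with the same config are bit-identical.

## Scope

Motion correction/registration, lesion segmentation (Tmax thresholding)
and skull stripping are upstream concerns: series are assumed registered
and lesion masks are inputs (or synthetic). See `docs/methods.md` for
the model details, parameter defaults and limitations.
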