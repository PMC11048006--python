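# subgrade

Sub-region CT radiomics and machine learning for binary WHO/ISUP grading of
renal tumours.

Clear cell renal cell carcinoma is graded 1–4 by nucleolar prominence on
histology; grades 1–2 (low) and 3–4 (high) drive different management, and
pre-operative biopsy grades poorly. This package implements a non-invasive
alternative as a reusable, tested pipeline: decompose the 3D tumour mask
from contrast-enhanced CT into **sub-regions** — volume-fraction cores and
hollow-rim peripheries — extract a standardised radiomics battery from each
region, and train a classifier grid to separate low- from high-grade
tumours, so the grade signal can be localised *within* the tumour. A
diagnostic-metrics suite compares predictors (e.g. machine learning vs
percutaneous biopsy) against nephrectomy histology.

Because patient CT cohorts cannot ship with code, the package includes a
seeded phantom generator that produces ellipsoidal tumours with
class-dependent core/periphery textures plus clinical covariate tables
matching published cohort demographics — every stage is runnable and
testable offline.

## The pipeline

For a mask M with voxel depth d(v) (Euclidean distance to background, in mm):

* core(p) = the round(p·|M|) deepest voxels; periphery(p) = M \ core(1−p).
  Seven regions per tumour: full, cores and peripheries at 25/50/75%.
* Features per region (fixed 20 HU bins, no resampling): 19 first-order,
  24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM, 16 shape = 110; optional
  filter images (gradient, exponential/log/sqrt/square, LoG, 3D wavelet)
  re-contribute 94 intensity/texture features each.
* Preparation, fitted on training rows only: z-scoring Z = (x−μ)/σ →
  pairwise-correlation filter at |r| > 0.8 → XGBoost gain-importance top-k
  → SMOTE balancing of the training partition.
* Models: 11 classifiers with published tuned settings (SVM, RF, XGBoost,
  NB, MLP, LSTM, LR, QDA, LightGBM, a gradient-boosting "CatBoost" slot,
  AdaBoost); one stratified 67/33 split per cohort reused across all
  7 regions × classifiers (231 cells over three cohorts), plus
  train-on-one-cohort / test-on-the-other external validation.
* Metrics: ACC/SEN/SPE with Wald 95% half-widths, trapezoidal AUC (or the
  balanced (SEN+SPE)/2 for label-only predictors such as biopsy), MCC, F1,
  McNemar's (FN−FP)²/(FN+FP), χ²-randomness; indeterminate biopsies count
  against the biopsy arm.

See `docs/methods.md` for definitions, defaults and design rationale.

## Worked example

```python
from subgrade.evaluate import ConfusionMatrix, metrics
from subgrade.pipeline import recovery_experiment

# phantoms -> sub-regions -> features -> selection -> classifier grid,
# on a 100-subject cohort whose grade signal is confined to the inner
# 50% tumour volume
print(recovery_experiment(n_subjects=100, seed=7).round(1))

# the biopsy-vs-nephrectomy panel for a label-only predictor
print(metrics(ConfusionMatrix(TP=1, FP=8, TN=9, FN=10)).as_dict())
```

Output (the grid half varies with the seed; the metrics line is exact):

```
region
core50         92.3
core75         90.6
core25         81.4
full           80.4
periphery75    64.7
periphery50    42.0
periphery25    41.4
Name: auc, dtype: float64
{'ACC': 35.71..., 'SPE': 52.94..., 'SEN': 9.09..., 'AUC': 31.01...,
 'MCC': -0.397..., 'F1': 0.1, 'McN': 0.637..., 'chi2': 0.035...}
```

The region ranking shows the injected signal being localised: the 50% core
(the exact signal support) leads; the 75% core and full mask dilute the
contrast; the 25% core sees the full contrast but over fewer voxels; the
signal-free 50%/25% peripheries sit near (or below) chance. The metrics
line is the full diagnostic panel of a predictor with 1 true / 10 missed
high-grade and 9 true / 8 false low-grade calls on 28 subjects — accuracy
35.7%, balanced AUC 31%, MCC −0.40, and a McNemar p of 0.64 (the FN/FP
asymmetry is not significant at this n).

The numbered drivers under `analysis/` run the full study narrative on
synthetic cohorts: `01_simulate_cohorts.py` (cohort tables + clinical
statistics), `02_extract_features.py`, `03_internal_grid.py` (region and
classifier rankings), `04_external_validation.py`, `05_biopsy_comparison.py`.
Each writes its tables under `results/`.

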