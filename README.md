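# marrowtex

Radiomic texture analysis of masked 2D MRI ROIs: an 81-descriptor
texture engine, a three-group statistical comparison workflow with
Benjamini–Hochberg FDR control, a combinatorial feature-selection /
random-forest evaluation protocol, and a synthetic cohort generator
that makes the whole pipeline testable end to end without any data
download.

## Descriptor families

Each ROI (an intensity image plus a binary mask) yields exactly 81
named descriptors:

| family | count | notes |
|--------|------:|-------|
| first-order (`fo_*`) | 17 | raw masked intensities; energy/entropy over 32 equal-width bins |
| GLCM (`glcm_*`) | 22 | Haralick-style; 4 directions (N/S/E/W, 1-pixel offset), per-direction features averaged |
| GLRLM (`glrlm_*`) | 16 | maximal constant-level runs, broken at mask boundaries, 4-direction average |
| GLSZM (`glszm_*`) | 16 | 8-connected equal-level zones |
| Tamura (`tam_*`) | 6 | coarseness map summaries (mean/std/median/entropy), contrast, roughness |
| LBP (`lbp_*`) | 4 | 8-neighbor radius-1 code histogram: mean, median, peaks, uniformity |

Matrix families operate on an in-ROI min–max quantization to `Ng`
gray levels (default 32), which makes them invariant to positive
affine intensity rescaling.  Because the source literature lists the
Tamura family only as "coarseness 1–4, contrast, roughness", the four
coarseness descriptors here are pinned to summary statistics of the
per-pixel optimal-scale map; this convention is documented in
`features_tamura_lbp.py`.

## Command line

```bash
marrowtex simulate --seed 0 --out cohort/            # PNGs + manifest.csv
marrowtex extract cohort/manifest.csv --out features.csv
marrowtex stats features.csv --out stats/            # per-sequence tests + JSON summary
marrowtex model features.csv --seed 0 --budget 200 --out model/
marrowtex run-all --seed 0 --budget 200 --out run/   # everything in one pass
```

Key flags: `--ng` (gray levels), `--alpha` (strict significance on
adjusted p), `--q` (FDR level), `--k-top` / `--max-combo`
(combination search space), `--n-rep` (repetitions), `--budget`
(cap on combinations searched per repetition), `--paper-order`
(balance *before* the 70/30 split — reproduces the source protocol's
ordering, which leaks synthetic copies of test subjects into
training; off by default).  Every stage writes a JSON run manifest
with seeds and configuration.

## Statistical workflow

Per sequence and per feature: Jarque–Bera normality in each of the
three groups (BME/INJ/OST) chooses ANOVA (all groups normal at 0.05)
or Kruskal–Wallis; BH-FDR is applied separately within the two branch
families; features significant at adjusted p < 0.001 get post hoc
pairwise comparisons (Tukey HSD, or Dunn mean-rank tests with
Bonferroni correction).

## Model pipeline

Random-forest impurity importance ranks the 162 per-subject features
(81 × 2 sequences); all combinations of the top 20 with up to 5
members are evaluated; each repetition draws a stratified 70/30
split, balances the training partition (bootstrap augmentation, then
SMOTE-style interpolation to equal class sizes), selects
hyperparameters by stratified 10-fold cross-validation, and scores
accuracy, per-class TPR and macro one-vs-rest AUC on the untouched
test partition.  Row-provenance tags assert that test rows never
participate in balancing.

## Synthetic cohorts

`marrowtex.synthetic_cohort` generates three-group, two-channel
cohorts (default 41/37/43 subjects, 242 ROIs) from a normalized
structured random field with four per-cell knobs (correlation length,
micro-blob density, intensity scale, plateau contrast).  The default
parameter table is calibrated so the five composite descriptors
separate the groups with the study's directionality: PD-FSE joint
maximum, long-run low-gray emphasis and run-length variance ordered
BME > INJ > OST; STIR mean absolute deviation and gray-level zone
variance ordered BME < OST < INJ.

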