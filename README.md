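# isomirpanel

Discovery of isomiR biomarker panels for cancer-subtype classification.

IsomiRs are length/sequence variants of mature miRNAs produced by
imprecise Drosha/Dicer cleavage or nucleotide addition (named e.g.
`hsa-miR-21-5p |3′t-2`: two nucleotides trimmed from the 3′ end).
Their expression profiles can separate disease subtypes that the parent
miRNAs cannot, but a quantification run yields tens of thousands of
isomiRs, most of them barely detected, and subtype cohorts are heavily
imbalanced. This package implements a three-stage pipeline that turns an
isomiR expression matrix plus subtype labels into a compact biomarker
panel:

1. **Low-expression filtering.** With *q* features and total
   expressions *TE = {te₁ … te_q}* (each *teτ = Σₐ xτᵃ*), the "soft"
   significance threshold is

   θ = q · ȲE̅ / χ²₍₁₋α/₂₎(q),  α = 0.05 by default,

   where χ²₍₁₋α/₂₎(q) is the chi-square quantile with *q* degrees of
   freedom. Features with *teτ < θ* are treated as noise and removed —
   the threshold adapts to the dataset instead of using a hard cutoff.

2. **Kernel-density mutual-information weighting.** Classical MI
   estimators need the feature and the label to be both continuous or
   both discrete. Here the feature is continuous (expression, min-max
   normalised to [0, 1]) and the label discrete, so the plug-in
   estimator mixes a Gaussian kernel with the 0/1 label metric
   d(yᵢ, yⱼ):

   f(xᵢ) = (1/√(2π)·n) Σⱼ exp(−(xᵢ−xⱼ)²/2)
   f(yᵢ) = (1/√(2π)·n) Σⱼ exp(−d(yᵢ,yⱼ)/2)
   f(xᵢ,yᵢ) = (1/(2π·n)) Σₖ exp(−√((xᵢ−xₖ)² + d(yₖ,yᵢ))/2)

   I(x, Y) = (1/n) Σᵢ ln [ f(xᵢ,yᵢ) / (f(xᵢ)·f(yᵢ)) ]

   The weight I(x, Y) ranks features by how much their expression says
   about the subtype; a constant feature scores exactly 0. Fisher-score
   and Hellinger-distance weightings are included as baselines.

3. **Panel selection.** For each candidate panel size *N*, the top-*N*
   features are evaluated by stratified 5-fold cross-validation of an
   RBF-SVM; training folds are min-max scaled and SMOTE-balanced
   (minority classes oversampled by nearest-neighbour interpolation),
   test folds are untouched, and performance is the macro-averaged
   one-vs-rest ROC AUC. The chosen panel is the smallest *N* after
   which no larger panel improves the AUC by at least ε (default
   0.005) — the plateau of the AUC curve.

A seeded synthetic-data generator reproduces the statistical structure
this pipeline assumes (exponential-law noise totals concentrated below
1, a small planted set of informative features, imbalanced 4-subtype
labels), so every stage is testable without any download.

## Worked example

```python
from isomirpanel import GeneratorConfig, generate, run_pipeline

matrix, labels, truth = generate(GeneratorConfig(seed=1))
res = run_pipeline(matrix, labels, seed=1)
```

Running `python examples/03_discover_panel.py` (exactly the above plus
printing) gives:

```
benchmark: 500 features x 200 samples, classes {'ERa+HER2+': 22, 'ERa+HER2-': 135, 'ERa-HER2+': 9, 'TripleNeg': 34}
filter: theta = 17.12, kept 20/500 features
AUC curve (panel size N -> mean macro-AUC over 5 folds):
  N= 1  AUC=0.8287
  ...
  N=16  AUC=0.9492
  N=17  AUC=0.9522  <- chosen
  N=18  AUC=0.9546
  ...
chosen panel size: 17 (macro-AUC 0.9522)
planted features recovered in the panel: 17/20
```

The filter removes all 480 noise features (their totals fall below
θ ≈ 17.1) while keeping the 20 planted informative ones; the AUC curve
climbs while added features contribute complementary subtype
information and flattens near N = 17, where the plateau rule stops; the
chosen panel recovers 17 of the 20 planted features at macro-AUC 0.95.
The other examples demonstrate the filter (`01`), the MI weight on a
4-sample micro-instance (`02`) and the Fisher/Hellinger comparison
(`04`).

## Command line

The same pipeline is available as a CLI for TSV inputs (expression
matrix: `isomir_id` + one column per sample; labels: `sample_id`,
`subtype`):

```bash
isomirpanel synth  --out-dir data --seed 1
isomirpanel run    --matrix data/matrix.tsv --labels data/labels.tsv \
                   --out-dir results --seed 1
# or stage by stage: isomirpanel filter / weight / baseline / select
```

`run` writes `filtered_matrix.tsv`, `filter_report.tsv`, `weights.tsv`
(+ full-precision sidecar), `auc_curve.tsv`, `panel.tsv` and
`summary.json`; running the stages separately produces byte-identical
files. A YAML config (`--config`) mirrors every flag; flags override
the file.

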