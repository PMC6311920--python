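"""Full biomarker-panel discovery on a synthetic benchmark.

Filter -> improved-MI weighting -> top-N SVM evaluation (SMOTE-balanced
training folds, stratified 5-fold CV, macro-AUC) -> plateau panel-size
selection.  The benchmark plants 20 informative features among 480 noise
features with imbalanced 4-subtype labels, so we can check how much of
the planted signal the chosen panel recovers.
"""

from isomirpanel import GeneratorConfig, generate, run_pipeline

matrix, labels, truth = generate(GeneratorConfig(seed=1))
print(f"benchmark: {matrix.n_features} features x {matrix.n_samples} samples, "
      f"classes {labels.class_counts()}")

res = run_pipeline(matrix, labels, seed=1)
fr, sel = res.filter_result, res.selection
print(f"filter: theta = {fr.theta:.2f}, kept {fr.n_kept}/{fr.q} features")
print("AUC curve (panel size N -> mean macro-AUC over 5 folds):")
for n, a in zip(sel.grid, sel.auc):
    marker = "  <- chosen" if n == sel.chosen_n else ""
    print(f"  N={n:2d}  AUC={a:.4f}{marker}")

recovered = len(set(sel.panel) & set(truth))
print(f"chosen panel size: {sel.chosen_n} "
      f"(macro-AUC {sel.auc[sel.grid.index(sel.chosen_n)]:.4f})")
print(f"planted features recovered in the panel: {recovered}/{len(truth)}")
print("panel head:", ", ".join(sel.panel[:3]), "...")
# The curve rises while panels add complementary subtype information and
# flattens once further features stop improving classification; the
# plateau rule picks the smallest panel at that point.
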