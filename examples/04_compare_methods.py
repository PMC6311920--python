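"""Compare improved-MI weighting with Fisher and Hellinger baselines.

All three methods rank the filtered features, and each ranking is pushed
through the same SMOTE-balanced SVM evaluation; the comparison is the
panel size each method needs and the macro-AUC it reaches there.
"""

from isomirpanel import GeneratorConfig, generate, run_pipeline

matrix, labels, truth = generate(GeneratorConfig(seed=2))
print(f"{'method':<10} {'panel size':>10} {'macro-AUC':>10} {'planted':>8}")
for method in ("mi", "fisher", "hellinger"):
    res = run_pipeline(matrix, labels, method=method, seed=2)
    sel = res.selection
    auc = sel.auc[sel.grid.index(sel.chosen_n)]
    rec = len(set(sel.panel) & set(truth))
    print(f"{method:<10} {sel.chosen_n:>10d} {auc:>10.4f} {rec:>5d}/20")
# A smaller panel at comparable AUC means the weighting concentrates the
# class-relevant features nearer the top of its ranking.
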