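"""Confusion-matrix metrics and the exact binomial interval on accuracy.

Evaluates a set of predictions the way a clinical classification report
does: per-class precision/recall/F1 from the predicted-by-true confusion
matrix, and overall accuracy with the exact (Clopper-Pearson) 95% interval
that R's binom.test reports.
"""

from episcore import accuracy_with_ci, evaluate_predictions

true = ["Normal"] * 29 + ["BWS1"] * 3 + ["BWS2"] * 3 + ["SRS1"] * 6 + ["FXS"] * 2
pred = (
    ["Normal"] * 29
    + ["BWS1", "BWS1", "BWS2"]
    + ["BWS2"] * 3
    + ["SRS1"] * 5 + ["Normal"]
    + ["FXS"] * 2
)
report = evaluate_predictions(true, pred, ["Normal", "BWS1", "BWS2", "SRS1", "FXS"])
print(report.render())

acc, lo, hi = accuracy_with_ci(50, 52, 0.95)
print(
    f"\n50 correct of 52: accuracy {acc:.4f}, exact 95% CI ({lo:.3f}, {hi:.3f})\n"
    "The interval comes from Beta quantiles, i.e. inverting the exact binomial\n"
    "test, so it is valid even at small test-set sizes."
)
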