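"""Screening-metric arithmetic on a clinical-style confusion table.

Uses the confusion counts of a published 364-subject evaluation (236
ischemic by angiography/FFR, 128 non-ischemic) to show the metric
conventions: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, each displayed half-up at one decimal.
"""

from twac.evaluation import ConfusionCounts, metrics_report, evaluate_by_group

total = ConfusionCounts(tp=199, tn=107, fp=21, fn=37)
print("total row:", metrics_report(total))

# per-subgroup report from raw label vectors
truth = [1] * 4 + [0] * 4
predicted = [1, 1, 1, 0, 0, 0, 0, 1]
groups = ["ptb"] * 4 + ["clinic"] * 4
print("\ngrouped report:")
print(evaluate_by_group(truth, predicted, groups).to_string(index=False))
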