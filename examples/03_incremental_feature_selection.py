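"""Trace the accuracy-vs-subset-size curve of incremental feature selection.

Features are added in decreasing-CL order (tied blocks together) and each
cumulative subset is scored by stratified 7-fold cross-validation of the
RBF-SVM at its default operating point (c = 2^11, g = 2^-13).
"""

import canlect as cl

spec = cl.SimSpec(n_pos=40, n_neg=40, length_range=(150, 150),
                  enrichment=8.0, seed=5)
dataset = cl.generate(spec)
ranking = cl.confidence_levels(cl.tabulate_counts(dataset))

result = cl.incremental_feature_selection(
    dataset, ranking, folds=7, seed=0, max_size=60
)

print("subset_size  cv_accuracy")
for size, acc in zip(result.subset_sizes, result.cv_accuracy):
    print(f"{size:>11d}  {acc:.4f}")
print(f"\nbest accuracy {max(result.cv_accuracy):.4f} "
      f"first reached at {result.argmax_size} features")
print("chosen subset:", ", ".join(result.chosen_features()))
# Accuracy climbs as informative (planted) tripeptides enter the subset
# and plateaus once they are all included; extra noise features beyond
# the plateau add nothing.
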