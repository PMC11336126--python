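"""Decision-tree disease classification from microstate features.

Simulates the cohort, assembles the 28-column per-subject microstate
feature vector (durations, occurrences, coverages, transition
probabilities, global rows), splits 8:2 with stratification, runs
five-fold cross-validation on the training set and reports the held-out
test performance.
"""

from mstates.classify import (
    crossvalidate_tree,
    evaluate_classifier,
    feature_columns,
    split_train_test,
)
from mstates.segmentation import metrics_table
from mstates.synth import CohortSpec, simulate_cohort

spec = CohortSpec(seed=5)
subjects, _ = simulate_cohort(spec, make_recordings=False, duration_s=60.0)
metrics = metrics_table([(s.subject_id, s.group, s.true_metrics)
                         for s in subjects])

# ground-truth metrics carry no GEV (that is a property of a fitted
# segmentation), so restrict the feature vector to fully observed columns
cols = [c for c in feature_columns() if metrics[c].notna().all()]
features = metrics[["subject", "group"] + cols]
train, test = split_train_test(features, test_fraction=0.2, seed=0)
print(f"{len(train)} training / {len(test)} test subjects "
      f"(stratified 8:2 split of {len(features)})")

scores, tree = crossvalidate_tree(train, cols, folds=5, seed=0)
print("five-fold CV accuracy:", ", ".join(f"{s:.2f}" for s in scores),
      f"(mean {scores.mean():.2f})")

report = evaluate_classifier(tree, test, cols)
print("\nheld-out test report:")
print(report.to_frame().to_string(index=False))
print(f"AUC = {report.auc:.2f}")
print("\n(the planted group effect is a 6 ms class-C dwell shift; on these "
      "noiseless ground-truth metrics it is cleanly separable — metrics "
      "estimated from noisy EEG, as in the full pipeline, classify far "
      "closer to chance)")
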