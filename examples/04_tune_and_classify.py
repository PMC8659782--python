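"""Tune the RBF-SVM with the grey wolf optimizer and evaluate per grade.

Renders a small balanced image set, extracts features, tunes (c, g) by
5-fold cross-validated accuracy, and prints the tuned parameters, the
confusion matrix, and per-grade accuracy on the held-out 30%.
"""

import numpy as np

from notoroot import (
    ExtractionConfig,
    PreprocessConfig,
    SyntheticImageSpec,
    TuneConfig,
    evaluate,
    extract_feature_table,
    generate_image_dataset,
    stratified_split,
    train_svm,
    tune_svm,
)
from notoroot.classifiers import split_features

records = generate_image_dataset(SyntheticImageSpec(), n_per_grade=25, seed=5)
table = extract_feature_table(
    records, config=ExtractionConfig(preprocess=PreprocessConfig(resize_to=None))
)
train, test = stratified_split(table, 0.7, seed=5)

# a small search budget keeps this example quick; defaults are pop 20 / 100 iters
opt = tune_svm(train, "gwo", TuneConfig(pop=8, iters=15), seed=5)
print(f"GWO best c={opt.best_c:.3f}, g={opt.best_g:.4f}, "
      f"CV fitness {opt.best_fitness:.2f}% (iteration {opt.best_iteration})")

Xtr, ytr = split_features(train)
Xte, yte = split_features(test)
report = evaluate(train_svm(Xtr, ytr, opt.best_c, opt.best_g), Xte, yte)
print(f"\ntest accuracy {report.accuracy_pct:.2f}% on {report.n} specimens")
print("confusion matrix (rows = true grade I..IV):")
print(np.array(report.confusion))
for grade, acc in report.per_class_pct.items():
    print(f"  grade {grade}: {acc:.1f}%")
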