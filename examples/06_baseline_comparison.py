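"""Compare the SVM against decision tree, random forest and logistic
regression on the identical split of the identical DPC matrix.

All four models are trained on the same stratified 80% and scored on
the same held-out 20%, so the rows are directly comparable.
"""

from patatinpred import (
    BaselineConfig,
    SplitConfig,
    SVMConfig,
    SyntheticConfig,
    comparison_table,
    encode_dataset,
    evaluate_model,
    generate,
    split_dataset,
    train_and_score_baseline,
    train_svm,
)

matrix = encode_dataset(generate(SyntheticConfig(n_per_class=200, seed=4)), "DPC")
train, test = split_dataset(matrix, SplitConfig(seed=4))

reports = {"svm_polynomial": evaluate_model(
    train_svm(train, SVMConfig(kernel="polynomial", seed=4)), test
)}
for name in ("decision_tree", "random_forest", "logistic_regression"):
    reports[name] = train_and_score_baseline(train, test, BaselineConfig(name, seed=4))

table = comparison_table(reports)
print(table.pivot(index="metric", columns="model", values="value").round(3).to_string())
print("\nEach column is one model scored on the same held-out 80 sequences.")
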