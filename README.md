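# patatinpred

Sequence-based binary classification of **patatin-like phospholipase
proteins** — the protein family whose maize member (the *mtl*/*nld*/*ZmPLA1*
gene product) triggers *in-vivo* maternal haploid induction — against
arbitrary non-patatin-like proteins, using composition descriptors and a
support vector machine.

The package is aimed at crop-genomics and protein-annotation groups who
need a fast, sequence-only screen for patatin-like (lipolytic acyl
hydrolase) candidates, and at anyone who wants a compact, fully tested
reference implementation of the classic descriptor + SVM protein
classification pipeline.

## The model

Each protein sequence of length *N* over the 20-letter amino-acid
alphabet is mapped onto fixed-length descriptor vectors:

| scheme | dims | definition |
|--------|-----:|------------|
| AAC    |   20 | residue frequencies `f_i / N` |
| DPC    |  400 | overlapping dipeptide frequencies `M_j / (N−1)` |
| GAAC   |    5 | frequencies of 5 physicochemical groups `N(g) / N` (aliphatic GAVLMI, aromatic FYW, positive KRH, negative DE, uncharged STCPNQ) |
| GDPC   |   25 | group-pair dipeptide frequencies `N_rs / (N−1)` |
| CTDC   |   39 | composition `C(r) = N(r)/N` of 3 classes for 13 physicochemical attributes |
| CTDT   |   39 | transitions `T(r,s) = (N(r,s)+N(s,r)) / (N−1)` between class pairs |

A C-SVM with one of four kernels (RBF, linear, sigmoid, polynomial) is
trained on a **balanced** positive/negative design with a stratified
80/20 hold-out split. The evaluation harness computes precision,
recall, F1, accuracy, the Matthews correlation coefficient
`MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, and ROC/AUC;
model selection uses stratified and repeated 10-fold cross-validation,
learning curves, and an exhaustive grid search over
`C ∈ {10⁻³ … 10⁷}` × `γ ∈ {10⁻⁵ … 10³}` (powers of ten, 99 pairs).
Features are ranked by mutual information
`I(X;Y) = D_KL(P(X,Y) ‖ P_X P_Y)` with the class label, and the SVM is
compared against decision-tree, random-forest and logistic-regression
baselines on the identical split.

A synthetic-data generator produces balanced datasets of i.i.d.
background sequences in which the positive class is enriched for a
small set of *planted dipeptides*, so every pipeline stage is testable
end to end without any external download.

## Worked example

```python
from patatinpred import (SplitConfig, SVMConfig, SyntheticConfig,
                         encode_dataset, evaluate_model, generate,
                         split_dataset, train_svm)

data = generate(SyntheticConfig(n_per_class=200, seed=0))   # 400 sequences
matrix = encode_dataset(data, "DPC")                        # 400 x 400 + label
train, test = split_dataset(matrix, SplitConfig(seed=0))    # 320 / 80
for kernel in ("rbf", "linear", "sigmoid", "polynomial"):
    model = train_svm(train, SVMConfig(kernel=kernel, seed=0))
    r = evaluate_model(model, test)
    print(kernel, round(r.accuracy, 3), round(r.mcc, 3))
```

prints

```
rbf 0.988 0.975
linear 0.887 0.795
sigmoid 0.988 0.975
polynomial 0.988 0.975
```

i.e. on the held-out 80 sequences the non-linear kernels recover the
planted dipeptide signal almost perfectly (MCC near 1), while the
linear kernel trails — the qualitative pattern expected when the class
signal lives at the dipeptide rather than the residue level. The
`examples/` directory has one short script per capability (encoding,
hold-out evaluation, cross-validation, grid search, MI ranking,
baseline comparison); each prints its numbers with a line on what they
mean. The same stages are scriptable via the `patatinpred` CLI
(`encode`, `train`, `evaluate`, `cv`, `gridsearch`, `rank`, `compare`,
`synth`, `run`).

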