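# Methods

## Problem setting

Patatin-like phospholipases carry a lipolytic acyl hydrolase domain;
in maize the family member encoded by *mtl*/*nld*/*ZmPLA1* triggers
maternal haploid induction. The package frames their recognition as a
balanced binary sequence-classification problem: given an amino-acid
sequence, predict patatin-like (positive) vs non-patatin-like
(negative). The design contract is a *balanced* dataset — equal class
counts — so accuracy, MCC and AUC are directly comparable and a
majority-class classifier sits at 0.5.

## Descriptors

All six encoders are pure composition statistics over the 20-letter
alphabet; none uses alignment, evolutionary profiles or structure.

- **AAC** (20): residue counts / N.
- **DPC** (400): overlapping dipeptide counts (window stride 1) /
  (N−1). Captures first-order residue ordering; normalised so every
  vector sums to 1.
- **GAAC** (5) and **GDPC** (25): the same statistics after collapsing
  residues into five physicochemical groups (aliphatic GAVLMI,
  aromatic FYW, positively charged KRH, negatively charged DE,
  uncharged STCPNQ). Both are exact linear aggregations of AAC/DPC
  over the grouping table — a property the test suite asserts.
- **CTDC / CTDT** (39 each): for 13 physicochemical attributes
  (seven hydrophobicity scales, normalised van der Waals volume,
  polarity, polarizability, charge, secondary structure, solvent
  accessibility), each partitioning the alphabet into 3 classes,
  CTDC reports the per-class composition N(r)/N and CTDT the
  frequency of adjacent class changes (N(r,s)+N(s,r))/(N−1) for the
  three unordered class pairs. The 13×3 grouping table ships as a
  human-readable TSV resource (`data/ctd_groups.tsv`, iFeature/Dubchak
  convention) and is validated at load time to be a partition; only
  this 13-attribute table yields the contracted 39 dimensions. The
  distribution (CTDD) block is deliberately not implemented.

Column orders are fixed (alphabetical residues and dipeptides, g1..g5
row-major, attribute-major CTD with transition pairs ordered 1-2, 2-3,
1-3) so feature matrices are bit-comparable across runs.

Input hygiene: sequences are uppercased at parse time; exact duplicate
sequences collapse to their first occurrence (the package's reading of
redundancy removal — no similarity-threshold clustering is attempted);
records with residues outside the standard alphabet (B, J, O, U, X, Z,
…) are dropped by default (configurable: reject/drop/strip) because
every descriptor denominator is defined only over the 20 letters;
records shorter than 2 residues are dropped. Filtering is idempotent
and conserves record counts (kept + removed = input).

## Classifier and evaluation

The SVM uses libsvm via scikit-learn with the four kernels rbf,
linear, sigmoid, polynomial. "Default hyper-parameters" are pinned to
C = 1.0, gamma = 1/(n_features · Var(X)) ("scale"), degree 3, coef0 0.
No feature standardisation is applied by default — all descriptors
already live in [0, 1] — but a `scale_features` flag exists.

Metrics are computed from the confusion matrix by the standard
formulas (precision, recall, F1, accuracy, MCC); a zero denominator in
any formula yields 0 together with a warning flag on the report, the
documented convention for degenerate folds (e.g. a constant classifier
on a balanced set scores accuracy 0.5, MCC 0 with a flag). Because
positive-class and macro-averaged precision/recall differ in general,
the report carries both (`precision` = positive class, `macro_*` =
unweighted two-class mean).

AUC is computed two ways and both are reported: `auc` is the
trapezoidal area under the ROC built from continuous decision-function
scores (and equals the Mann–Whitney U statistic / (n⁺ n⁻), an identity
the tests check), while `auc_from_labels` is the single-operating-point
value (TPR + TNR)/2 obtained when only hard predictions enter the ROC.
The two coincide only for a perfectly ranked score vector; reporting
both surfaces the discrepancy instead of silently choosing one.

Cross-validation uses stratified k-fold (k = 10 default) with seeded
shuffling; fold-level score is accuracy, with full per-fold metric
reports available on request. Repeated CV runs r independently
reshuffled k-fold passes and pools all r·k fold scores. Reported
spread is the population standard deviation (ddof = 0) of fold scores,
matching the common library convention. Learning curves evaluate
training and validation accuracy at 10 evenly spaced training sizes up
to the fold-train maximum (k−1)/k·n, with shuffled subsampling so
small subsets stay class-mixed.

The grid search scores every (C, γ) pair on the inclusive powers-of-ten
grids C = 10⁻³…10⁷ (11 values) × γ = 10⁻⁵…10³ (9 values) — 99
configurations — by stratified 10-fold CV accuracy, returns the full
surface (heat-map-ready), and breaks ties deterministically toward the
smallest C, then the smallest γ (an invented but fixed convention).

Baselines — decision tree, random forest (100 trees), logistic
regression — run through the identical split and metric path so the
comparison is paired. Logistic regression uses `max_iter=1000`: the
historic default of 100 does not converge on 400-dimensional DPC
features, and a non-converged solver would make the comparison
seed-dependent in an uninteresting way. Baseline hyper-parameters are
recorded in the run manifest.

## Mutual-information ranking

Features are ranked by estimated I(feature; label) in nats. The paper
formula defines MI but not an estimator for continuous compositions,
so two are exposed: the default k-nearest-neighbour estimator for
discrete targets (k = 3, seeded) and an equal-width histogram plug-in
estimator (10 bins) used as an independent cross-check — the tests
require both to agree on the top planted feature, and the histogram
estimator to hit the closed form ln 2 exactly for a feature identical
to a balanced binary label. Ties in the ranking break
lexicographically. Absolute MI values are estimator-dependent;
only ranks should be compared across estimators.

## Synthetic data generator

`generate(SyntheticConfig(...))` emulates the balanced two-class
study design: negatives are i.i.d. strings over a background residue
distribution (uniform by default); positives are drawn from the same
background, after which planted dipeptides are written in at uniform
random positions, Poisson-distributed with mean `enrichment` plantings
per 100 residues. Defaults — 300 sequences per class, lengths uniform
in 100–400 (real patatin-like proteins run ≈ 400 aa), three planted
dipeptides RI, LA, ID, enrichment 8 — are the fixture conditions used
throughout the tests. Planting at the dipeptide level (not single
residues) makes DPC genuinely more informative than AAC/GAAC on these
fixtures, mirroring the qualitative descriptor ordering of interest.

What the generator does *not* emulate: real amino-acid background
frequencies, domain architecture, length–class correlations,
phylogenetic redundancy, or homology structure between train and test.
Passing tests therefore demonstrate that the pipeline recovers a known
dipeptide-level signal under the stated noise model — not that the
real-data benchmark numbers are attainable on arbitrary proteomes.
With `enrichment=0` the two classes are exchangeable and any
classifier's CV accuracy concentrates at 0.5, which the tests use as a
leakage check.

## Numerical and design choices

- Seeds flow explicitly through every config; repeated-CV sub-seeds
  derive from a `SeedSequence`, keeping values below 2³¹.
- Splits use stratified shuffling; 0.8 of a balanced 1170-row matrix
  gives exactly 936/234 with 468/117 positives.
- Degenerate inputs fail loudly: single-class training sets, k larger
  than the smallest class, feature-name mismatches between train and
  apply, empty datasets after filtering, out-of-range `top_k`.
- Problem sizes in the test and acceptance runs (585/class at study
  scale, 100–300/class elsewhere, 200 samples for the grid-search
  demonstration) were chosen as the smallest sizes at which the
  planted-signal effects are stable across seeds.
- The published benchmark numbers (hold-out ≈ 0.95 accuracy for the
  polynomial kernel on DPC, repeated-CV ≈ 0.94, random forest ≈ 0.912)
  are reproducible only on the curated UniProt-derived dataset, which
  cannot be redistributed; the reproduction tests run when that
  spreadsheet is placed at `data/supplementary_s1.xlsx` and fail with
  an explanatory message otherwise.

## Known limitations

Binary, balanced designs only — no probability calibration, no
multi-class support, no class-imbalance handling. No clustering-based
redundancy reduction (exact-duplicate removal only), no UniProt
retrieval, no descriptor beyond the six above, and no statistical
tests between kernels or models.
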