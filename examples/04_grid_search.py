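"""Exhaustive C x gamma grid search for the RBF kernel.

Scores all 99 combinations of C in 1e-3..1e7 and gamma in 1e-5..1e3
(powers of ten) by stratified 10-fold CV accuracy, and prints the best
region of the accuracy surface. The surface DataFrame is heat-map
ready (rows = C, columns = gamma).
"""

from patatinpred import CVConfig, SyntheticConfig, encode_dataset, generate
from patatinpred.evaluation import grid_search

matrix = encode_dataset(generate(SyntheticConfig(n_per_class=100, seed=2)), "DPC")
result = grid_search(matrix, kernel="rbf", cv_cfg=CVConfig(k=10, seed=2))

C, gamma = result.best_params
print(f"evaluated {len(result.grid)} (C, gamma) pairs")
print(f"best: C={C:g}, gamma={gamma:g} -> CV accuracy {result.best_score:.3f}\n")

surface = result.surface()
print("accuracy surface (rows C, columns gamma):")
print(surface.round(2).to_string())
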