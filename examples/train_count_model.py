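"""Train the plants-per-object network with recursive feature elimination.

Builds a labelled object table from a few synthetic scenes (each object
carries its exact plant count), prunes the 13 morphological features by
weight-based RFE, and reports held-out accuracy of the counting network.
"""

import numpy as np

from wheatdensity import (
    FEATURE_NAMES,
    evaluate,
    recursive_feature_elimination,
    train_network,
)
from wheatdensity.benchmarks import labeled_scene_batch

table, records = labeled_scene_batch(
    densities=(150.0, 300.0, 450.0), seeds=(11, 12, 13, 14),
)
print(f"{len(table)} labelled objects from {len(records)} scenes "
      f"({int((table.true_count == 0).sum())} null objects)")

trace, model = recursive_feature_elimination(
    table[FEATURE_NAMES], table["true_count"], k_n=2, reps=5, seed=0,
)
print("RFE RMSE by subset size:",
      {n: round(r, 3) for n, _, r in trace.records})
print(f"kept {trace.chosen_n} features: {trace.chosen_features} "
      f"(smallest subset within 2% of the best RMSE)")

rng = np.random.default_rng(0)
perm = rng.permutation(len(table))
n_test = len(table) // 10
tr, te = perm[n_test:], perm[:n_test]
final = train_network(table.iloc[tr][trace.chosen_features],
                      table.iloc[tr]["true_count"], k_n=2, seed=1)
rep = evaluate(final, table.iloc[te][trace.chosen_features],
               table.iloc[te]["true_count"])
print(f"held-out ({rep.n_test} objects): R2 = {rep.r2:.2f}, "
      f"RMSE = {rep.rmse:.2f} plants/object, bias = {rep.bias:+.2f}")
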