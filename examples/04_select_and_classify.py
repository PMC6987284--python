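"""Evolutionary feature selection + crossed 3-NN evaluation, end to end.

The selector evolves a feature subset together with an A/B split of the
cohort, scoring each candidate by the mean of the two crossed 3-NN
accuracies (train A / test B and vice versa).  The final report mirrors a
clinical diagnostic-accuracy table: confusion matrices per arm, pooled
metrics with exact binomial CIs, and per-arm ROC/AUC.
"""

import focusradiomics as fr
from focusradiomics.twist import TwistConfig

table = fr.planted_feature_table(n_per_class=30, n_informative=3,
                                 n_noise=50, effect_size=2.0, seed=5)
result = fr.evolve(table, TwistConfig(population_size=60, generations=80,
                                      seed=5))

info = sorted(f for f in result.selected_features if f.startswith("info"))
print(f"selected {len(result.selected_features)} of {table.shape[1] - 1} "
      f"features; informative ones found: {info}")
print(f"best crossed fitness: {result.best_fitness:.3f}")
print(f"group A: {len(result.group_A)} cases, group B: {len(result.group_B)}")

report = fr.crossed_evaluation(table, result)
print("\n" + report.to_markdown())
print("The three planted features (class means 2 SD apart) drive the "
      "separation; the pooled\ncolumn sums the two test arms, and the AUC "
      "column averages the two per-arm AUCs.")
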