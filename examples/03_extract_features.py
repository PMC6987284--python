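"""Extract the 215-feature radiomic table from a synthetic cohort.

Per time-point: 6 intensity statistics, 5 shape descriptors (computed once
from the single mask, replicated), 12 GLCM and 20 GLRLM texture statistics
(mean and SD over the 13 unique 3D directions) = 43; over T0-T4 that is
215 features per case.
"""

import focusradiomics as fr

cohort = fr.generate_cohort(fr.CohortConfig(n_benign=4, n_malignant=4, seed=11))
table = fr.extract_cohort(cohort)

print(f"feature table: {table.shape[0]} cases x {table.shape[1] - 1} features")
per_t = sum(c.endswith("_T2") for c in table.columns if c != "label")
print(f"features per time-point: {per_t}")

cols = ["Mean_T0", "Mean_T1", "Mean_T4", "Entropy_mean_T2", "Volume_T0"]
print("\n", table[cols + ["label"]].round(2).to_string())

mal = table[table.label == fr.MALIGNANT]
ben = table[table.label == fr.BENIGN]
print(f"\nMean_T1 (early enhancement): malignant {mal['Mean_T1'].mean():.1f} "
      f"vs benign {ben['Mean_T1'].mean():.1f}")
print(f"Mean_T4 (late):              malignant {mal['Mean_T4'].mean():.1f} "
      f"vs benign {ben['Mean_T4'].mean():.1f}")
print("\nMalignant cases are brighter early and dimmer late (wash-out): the "
      "per-time-point\nfeature blocks encode exactly this dynamic pattern.")
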