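"""Build a classifier table, balance it with SMOTE and partition it.

Per-recording aggregation takes the median (input sets 2/4) or the
trend-directed 10th/90th percentiles (sets 1/3) of the window features;
sets 1/2 append six obstetric covariates. SMOTE grows the minority
(imminent) class 3:1 using five neighbors, and the balanced table is split
into stratified train/validation/test subsets 30 times.
"""

import numpy as np

from ehgpred import (
    SynthConfig,
    build_table,
    extract_cohort,
    generate_cohort,
    make_partitions,
    smote,
)

cohort = generate_cohort(SynthConfig(n_imminent=10, n_control=30, duration_s=600.0, seed=4))
feats = extract_cohort(cohort)

for input_set in (2, 4):
    table = build_table(feats, input_set=input_set)
    print(f"input set {input_set}: {table.n_samples} samples x "
          f"{table.X.shape[1]} features, {int(table.y.sum())} positive")

table = build_table(feats, input_set=2)
balanced = smote(table, ratio=3.0, k=5, seed=4)
print(f"after SMOTE 3:1: {int((balanced.y == 1).sum())} minority / "
      f"{int((balanced.y == 0).sum())} majority "
      f"({int((balanced.origin == 'synthetic_smote').sum())} synthetic)")

parts = make_partitions(balanced.y, n_reps=30, seed=4)
tr, va, te = parts.partitions[0]
print(f"partition sizes: train {tr.size}, validation {va.size}, test {te.size}")
frac = balanced.y.mean()
print(f"class fraction {frac:.2f} preserved per subset within one sample: "
      f"{[float(round(np.mean(balanced.y[idx]), 2)) for idx in (tr, va, te)]}")
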