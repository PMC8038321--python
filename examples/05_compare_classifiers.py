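"""Compare classifier configurations with paired Wilcoxon tests.

Metrics from the same 30 partitions are compared pairwise — across the two
optimization criteria and across input sets — separately for validation and
test, with raw two-sided signed-rank p-values.
"""

import pandas as pd

from ehgpred import (
    SynthConfig,
    build_table,
    compare_report,
    extract_cohort,
    generate_cohort,
    prepare_views,
    run_experiment,
)

cohort = generate_cohort(SynthConfig(n_imminent=12, n_control=36, duration_s=600.0, seed=6))
feats = extract_cohort(cohort)

frames = []
grid = {"n_hidden": [25, 100], "activation": ["tanh"]}
for input_set in (2, 4):
    table = build_table(feats, input_set=input_set)
    views, _ = prepare_views(table, n_partitions=10, seed=6)
    results = run_experiment(
        views, classifier="elm", criteria=("f1", "sensitivity"), grid=grid,
        n_seeds=8, base_seed=6, input_set=input_set,
    )
    frames.extend(res.metric_table for res in results.values())

report = compare_report(pd.concat(frames, ignore_index=True))
summary = report.summary
val_f1 = summary[(summary.subset == "validation") & (summary.metric == "f1")]
print("validation F1 (mean +/- SD, CV%):")
for _, row in val_f1.iterrows():
    print(f"  {row['name']:<12} {row['mean']:5.1f} +/- {row['sd']:4.1f}  (CV {row['cv']:4.1f}%)")

sig = report.comparisons[report.comparisons.significant]
print(f"\n{len(report.comparisons)} paired comparisons, {len(sig)} significant at p < 0.05:")
print(sig.head(10).to_string(index=False))
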