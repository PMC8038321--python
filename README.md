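# ehgpred

Electrohysterogram-based prediction of imminent delivery in threatened
preterm labor.

Threatened preterm labor (TPL) is the most common cause of hospitalization
in the second half of pregnancy, yet most women admitted with TPL do not
deliver preterm. The uterine myoelectrical activity recordable on the
abdomen — the electrohysterogram (EHG) — changes measurably as labor
approaches: burst amplitude grows, spectral content shifts above 0.34 Hz,
and the signal becomes more regular. `ehgpred` is a reusable pipeline that
turns 30-minute two-channel EHG recordings plus six obstetric covariates
into a binary prediction of *imminent delivery*, defined as time to
delivery (TTD) ≤ 7 days.

The pipeline, end to end:

1. **Conditioning** — bipolar derivation M1 − M2, zero-phase Butterworth
   band-pass to 0.1–4 Hz, decimation to 20 Hz, 120 s analysis windows with
   50% overlap restricted to artifact-free intervals.
2. **Characterization** — 23 parameters per window: peak-to-peak amplitude;
   dominant frequencies DF1 (0.2–1 Hz) and DF2 (0.34–1 Hz); the H/L energy
   ratio E[0.34–1]/E[0.2–0.34]; power-spectrum deciles D1–D9; the spectral
   moment ratio SMR = M₋₁/M₅; binary and 6-state Lempel-Ziv complexity;
   sample, fuzzy and spectral entropy; time reversibility
   ⟨(x_t − x_{t−1})³⟩; Poincaré SD1, SD2, SD1/SD2.
3. **Aggregation** — per recording, either the median of each parameter or
   trend-directed percentiles (90th for parameters that rise in contractile
   periods, 10th for those that fall), optionally joined with the obstetric
   covariates (four input sets).
4. **Preparation** — SMOTE oversampling of the minority class at 3:1 with
   five neighbors, 30 stratified train/validation/test partitions
   (89/45/66 of 200), standardize + PCA retaining 98% variance per fold.
5. **Classification** — random forest (information-gain splits), extreme
   learning machine (random hidden layer, pseudoinverse readout,
   score = (H β + 1)/2) and kernel-weighted K-nearest neighbors, designed
   over hyperparameter grids under two optimization criteria (mean
   validation F1, or mean validation sensitivity with F1 tie-break), with
   the best validation seed stored per partition for exact reproducibility.
6. **Evaluation** — F1 / sensitivity / specificity in percent with mean, SD
   and coefficient of variation over the 30 partitions, paired Wilcoxon
   signed-rank comparisons, and vertically averaged ROC curves with AUC.

Because the corresponding clinical recordings are private, the package
ships a synthetic cohort generator (`ehgpred.synth`) producing
study-shaped cohorts — 140 recordings, 30 imminent / 110 controls, with
class-dependent burst amplitude, spectral content and regularity — so
every stage is testable and the full protocol can be exercised end to end.
See `docs/methods.md` for the model details and the generator's scope.

## Worked example

```python
from ehgpred import SynthConfig, build_table, extract_cohort, generate_cohort
from ehgpred import prepare_views, run_experiment

cohort = generate_cohort(SynthConfig(n_imminent=12, n_control=36,
                                     duration_s=600.0, seed=5))
table = build_table(extract_cohort(cohort), input_set=2)   # median EHG + obstetric
views, _ = prepare_views(table, n_partitions=10, seed=5)
results = run_experiment(views, classifier="elm",
                         criteria=("f1", "sensitivity"),
                         grid={"n_hidden": [10, 50, 100],
                               "activation": ["sigmoid", "tanh"]},
                         n_seeds=10, base_seed=5, input_set=2)
```

Running this (`python examples/04_train_and_select.py`) prints:

```
criterion f1: selected {'n_hidden': 10, 'activation': 'sigmoid'}
  validation: F1  96.9%  sens  97.5%  spec  96.2%
        test: F1  89.6%  sens  91.7%  spec  86.7%
  mean AUC: validation 96.9%, test 95.6%
criterion sensitivity: selected {'n_hidden': 50, 'activation': 'sigmoid'}
  validation: F1  95.5%  sens 100.0%  spec  90.0%
        test: F1  85.3%  sens  93.3%  spec  74.2%
  mean AUC: validation 98.6%, test 94.4%
```

The F1-optimized ELM balances sensitivity and specificity; the
sensitivity-optimized one pushes the true-positive rate on imminent
deliveries higher at the cost of specificity — the clinically relevant
trade-off, since a missed imminent delivery is costlier than a false
alarm. Test metrics sit below validation metrics, as expected for a
selection made on validation data. On synthetic cohorts the absolute
levels reflect the generator's stipulated effect sizes, not clinical
performance.

The other scripts in `examples/` walk through cohort simulation, window
features, aggregation/balancing and classifier comparison. A thin CLI
(`ehgpred simulate/extract/aggregate/prepare/train/report`) wraps the same
stages for shell use.

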