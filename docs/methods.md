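# Methods

`ehgpred` implements a complete evaluation pipeline for predicting imminent
delivery (time to delivery, TTD, of at most 7 days) in women with threatened
preterm labor from 30-minute two-channel abdominal electrohysterogram (EHG)
recordings. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic cohort generator does and does not
emulate.

## Signal model and conditioning

The analysis signal is the bipolar derivation M1 − M2 of two monopolar
abdominal electrodes, which cancels common-mode interference. It is
band-passed to 0.1–4 Hz — the EHG band, below ECG and most respiration
content — and decimated to 20 Hz. The filter is a 5th-order Butterworth
applied forward-backward (zero phase), chosen so that burst morphology is
not phase-distorted before the nonlinear features; decimation uses a
polyphase anti-aliasing filter. Both the filter family/order and the band
are configurable; zero-phase filtering of a signal already confined to the
band changes its RMS by well under 2% when the signal's energy sits in the
EHG fast-wave range (0.2–1 Hz), which is where real and synthetic EHG
energy lies. A residual DC offset from finite-length filtering is removed
explicitly, since the analysis band excludes DC.

Artifact handling is annotation-driven: each recording carries machine-
readable intervals of usable signal (half-open `[start, end)`, seconds from
recording start). Analysis windows are 120 s with 50% overlap, and a window
is admitted only if *every* sample is valid — partial windows would
contaminate the entropy and complexity estimates. A fully valid 30-min
recording yields 29 windows of 2400 samples. No automatic artifact detector
is provided.

## The 23 window parameters

Each window is summarized by 23 parameters chosen to capture the three
electrophysiological trends of approaching labor: rising amplitude, a
spectral shift toward the fast-wave-high band, and increasing regularity.

* **Amplitude**: peak-to-peak amplitude (`app`).
* **Spectral** (from a Hamming-tapered full-window periodogram, resolution
  1/120 Hz): dominant frequency in 0.2–1 Hz (`df1`) and 0.34–1 Hz (`df2`);
  the H/L energy ratio between 0.34–1 Hz (fast wave high) and 0.2–0.34 Hz
  (fast wave low); the nine deciles `d1…d9` of cumulative in-band (0.2–1 Hz)
  spectral power; and the spectral moment ratio `smr` = M₋₁/M₅ with
  Mₙ = Σ P(f)·fⁿ over 0.2–1 Hz. The 0.2–1 Hz band follows fast-wave
  physiology and avoids ECG/respiration interference; the moment orders
  (−1, 5) follow the Dimitrov-style index used in the EHG literature. All
  bands and orders are configurable.
* **Complexity/regularity**: binary and 6-state Lempel-Ziv complexity
  (LZ76 phrase counting, normalized as c·log_α(n)/n; binary symbolization
  is a median split, the multistate variant uses within-window equiprobable
  quantile bins, robust to amplitude nonstationarity); sample entropy and
  fuzzy entropy (m = 2, tolerance r = 0.15 × window SD, fuzzy membership
  exp(−(d/r)²) on mean-centered templates); spectral entropy (Shannon
  entropy of the normalized 0.1–4 Hz spectrum divided by log of the bin
  count, hence in [0, 1]); time reversibility (mean cubed lag-1 difference);
  and the Poincaré descriptors SD1, SD2, SD1/SD2 at lag 1.

Sample and fuzzy entropy count template pairs over the N − m templates whose
(m+1)-sample extension exists, so both template lengths see the same index
set; a pure ramp therefore gives sample entropy exactly 0. Undefined values
(zero-variance windows, empty bands, no template matches) are recorded as
NaN sentinels, never imputed; aggregation then skips those windows for that
feature only, and a recording is excluded only if a feature is missing in
every window.

### Numerical implementation of the entropies

The O(N²) pair loops are compiled (numba). Sample entropy enumerates pairs
in sorted order of the templates' first components and stops each scan at
the tolerance band edge — a pure pruning that leaves the integer counts
identical to the plain double loop. Fuzzy entropy evaluates
exp(−(d/r)²) through range reduction with a degree-11 polynomial (relative
error ≲ 1e-14, with memberships below e⁻³⁴ dropped); agreement with a plain
`np.exp` double-loop reference is at the 1e-13 level, and the test suite
enforces 1e-10 on 100 random 300-sample windows.

## Aggregation and input sets

Window values are collapsed per recording either by the median (50th
percentile, representative of basal activity, since bursts occupy a small
fraction of a 30-min session) or by trend-directed percentiles that target
the contractile bursts: the 90th percentile for features that increase in
contractile periods as labor approaches (`app`, `df1`, `df2`, H/L, deciles,
time reversibility), and the 10th for those that decrease (`smr`, both
Lempel-Ziv measures, the three entropies, SD1, SD2, SD1/SD2). Percentiles
interpolate linearly between order statistics (the "type 7" convention),
declared explicitly because percentile dialects differ.

Four classifier input sets: (1) trend-directed percentiles + 6 obstetric
covariates (cervical length, gestational age, maternal age, gestations,
parity, abortions); (2) median + obstetric; (3) trend-directed percentiles
only; (4) median only. Sets 1/2 have 29 features, 3/4 have 23. The positive
class is TTD ≤ 7 days, threshold inclusive. Recordings with missing
obstetric covariates are excluded from sets 1/2 with a named-field log
entry (the package's declared policy for partially missing covariates).

## Balancing, partitioning, reduction

The cohort is imbalanced (30 imminent / 110 controls, 21.4% prevalence).
SMOTE grows the minority class to 3× its original count (30 → 90 against
110 majority, i.e. 45%/55% of the 200-sample balanced table): each synthetic
sample interpolates uniformly between a random minority sample and one of
its k = 5 nearest minority neighbors. Neighbor distances are Euclidean on
z-scored features so EHG and obstetric scales are commensurate; the
interpolation itself happens in the original feature space.

The balanced table is split 30 times into stratified train/validation/test
subsets: 1/3 test, and of the remaining design data 2/3 train and 1/3
validation (89/45/66 for 200 samples). Per-class allocations use
largest-remainder rounding, so class proportions are preserved within one
sample in every subset, and the same 30 partitions serve every classifier
and criterion. Each training subset defines a standardize-then-PCA map; the
number of components is the smallest k whose cumulative explained-variance
ratio reaches 98% (computed in-package on a full PCA fit, so that reaching
the threshold exactly counts as retained). Zero-variance features are
dropped with a log entry.

**Replicated leakage.** By default SMOTE runs on the full table *before*
partitioning — synthetic minority samples share parents across train,
validation and test — and that is deliberate: it replicates a protocol
commonly used with this design, and the package's evaluation numbers are
to be read with that caveat. `leak_safe=True` instead partitions the raw
table and confines SMOTE and PCA fitting to each training fold; test
subsets then contain no synthetic samples, and test metrics are expected
to drop. The acceptance suite checks the direction of this effect.

## Classifiers and the selection protocol

* **Random forest**: bootstrap trees with information-gain (entropy) splits
  and ⌈√p⌉ feature subsampling (sklearn backend). Grid: number of trees,
  maximum depth, minimum node size (the "cost of division" is exposed as
  minimum node size; an information-gain threshold would be the
  alternative reading).
* **Extreme learning machine**: single hidden layer, input weights and
  biases uniform(−1, 1) from the seed, hidden matrix H = act(XW + b),
  output weights by Moore–Penrose pseudoinverse against ±1 targets. Grid:
  hidden-layer size, activation (sigmoid/tanh/relu). With at least as many
  hidden units as training samples the least-squares fit interpolates, so
  training metrics of 100% are expected.
* **Kernel-weighted KNN**: Minkowski distance, distances normalized by the
  (k+1)-th neighbor before kernel weighting (rectangular = unweighted vote,
  triangular, Epanechnikov, Gaussian, rank). No training randomness.

Default grids (RF trees {100, 250, 500} × depth {4, 8, 16, ∞} × node size
{1, 5, 10}; ELM hidden {10, 25, 50, 100, 150} × 3 activations; KNN
k {3…15 odd} × p {1, 2} × 5 kernels) are configurable; odd k avoids vote
ties.

**Seed as hyperparameter.** For the stochastic learners, every combination
is trained on every partition under 30 candidate seeds; the best validation
seed is stored and reused at test time, making results exactly reproducible.
The grid is evaluated once and both optimization criteria rank from the same
table: criterion `f1` maximizes mean validation F1; criterion `sensitivity`
maximizes mean validation sensitivity with mean F1 breaking ties (within
1e-9). The sensitivity-primary ranking is the design choice here: it is what
makes sensitivity-optimized ELMs differ from F1-optimized ones, at the
expected cost of specificity. Selection consumes only train/validation
views; an API-level separation keeps test data out of the search.

**Exact ties.** When validation metrics saturate — routine on well-separated
cohorts under the replicated-leakage protocol — several combinations tie on
the mean validation metric to the last float digit, and the winner would be
an accident of grid ordering. Residual exact ties are therefore broken by
mean training F1 at the chosen seeds: among validation-equivalent models,
prefer the one that also fits its training data. This uses only
design-stage information and makes selection deterministic and
capacity-consistent (an interpolating wide ELM is preferred over a small
net that merely matches it on validation).

## Metrics and comparison

F1, sensitivity and specificity in percent (a true positive is an imminent
delivery correctly predicted), summarized over the 30 partitions by mean,
SD and coefficient of variation (CV uses test-subset metrics). Zero
denominators yield NaN sentinels with a log entry. Paired comparisons use
the two-sided Wilcoxon signed-rank test: zeros dropped, exact null
distribution for ≤ 25 nonzero pairs (dynamic programming over doubled
midranks, so ties are exact too), otherwise a continuity-corrected normal
approximation with tie correction; α = 0.05 with raw p-values (no
multiplicity correction, and the report says so). All-zero differences give
p = 1 by convention. ROC curves are vertically averaged on a fixed
101-point FPR grid, and AUC is the per-partition trapezoid mean —
identically the rank-sum statistic divided by n₊n₋.

## Synthetic cohort generator

No public EHG database matches this study design, so the generator creates
study-shaped cohorts: by default 140 recordings (30 imminent / 110
controls) of 1800 s at 20 Hz (simulated at 100 Hz, then decimated). Each
recording is a 1/f-shaped baseline band-limited to 0.1–4 Hz plus
Poisson-arriving bursts: Tukey-windowed envelopes of duration U(30, 90) s
modulating band-limited noise. Class effects follow the physiology the
pipeline is designed to detect:

| parameter | imminent | control | rationale |
| --- | --- | --- | --- |
| burst rate / 10 min | 4.0 | 2.5 | more frequent contractions near labor |
| burst amplitude (a.u.) | 60 | 40 | ~1 SD separation on the log scale (per-recording lognormal, σ = 0.3) |
| burst center frequency (Hz) | 0.45 | 0.35 | spectral shift above the 0.34 Hz fast-wave split |
| carrier regularity (AR) | 0.9 | 0.7 | narrower carrier band → more regular, lower entropy |
| cervical length (mm) | N(15, 5) | N(27, 6) | shorter cervix with imminent delivery |

TTD is U(0.5, 7) days for the imminent class and U(8, 60) for controls —
only the 7-day threshold matters downstream. Gestational age N(31, 2.5)
weeks, maternal age N(33, 5) years for both classes; gestations/parity/
abortions are small truncated Poisson counts. All obstetric distributions
are synthetic stipulations chosen to be clinically plausible; no
distributional description of a real cohort was available to estimate them.
Monopolar channels are built as common-mode interference ± half the bipolar
signal plus sensor noise, so the bipolar derivation recovers the signal.

What the generator does *not* emulate: uterine conduction physiology,
fetal ECG or respiration interference, tocolytic-phase effects, or
inter-recording correlation from the same woman (the real design records
some women twice). Passing tests therefore demonstrate that the pipeline
recovers class structure of the kind the physiology predicts — not
clinical performance on real EHG.

## Problem sizes used by the test and acceptance runs

The end-to-end acceptance check runs the full default cohort (140
recordings, 1800 s) through the ELM pipeline under both criteria for three
generator seeds; one such run takes about two minutes on a single CPU. The
leak-safe direction check uses a reduced design (16/44 recordings of 600 s,
10 partitions, a 2-point ELM grid, 10 seeds) because it tests a protocol
property, not the study conditions. Unit and property tests use 300-sample
windows and 10-minute recordings. The acceptance script
(`scripts/acceptance.py`) runs one full-size pipeline per invocation.

## Known limitations

* The synthetic effect sizes are stipulated, not estimated from data; the
  absolute metric levels reported on synthetic cohorts have no clinical
  meaning.
* The default protocol replicates SMOTE-before-partitioning leakage by
  design (see above); use `leak_safe=True` for honest generalization
  estimates.
* The exact hyperparameter search ranges of the original study design are
  not public; the defaults here are field-typical and configurable.
* EDF support reads channels "M1"/"M2" via `mne` and is read-only.
* With very small training folds the minority class can fall below the
  SMOTE neighbor count k; the error message instructs reducing k.
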