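"""Performance metrics, paired nonparametric comparison and averaged ROC.

Metrics are reported in percent: F1 = 100 * 2TP/(2TP + FP + FN),
sensitivity = 100 * TP/(TP + FN), specificity = 100 * TN/(TN + FP); a true
positive is an imminent delivery (TTD <= 7 days) correctly predicted.
Across the 30 holdout partitions each metric is summarized by mean, SD and
coefficient of variation (100 * SD/mean). Paired classifier comparisons use
the two-sided Wilcoxon signed-rank test at alpha = 0.05 with raw p-values
(no multiplicity correction); validation and test metrics are never mixed
in a comparison. ROC curves are averaged vertically on a fixed 101-point
FPR grid and AUC is the per-partition trapezoid mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METRIC_NAMES = ("f1", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics(counts: ConfusionCounts | tuple) -> dict[str, float]:
    """F1, sensitivity and specificity in percent (NaN on zero denominators)."""
    if not isinstance(counts, ConfusionCounts):
        counts = ConfusionCounts(*counts)
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    out: dict[str, float] = {}
    d = 2 * tp + fp + fn
    out["f1"] = 100.0 * 2 * tp / d if d > 0 else math.nan
    out["sensitivity"] = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else math.nan
    out["specificity"] = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else math.nan
    for name, v in out.items():
        if math.isnan(v):
            logger.warning("zero denominator: %s undefined", name)
    return out


def summarize(values: np.ndarray) -> dict[str, float]:
    """Mean, SD and coefficient of variation (percent) of a metric vector."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    cv = 100.0 * sd / mean if mean > 0 else math.nan
    return {"mean": mean, "sd": sd, "cv": cv}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_p(ranks2: np.ndarray, w2_plus: int) -> float:
    """Two-sided exact p for the signed-rank sum via DP over doubled ranks.

    ``ranks2`` are midranks x2 (integers even with ties); the null assigns
    each rank a +/- sign with probability 1/2. p = min(1, 2 * min(P(W+ <=
    w), P(W+ >= w))), point mass included on both sides.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    p_le = float(dist[: w2_plus + 1].sum())
    p_ge = float(dist[w2_plus:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_wilcoxon(
    metric_a: np.ndarray, metric_b: np.ndarray, exact_limit: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired metric vectors.

    Zero differences are dropped. With at most ``exact_limit`` nonzero
    pairs the exact null distribution of the rank sum is used (midranks for
    ties); above that, the normal approximation with tie correction. All
    differences zero returns (0, 1) by convention, flagged in the log.
    Returns (W, p) with W = min(W+, W-).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences zero; p = 1 by convention")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_limit:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2_plus = int(round(2 * w_plus))
        p = _exact_signed_rank_p(ranks2, w2_plus)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        if var <= 0:
            return w, 1.0
        # continuity-corrected two-sided normal approximation
        z = (abs(w_plus - mean) - 0.5) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    return w, min(1.0, float(p))


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCCurve:
    """Vertically averaged ROC over partitions on a fixed FPR grid."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    aucs: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Single-partition ROC (fpr, tpr, auc) from continuous scores.

    Threshold sweep over unique scores with trapezoid AUC; identical to the
    Mann-Whitney U statistic divided by n+ * n-. Raises on single-class
    labels.
    """
    from sklearn.metrics import roc_curve

    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def average_roc(
    per_partition: list[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> ROCCurve:
    """Vertical averaging of per-partition ROC curves on a fixed FPR grid."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    aucs = []
    for scores, labels in per_partition:
        fpr, tpr, auc = roc_auc(scores, labels)
        tprs.append(np.interp(grid, fpr, tpr))
        aucs.append(auc)
    return ROCCurve(fpr_grid=grid, mean_tpr=np.mean(tprs, axis=0), aucs=np.asarray(aucs))


# ---------------------------------------------------------------------------
# comparison report


@dataclass
class ComparisonReport:
    """Summary table plus the enumerated pairwise Wilcoxon comparisons."""

    summary: pd.DataFrame
    comparisons: pd.DataFrame


def _config_name(classifier: str, criterion: str, input_set: int) -> str:
    crit = "F1" if criterion == "f1" else "SENS"
    return f"{classifier.upper()}_{crit}_{input_set}"


def compare_report(metric_table: pd.DataFrame, alpha: float = 0.05) -> ComparisonReport:
    """Pairwise Wilcoxon comparisons across criteria and across input sets.

    ``metric_table`` has one row per (classifier, criterion, input_set,
    subset, partition) with columns ``f1``, ``sensitivity``,
    ``specificity``. Comparisons are (a) same classifier and input set
    across the two criteria, and (b) same classifier and criterion across
    input-set pairs — separately for the validation and test subsets, never
    mixing them. p-values are raw (no multiplicity correction).
    """
    required = {"classifier", "criterion", "input_set", "subset", "partition", *METRIC_NAMES}
    if not required.issubset(metric_table.columns):
        raise ValueError(f"metric_table must have columns {sorted(required)}")

    summary_rows = []
    for (clf, crit, iset, subset), grp in metric_table.groupby(
        ["classifier", "criterion", "input_set", "subset"]
    ):
        for m in METRIC_NAMES:
            s = summarize(grp[m].to_numpy())
            summary_rows.append(
                {
                    "name": _config_name(clf, crit, iset),
                    "classifier": clf,
                    "criterion": crit,
                    "input_set": iset,
                    "subset": subset,
                    "metric": m,
                    **s,
                }
            )
    summary = pd.DataFrame(summary_rows)

    def _vec(clf, crit, iset, subset, m):
        grp = metric_table[
            (metric_table.classifier == clf)
            & (metric_table.criterion == crit)
            & (metric_table.input_set == iset)
            & (metric_table.subset == subset)
        ].sort_values("partition")
        return grp[m].to_numpy()

    comp_rows = []
    classifiers = sorted(metric_table.classifier.unique())
    criteria = sorted(metric_table.criterion.unique())
    input_sets = sorted(metric_table.input_set.unique())
    subsets = [s for s in ("validation", "test") if s in set(metric_table.subset)]
    for subset in subsets:
        for clf in classifiers:
            # (a) same classifier & input set, across criteria
            if len(criteria) == 2:
                for iset in input_sets:
                    for m in METRIC_NAMES:
                        va = _vec(clf, criteria[0], iset, subset, m)
                        vb = _vec(clf, criteria[1], iset, subset, m)
                        if va.size == 0 or va.size != vb.size:
                            raise ValueError("mismatched partition sets in comparison")
                        _, p = paired_wilcoxon(va, vb)
                        comp_rows.append(
                            {
                                "subset": subset,
                                "metric": m,
                                "a": _config_name(clf, criteria[0], iset),
                                "b": _config_name(clf, criteria[1], iset),
                                "p_value": p,
                                "significant": p < alpha,
                            }
                        )
            # (b) same classifier & criterion, across input sets
            for crit in criteria:
                for i, iset_a in enumerate(input_sets):
                    for iset_b in input_sets[i + 1 :]:
                        for m in METRIC_NAMES:
                            va = _vec(clf, crit, iset_a, subset, m)
                            vb = _vec(clf, crit, iset_b, subset, m)
                            if va.size == 0 or va.size != vb.size:
                                raise ValueError("mismatched partition sets in comparison")
                            _, p = paired_wilcoxon(va, vb)
                            comp_rows.append(
                                {
                                    "subset": subset,
                                    "metric": m,
                                    "a": _config_name(clf, crit, iset_a),
                                    "b": _config_name(clf, crit, iset_b),
                                    "p_value": p,
                                    "significant": p < alpha,
                                }
                            )
    comparisons = pd.DataFrame(comp_rows)
    return ComparisonReport(summary=summary, comparisons=comparisons)
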