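"""End-to-end orchestration: cohort -> features -> table -> balanced
partitions -> classifier design -> metrics.

The default protocol mirrors the evaluation design the package implements:
SMOTE on the full table, then 30 stratified holdout partitions, then a
per-partition standardize+PCA map fitted on the training subset.
``leak_safe=True`` instead partitions the raw (unbalanced) table and
applies SMOTE only inside each training fold, so no synthetic sample
shares a parent with validation or test data; this is the methodologically
hygienic variant and is expected to score lower on test metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import evaluate as ev
from . import models as mdl
from . import resample as rs
from .features import FeatureParams, extract_all
from .ingest import RawRecording, condition, cut_windows
from .synth import SynthConfig, SynthRecording, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything one classifier/criterion/input-set experiment produced."""

    classifier: str
    criterion: str
    input_set: int
    leak_safe: bool
    selection: mdl.SelectionResult
    metric_table: pd.DataFrame  # per partition and subset, percent metrics
    roc_validation: ev.ROCCurve
    roc_test: ev.ROCCurve

    def mean_metric(self, subset: str, metric: str) -> float:
        grp = self.metric_table[self.metric_table.subset == subset]
        return float(grp[metric].mean())


def extract_cohort(
    recordings: list[RawRecording] | list[SynthRecording],
    band: tuple[float, float] = (0.1, 4.0),
    fs_out: float = 20.0,
    win_s: float = 120.0,
    overlap: float = 0.5,
    feature_params: FeatureParams = FeatureParams(),
) -> list[tuple[str, pd.DataFrame, dict, float]]:
    """Condition, window and characterize every recording of a cohort.

    Returns (id, window-feature frame, obstetric, ttd_days) tuples in
    cohort order; recordings without a single valid window contribute an
    empty frame and are excluded later by table assembly.
    """
    out = []
    for rec in recordings:
        raw = rec.as_raw() if isinstance(rec, SynthRecording) else rec
        sig = condition(raw, band=band, fs_out=fs_out)
        ws = cut_windows(sig, win_s=win_s, overlap=overlap)
        if len(ws.windows) == 0:
            wf = pd.DataFrame()
        else:
            wf = extract_all(ws, feature_params)
        out.append((raw.id, wf, raw.obstetric, raw.ttd_days))
    return out


def _partition_views(
    X: np.ndarray,
    y: np.ndarray,
    partitions: rs.PartitionSet,
    pca_variance: float,
    pca_scope: str = "train",
) -> list[tuple]:
    """Per-partition (Xtr, ytr, Xval, yval, Xte, yte) after per-fold PCA.

    ``pca_scope`` selects the data the PCA map is fitted on: the training
    subset (default) or the full design data (train + validation).
    """
    if pca_scope not in ("train", "train_val"):
        raise ValueError("pca_scope must be 'train' or 'train_val'")
    views = []
    for train, val, test in partitions.partitions:
        fit_idx = train if pca_scope == "train" else np.concatenate([train, val])
        pmap = rs.fit_pca(X[fit_idx], variance=pca_variance)
        views.append(
            (
                rs.apply_pca(pmap, X[train]),
                y[train],
                rs.apply_pca(pmap, X[val]),
                y[val],
                rs.apply_pca(pmap, X[test]),
                y[test],
            )
        )
    return views


def _partition_views_leak_safe(
    table: agg.FeatureTable,
    partitions: rs.PartitionSet,
    smote_ratio: float,
    smote_k: int,
    pca_variance: float,
    seed: int,
) -> list[tuple]:
    """Leak-safe views: SMOTE and PCA confined to each training fold."""
    views = []
    for rep, (train, val, test) in enumerate(partitions.partitions):
        sub = agg.FeatureTable(
            X=table.X.iloc[train],
            y=table.y[train],
            origin=table.origin[train],
            input_set=table.input_set,
        )
        bal = rs.smote(sub, ratio=smote_ratio, k=smote_k, seed=seed + rep)
        Xtr = bal.X.to_numpy(dtype=float)
        ytr = bal.y
        pmap = rs.fit_pca(Xtr, variance=pca_variance)
        X = table.X.to_numpy(dtype=float)
        views.append(
            (
                rs.apply_pca(pmap, Xtr),
                ytr,
                rs.apply_pca(pmap, X[val]),
                table.y[val],
                rs.apply_pca(pmap, X[test]),
                table.y[test],
            )
        )
    return views


def prepare_views(
    table: agg.FeatureTable,
    n_partitions: int = 30,
    smote_ratio: float = 3.0,
    smote_k: int = 5,
    pca_variance: float = 0.98,
    pca_scope: str = "train",
    leak_safe: bool = False,
    seed: int = 0,
) -> tuple[list[tuple], rs.PartitionSet]:
    """Balanced, partitioned, PCA-reduced per-partition data views."""
    if leak_safe:
        partitions = rs.make_partitions(table.y, n_reps=n_partitions, seed=seed)
        views = _partition_views_leak_safe(
            table, partitions, smote_ratio, smote_k, pca_variance, seed
        )
    else:
        balanced = rs.smote(table, ratio=smote_ratio, k=smote_k, seed=seed)
        partitions = rs.make_partitions(balanced.y, n_reps=n_partitions, seed=seed)
        X = balanced.X.to_numpy(dtype=float)
        views = _partition_views(X, balanced.y, partitions, pca_variance, pca_scope)
    return views, partitions


def run_experiment(
    views: list[tuple],
    classifier: str = "elm",
    criteria: tuple[str, ...] = ("f1", "sensitivity"),
    grid: dict | None = None,
    n_seeds: int = 30,
    base_seed: int = 0,
    input_set: int = 2,
    leak_safe: bool = False,
) -> dict[str, StudyResult]:
    """Grid search + selection under each criterion on prepared views.

    The grid is evaluated once; both criteria rank from the same table
    (same partitions, same candidate seeds). Returns one StudyResult per
    criterion with per-partition train/validation/test metrics and averaged
    ROC curves.
    """
    grid = grid if grid is not None else mdl.default_grid()[classifier]
    combos = mdl.grid_combinations(grid)
    design_views = [(v[0], v[1], v[2], v[3]) for v in views]
    search = mdl.evaluate_grid(
        classifier, combos, design_views, n_seeds=n_seeds, base_seed=base_seed
    )
    out: dict[str, StudyResult] = {}
    for criterion in criteria:
        selection = mdl.select_model(search, criterion)
        counts = mdl.evaluate_selection(selection, views)
        rows = []
        for subset, per_part in counts.items():
            for p, c in enumerate(per_part):
                m = ev.metrics(c)
                rows.append(
                    {
                        "classifier": classifier,
                        "criterion": criterion,
                        "input_set": input_set,
                        "subset": subset,
                        "partition": p,
                        **m,
                    }
                )
        metric_table = pd.DataFrame(rows)
        roc_val = ev.average_roc(mdl.score_selection(selection, views, "validation"))
        roc_test = ev.average_roc(mdl.score_selection(selection, views, "test"))
        out[criterion] = StudyResult(
            classifier=classifier,
            criterion=criterion,
            input_set=input_set,
            leak_safe=leak_safe,
            selection=selection,
            metric_table=metric_table,
            roc_validation=roc_val,
            roc_test=roc_test,
        )
    return out


def run_study(
    synth_config: SynthConfig | None = None,
    classifier: str = "elm",
    input_set: int = 2,
    criteria: tuple[str, ...] = ("f1", "sensitivity"),
    grid: dict | None = None,
    n_partitions: int = 30,
    n_seeds: int = 30,
    smote_ratio: float = 3.0,
    smote_k: int = 5,
    pca_variance: float = 0.98,
    leak_safe: bool = False,
    seed: int = 0,
) -> dict[str, StudyResult]:
    """Full synthetic study: generate -> extract -> aggregate -> evaluate."""
    cfg = synth_config if synth_config is not None else SynthConfig(seed=seed)
    cohort = generate_cohort(cfg)
    feats = extract_cohort(cohort)
    table = agg.build_table(feats, input_set=input_set)
    views, _ = prepare_views(
        table,
        n_partitions=n_partitions,
        smote_ratio=smote_ratio,
        smote_k=smote_k,
        pca_variance=pca_variance,
        leak_safe=leak_safe,
        seed=seed,
    )
    return run_experiment(
        views,
        classifier=classifier,
        criteria=criteria,
        grid=grid,
        n_seeds=n_seeds,
        base_seed=seed,
        input_set=input_set,
        leak_safe=leak_safe,
    )
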