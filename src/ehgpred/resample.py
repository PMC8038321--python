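"""Class balancing (SMOTE), repeated stratified holdout partitions and PCA.

The cohort is imbalanced (default 30 imminent vs 110 controls). SMOTE grows
the minority class to ratio x its original size by interpolating each
synthetic sample between a minority sample and one of its k nearest
minority neighbors (Euclidean distance on z-scored features, so EHG and
obstetric scales are commensurate). The balanced table is then split 30
times into stratified train/validation/test subsets (1/3 test; of the
remaining design data, 2/3 train and 1/3 validation), and each training
subset defines a standardize-then-PCA map retaining 98% of the variance.

By default SMOTE runs on the full table before partitioning and PCA is fit
per partition on the training subset — the synthetic minority samples
therefore share parents across subsets, a deliberate replication of a
common (leaky) protocol. ``leak_safe`` pipelines instead partition the raw
table and apply SMOTE only inside each training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .aggregate import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class PartitionSet:
    """Repeated stratified holdout: disjoint (train, validation, test) triples."""

    partitions: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    seed: int

    def __len__(self) -> int:
        return len(self.partitions)


@dataclass
class PCAMap:
    """Standardize-then-project map fitted on a training subset."""

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # shape (n_components, n_kept_features)
    kept_columns: np.ndarray  # indices of nonzero-variance input columns
    variance_retained: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def smote(
    table: FeatureTable, ratio: float = 3.0, k: int = 5, seed: int = 0
) -> FeatureTable:
    """Oversample the minority class to ratio x its original count.

    Each synthetic sample interpolates uniformly between a randomly chosen
    minority sample and one of its k nearest minority neighbors (neighbors
    found on z-scored features; interpolation happens in the original
    feature space). Synthetic rows are flagged ``origin="synthetic_smote"``;
    the majority class is untouched. ``ratio=1`` returns the table unchanged.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    counts = np.bincount(table.y, minlength=2)
    minority = int(np.argmin(counts))
    n_min = int(counts[minority])
    if n_min <= k:
        raise ValueError(
            f"minority class has {n_min} samples <= k={k}; use a smaller k"
        )
    n_new = int(round(ratio * n_min)) - n_min
    if n_new <= 0:
        return table

    X = table.X.to_numpy(dtype=float)
    min_idx = np.flatnonzero(table.y == minority)
    Xm = X[min_idx]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xm - mu) / sd
    # k nearest minority neighbors of each minority sample (self excluded)
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]

    rng = np.random.default_rng(seed)
    new_rows = np.empty((n_new, X.shape[1]))
    new_ids = []
    for s in range(n_new):
        i = int(rng.integers(n_min))
        j = int(nn[i, rng.integers(k)])
        u = float(rng.uniform(0.0, 1.0))
        new_rows[s] = Xm[i] + u * (Xm[j] - Xm[i])
        new_ids.append(f"{table.X.index[min_idx[i]]}~sm{s:03d}")

    X_out = pd.concat(
        [table.X, pd.DataFrame(new_rows, index=new_ids, columns=table.X.columns)]
    )
    y_out = np.concatenate([table.y, np.full(n_new, minority)])
    origin_out = np.concatenate(
        [table.origin, np.full(n_new, "synthetic_smote", dtype=object)]
    )
    return FeatureTable(X=X_out, y=y_out, origin=origin_out, input_set=table.input_set)


def _subset_sizes(n: int) -> tuple[int, int, int]:
    """(train, validation, test) sizes: 1/3 test, then 2/3 train of the rest."""
    n_test = n // 3
    n_design = n - n_test
    n_train = (n_design * 2) // 3
    n_val = n - n_test - n_train
    return n_train, n_val, n_test


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(targets).astype(int)
    rem = targets - base
    short = total - base.sum()
    order = np.argsort(-rem)
    base[order[:short]] += 1
    return base


def make_partitions(
    labels: np.ndarray, n_reps: int = 30, seed: int = 0
) -> PartitionSet:
    """Repeated stratified holdout partitions, reproducible from the seed.

    Per repetition every sample index lands in exactly one of train,
    validation, test; per-class allocations follow largest-remainder
    rounding of the global subset fractions, so class proportions are
    preserved within one sample in every subset.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    classes, class_counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or class_counts.min() < 3:
        raise ValueError("need both classes with at least 3 samples")
    n_train, n_val, n_test = _subset_sizes(n)
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(n_reps):
        train_idx: list[np.ndarray] = []
        val_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for cls, n_c in zip(classes, class_counts):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            targets = np.array(
                [n_c * n_train / n, n_c * n_val / n, n_c * n_test / n]
            )
            alloc = _largest_remainder(targets, n_c)
            train_idx.append(idx[: alloc[0]])
            val_idx.append(idx[alloc[0] : alloc[0] + alloc[1]])
            test_idx.append(idx[alloc[0] + alloc[1] :])
        partitions.append(
            (
                np.sort(np.concatenate(train_idx)),
                np.sort(np.concatenate(val_idx)),
                np.sort(np.concatenate(test_idx)),
            )
        )
    return PartitionSet(partitions=partitions, seed=seed)


def fit_pca(train_features: np.ndarray, variance: float = 0.98) -> PCAMap:
    """Standardize-then-PCA map retaining >= ``variance`` of the variance.

    Features are z-scored by the training mean/SD (zero-variance features
    dropped with a log entry); the number of components is the minimal k
    with cumulative explained-variance ratio >= ``variance``.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size < X.shape[1]:
        logger.warning("dropping %d zero-variance features", X.shape[1] - kept.size)
    if kept.size == 0:
        raise ValueError("all features have zero variance")
    mu = X[:, kept].mean(axis=0)
    scale = sd[kept]
    Z = (X[:, kept] - mu) / scale
    pca = PCA()
    pca.fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance - 1e-12)) + 1
    return PCAMap(
        center=mu,
        scale=scale,
        loadings=pca.components_[:n_comp],
        kept_columns=kept,
        variance_retained=float(cum[n_comp - 1]),
    )


def apply_pca(pca_map: PCAMap, features: np.ndarray) -> np.ndarray:
    """Project features through a fitted PCAMap."""
    X = np.asarray(features, dtype=float)
    Z = (X[:, pca_map.kept_columns] - pca_map.center) / pca_map.scale
    return Z @ pca_map.loadings.T


def inverse_pca(pca_map: PCAMap, reduced: np.ndarray) -> np.ndarray:
    """Back-project reduced coordinates to the standardized feature space."""
    return np.asarray(reduced, dtype=float) @ pca_map.loadings
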