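"""RF, ELM and KNN classifiers, the hyperparameter grid search and the
seed-as-hyperparameter selection protocol.

Three computationally efficient classifiers are trained on the reduced
feature tables: a random forest with entropy (information-gain) splits, an
extreme learning machine (single hidden layer with random uniform input
weights, least-squares/pseudoinverse output weights) and a kernel-weighted
K-nearest-neighbors rule on the Minkowski distance. Every model exposes a
continuous positive-class score in [0, 1]-like units; thresholding the
score at 0.5 reproduces the discrete prediction.

For the stochastic learners (RF, ELM) each hyperparameter combination is
trained on every partition under several candidate seeds; the best seed on
the validation subset is stored as an additional hyperparameter and reused
at test time, so results are exactly reproducible. KNN involves no training
randomness. Selection ranks combinations by the mean validation metric over
all partitions under two criteria: ``f1`` maximizes mean F1;
``sensitivity`` maximizes mean sensitivity with mean F1 as tie-break.
Selection consumes only train/validation views; test subsets never
influence it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

KNN_KERNELS = ("rectangular", "triangular", "epanechnikov", "gaussian", "rank")
ELM_ACTIVATIONS = ("sigmoid", "tanh", "relu")


def default_grid() -> dict[str, dict[str, list]]:
    """Default hyperparameter grids (fully configurable via YAML/CLI)."""
    return {
        "rf": {
            "n_trees": [100, 250, 500],
            "max_depth": [4, 8, 16, None],
            "min_node_size": [1, 5, 10],
        },
        "elm": {
            "n_hidden": [10, 25, 50, 100, 150],
            "activation": list(ELM_ACTIVATIONS),
        },
        "knn": {
            "k": [3, 5, 7, 9, 11, 13, 15],
            "minkowski_p": [1, 2],
            "kernel": list(KNN_KERNELS),
        },
    }


def grid_combinations(grid: dict[str, list]) -> list[dict]:
    """Cartesian product of a per-classifier grid as a list of dicts."""
    keys = list(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class TrainedModel:
    """A fitted classifier with a continuous positive-class score."""

    kind: str
    hyperparameters: dict
    seed: int | None
    _scorer: object

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return self._scorer(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score_samples(X) >= 0.5).astype(int)


def train_rf(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 250,
    max_depth: int | None = None,
    min_node_size: int = 1,
    seed: int = 0,
) -> TrainedModel:
    """Random forest with information-gain (entropy) splits.

    Bootstrap-sampled trees with ceil(sqrt(p)) feature subsampling per
    split; the score is the fraction of trees voting for the positive
    class. Deterministic given the seed.
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="entropy",
        max_depth=max_depth,
        min_samples_leaf=min_node_size,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
    )
    clf.fit(np.asarray(X, dtype=float), y)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])

    def scorer(Xq: np.ndarray) -> np.ndarray:
        return clf.predict_proba(Xq)[:, pos_col]

    return TrainedModel(
        kind="rf",
        hyperparameters={
            "n_trees": n_trees,
            "max_depth": max_depth,
            "min_node_size": min_node_size,
        },
        seed=seed,
        _scorer=scorer,
    )


def _activation(name: str):
    if name == "sigmoid":
        return lambda z: 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh
    if name == "relu":
        return lambda z: np.maximum(z, 0.0)
    raise ValueError(f"unknown activation '{name}'")


def train_elm(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 50,
    activation: str = "tanh",
    seed: int = 0,
) -> TrainedModel:
    """Extreme learning machine: random input layer, pseudoinverse readout.

    Input weights and biases are drawn uniform(-1, 1) from the seed, the
    hidden matrix is H = act(XW + b), and the output weights are the
    Moore-Penrose pseudoinverse of H applied to +/-1 targets. The score
    maps the raw output o to (o + 1)/2 so that 0.5 is the class boundary.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    act = _activation(activation)
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(X.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = act(X @ W + b)
    targets = 2.0 * y - 1.0
    beta = np.linalg.pinv(H) @ targets

    def scorer(Xq: np.ndarray) -> np.ndarray:
        return (act(Xq @ W + b) @ beta + 1.0) / 2.0

    return TrainedModel(
        kind="elm",
        hyperparameters={"n_hidden": n_hidden, "activation": activation},
        seed=seed,
        _scorer=scorer,
    )


def _kernel_weights(u: np.ndarray, kernel: str) -> np.ndarray:
    # u: normalized distances in [0, 1]; all kernels give nonincreasing weights
    if kernel == "rectangular":
        return np.full_like(u, 0.5)
    if kernel == "triangular":
        return np.maximum(1.0 - u, 0.0)
    if kernel == "epanechnikov":
        return np.maximum(0.75 * (1.0 - u**2), 0.0)
    if kernel == "gaussian":
        return np.exp(-(u**2) / 2.0)
    if kernel == "rank":
        k = u.size
        return (k + 1.0 - np.arange(1, k + 1)).astype(float)
    raise ValueError(f"unknown kernel '{kernel}'")


def train_knn(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    minkowski_p: float = 2.0,
    kernel: str = "rectangular",
) -> TrainedModel:
    """Kernel-weighted KNN on the Minkowski distance; no training randomness.

    Distances to the k nearest training points are normalized by the
    (k+1)-th neighbor distance before kernel weighting; the score is the
    weighted fraction of positive neighbors. The rectangular kernel reduces
    to the unweighted vote.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds training size {X.shape[0]}")

    def scorer(Xq: np.ndarray) -> np.ndarray:
        D = cdist(Xq, X, metric="minkowski", p=minkowski_p)
        order = np.argsort(D, axis=1, kind="stable")
        scores = np.empty(Xq.shape[0])
        for i in range(Xq.shape[0]):
            idx = order[i, :k]
            d = D[i, idx]
            if k < X.shape[0]:
                d_norm = D[i, order[i, k]]
            else:
                d_norm = d[-1] if d[-1] > 0 else 1.0
            u = d / d_norm if d_norm > 0 else np.zeros_like(d)
            w = _kernel_weights(u, kernel)
            if w.sum() <= 0:
                w = np.ones_like(w)
            scores[i] = float(np.sum(w * (y[idx] == 1)) / w.sum())
        return scores

    return TrainedModel(
        kind="knn",
        hyperparameters={"k": k, "minkowski_p": minkowski_p, "kernel": kernel},
        seed=None,
        _scorer=scorer,
    )


def train_model(kind: str, X, y, combo: dict, seed: int | None) -> TrainedModel:
    if kind == "rf":
        return train_rf(X, y, seed=seed, **combo)
    if kind == "elm":
        return train_elm(X, y, seed=seed, **combo)
    if kind == "knn":
        return train_knn(X, y, **combo)
    raise ValueError(f"unknown classifier kind '{kind}'")


# ---------------------------------------------------------------------------
# grid evaluation and criterion-based selection


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def _f1_sens(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float]:
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return f1, sens


@dataclass
class GridSearchTable:
    """Validation confusion counts per (combination, partition, seed).

    Computed once; both optimization criteria rank from the same table, so
    the partitions and candidate seeds are shared exactly as the evaluation
    protocol requires. Training counts (same nesting) break exact
    validation ties during selection; under validation saturation,
    combinations routinely tie to the last float digit.
    """

    kind: str
    combos: list[dict]
    seeds: list[int | None]
    # counts[c][p][s] = (tp, tn, fp, fn) on the validation subset
    counts: list[list[list[tuple[int, int, int, int]]]]
    train_counts: list[list[list[tuple[int, int, int, int]]]] | None = None


@dataclass
class SelectionResult:
    """A selected combination with its per-partition seed ledger."""

    kind: str
    criterion: str
    combo: dict
    seed_ledger: list[int | None]  # chosen seed per partition
    mean_val_f1: float
    mean_val_sensitivity: float


def evaluate_grid(
    kind: str,
    combos: list[dict],
    partition_data: list[tuple],
    n_seeds: int = 30,
    base_seed: int = 0,
) -> GridSearchTable:
    """Train every combination on every partition under every candidate seed.

    ``partition_data[p]`` is (X_train, y_train, X_val, y_val); only these
    design views are consumed here — test data never enters the search.
    KNN gets a single ``None`` seed (no training randomness).
    """
    if not combos:
        raise ValueError("empty hyperparameter grid")
    if not partition_data:
        raise ValueError("no partitions")
    if kind == "knn":
        seeds: list[int | None] = [None]
    else:
        seeds = [int(base_seed + 1000 * s) for s in range(n_seeds)]
    counts: list[list[list[tuple[int, int, int, int]]]] = []
    train_counts: list[list[list[tuple[int, int, int, int]]]] = []
    for combo in combos:
        per_part = []
        per_part_train = []
        for Xtr, ytr, Xval, yval in partition_data:
            if yval.size == 0:
                raise ValueError("empty validation subset")
            per_seed = []
            per_seed_train = []
            for seed in seeds:
                model = train_model(kind, Xtr, ytr, combo, seed)
                per_seed.append(_confusion(yval, model.predict(Xval)))
                per_seed_train.append(_confusion(ytr, model.predict(Xtr)))
            per_part.append(per_seed)
            per_part_train.append(per_seed_train)
        counts.append(per_part)
        train_counts.append(per_part_train)
    return GridSearchTable(
        kind=kind, combos=combos, seeds=seeds, counts=counts, train_counts=train_counts
    )


def _criterion_key(f1: float, sens: float, criterion: str) -> tuple:
    if criterion == "f1":
        return (f1,)
    if criterion == "sensitivity":
        return (sens, f1)
    raise ValueError("criterion must be 'f1' or 'sensitivity'")


def select_model(table: GridSearchTable, criterion: str) -> SelectionResult:
    """Rank combinations under a criterion and record the chosen seeds.

    For each combination and partition the best validation seed (by the
    criterion's key) is chosen first; combinations are then ranked by the
    mean validation metric across partitions, with mean F1 breaking
    sensitivity ties (within 1e-9). Combinations that still tie exactly on
    validation are separated by mean training F1 at the chosen seeds —
    among validation-equivalent models, prefer the one that also fits its
    training data. Only design-stage (train/validation) information enters.
    """
    n_combos = len(table.combos)
    train_counts = table.train_counts
    best: SelectionResult | None = None
    best_key: tuple | None = None
    for ci in range(n_combos):
        per_part = table.counts[ci]
        ledger: list[int | None] = []
        f1s, senss, train_f1s = [], [], []
        for pi, per_seed in enumerate(per_part):
            seed_metrics = [_f1_sens(*c) for c in per_seed]
            keys = [_criterion_key(f, s, criterion) for f, s in seed_metrics]
            si = max(range(len(keys)), key=lambda i: keys[i])
            ledger.append(table.seeds[si])
            f1s.append(seed_metrics[si][0])
            senss.append(seed_metrics[si][1])
            if train_counts is not None:
                train_f1s.append(_f1_sens(*train_counts[ci][pi][si])[0])
        mean_f1 = float(np.mean(f1s))
        mean_sens = float(np.mean(senss))
        mean_train_f1 = float(np.mean(train_f1s)) if train_f1s else 0.0
        if criterion == "f1":
            key = (round(mean_f1, 9), round(mean_train_f1, 9))
        else:
            key = (round(mean_sens, 9), round(mean_f1, 9), round(mean_train_f1, 9))
        if best_key is None or key > best_key:
            best_key = key
            best = SelectionResult(
                kind=table.kind,
                criterion=criterion,
                combo=table.combos[ci],
                seed_ledger=ledger,
                mean_val_f1=mean_f1,
                mean_val_sensitivity=mean_sens,
            )
    assert best is not None
    return best


def evaluate_selection(
    selection: SelectionResult, partition_data_full: list[tuple]
) -> dict[str, list[tuple[int, int, int, int]]]:
    """Confusion counts on train/validation/test with the stored seeds.

    ``partition_data_full[p]`` is (X_train, y_train, X_val, y_val, X_test,
    y_test). Models are retrained with the ledgered seed (deterministic,
    hence identical to the selection-time model) and evaluated once per
    subset; scores are also returned for ROC analysis via
    :func:`score_selection`.
    """
    out: dict[str, list[tuple[int, int, int, int]]] = {
        "train": [],
        "validation": [],
        "test": [],
    }
    for (Xtr, ytr, Xval, yval, Xte, yte), seed in zip(
        partition_data_full, selection.seed_ledger
    ):
        model = train_model(selection.kind, Xtr, ytr, selection.combo, seed)
        out["train"].append(_confusion(ytr, model.predict(Xtr)))
        out["validation"].append(_confusion(yval, model.predict(Xval)))
        out["test"].append(_confusion(yte, model.predict(Xte)))
    return out


def score_selection(
    selection: SelectionResult, partition_data_full: list[tuple], subset: str = "test"
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-partition (scores, labels) pairs for ROC/AUC on one subset."""
    pos = {"train": (0, 1), "validation": (2, 3), "test": (4, 5)}[subset]
    out = []
    for part, seed in zip(partition_data_full, selection.seed_ledger):
        Xtr, ytr = part[0], part[1]
        Xs, ys = part[pos[0]], part[pos[1]]
        model = train_model(selection.kind, Xtr, ytr, selection.combo, seed)
        out.append((model.score_samples(Xs), np.asarray(ys, dtype=int)))
    return out
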