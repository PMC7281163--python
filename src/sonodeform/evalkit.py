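"""Grouped cross-validation, set-based metrics, grid search and the
fluorescence cross-domain evaluation.

Fold assignment happens at the cell level: all 201 images of a cell (the
original combined image and its augmented variants) travel together, so no
cell ever contributes images to both sides of a fold.  Folds are stratified
by class, which makes the canonical 40-cell design yield 32 training and
8 test cells (4 per class) in every fold.

Metrics follow the set formulation: with M the predicted-invasive set, M*
the truly invasive set, and U the universe of scored images,

    a = (|M* ∩ M| + |(M* ∪ M)^c|) / |U|
    p = |M* ∩ M| / |M|,   r = |M* ∩ M| / |M*|,   F1 = 2pr / (p + r).

Metrics are reported at the image level (each augmented image scored
independently); a cell-level majority-vote summary is provided as a clearly
secondary output.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentedDataset
from .cnn import ShallowCNNClassifier, bce_loss

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "GridSpec",
    "GroupStratifiedCellKFold",
    "make_folds",
    "compute_metrics",
    "metrics_from_labels",
    "cross_validate",
    "grid_search",
    "cross_domain_evaluate",
]


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_cell_ids: tuple[str, ...]
    test_cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_cell_ids) & set(self.test_cell_ids):
            raise ValueError("train and test cell ids overlap")


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    loss: float = float("nan")
    n_detected: int = 0  # |M|
    n_true: int = 0  # |M*|
    n_hit: int = 0  # |M* ∩ M|
    n_universe: int = 0  # |U|

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "loss": self.loss,
        }


@dataclass(frozen=True)
class GridSpec:
    """Hyper-parameter grids: rho stepped x10, beta x2, epsilon +20."""

    learning_rates: tuple[float, ...] = (0.00025, 0.0025, 0.025, 0.25)
    batch_sizes: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    epoch_grid: tuple[int, ...] = tuple(range(20, 301, 20))
    optimizers: tuple[str, ...] = ("sgd", "rmsprop", "adagrad", "adadelta", "adam")

    def n_configurations(self, optimizer: str) -> int:
        n_lr = 1 if optimizer == "adadelta" else len(self.learning_rates)
        return n_lr * len(self.batch_sizes) * len(self.epoch_grid)


# ---------------------------------------------------------------------------
# folds


def make_folds(cells, k: int, seed: int = 0) -> list[FoldSplit]:
    """Stratified grouped k-fold split of cells.

    ``cells`` is a list of CellRecord or a DataFrame with cell_id/label
    columns.  Within each class, cells are shuffled and dealt round-robin
    into the k test sets, so balanced cohorts yield identical per-class
    test counts in every fold.
    """
    if isinstance(cells, pd.DataFrame):
        ids = list(cells["cell_id"])
        labels = list(cells["label"])
    else:
        ids = [c.cell_id for c in cells]
        labels = [c.label for c in cells]
    if len(set(ids)) != len(ids):
        raise ValueError("cell ids must be unique")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of cells ({len(ids)})")
    rng = np.random.default_rng(seed)
    test_sets: list[list[str]] = [[] for _ in range(k)]
    for cls in sorted(set(labels)):
        cls_ids = sorted(i for i, l in zip(ids, labels) if l == cls)
        rng.shuffle(cls_ids)
        for j, cid in enumerate(cls_ids):
            test_sets[j % k].append(cid)
    all_ids = set(ids)
    return [
        FoldSplit(
            fold_index=f,
            train_cell_ids=tuple(sorted(all_ids - set(test))),
            test_cell_ids=tuple(sorted(test)),
        )
        for f, test in enumerate(test_sets)
    ]


class GroupStratifiedCellKFold:
    """sklearn-compatible splitter wrapping :func:`make_folds`.

    ``split(X, y, groups)`` yields (train_idx, test_idx) over samples whose
    group (parent cell id) falls in the fold's train/test cell sets.
    """

    def __init__(self, n_splits: int = 5, seed: int = 0):
        self.n_splits = n_splits
        self.seed = seed

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def split(self, X, y, groups):
        y = np.asarray(y)
        groups = np.asarray(groups)
        # one label per group
        cells = pd.DataFrame({"cell_id": groups, "label": y}).drop_duplicates(
            "cell_id"
        )
        for fold in make_folds(cells, self.n_splits, self.seed):
            test_mask = np.isin(groups, fold.test_cell_ids)
            yield np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(M, M_star, U, loss: float = float("nan")) -> MetricsReport:
    """Set-based accuracy, precision, recall and F1.

    ``M`` is the predicted-invasive id set, ``M_star`` the truly invasive
    ids, ``U`` the universe of all scored ids.
    """
    M, M_star, U = set(M), set(M_star), set(U)
    if not M <= U or not M_star <= U:
        raise ValueError("M and M* must be subsets of U")
    if not U:
        raise ValueError("universe U is empty")
    hit = len(M & M_star)
    correct_neg = len(U - (M | M_star))
    accuracy = (hit + correct_neg) / len(U)
    if M:
        precision = hit / len(M)
    else:
        warnings.warn("|M| = 0: precision defined as 0", stacklevel=2)
        precision = 0.0
    if M_star:
        recall = hit / len(M_star)
    else:
        warnings.warn("|M*| = 0: recall defined as 0", stacklevel=2)
        recall = 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        loss=loss,
        n_detected=len(M),
        n_true=len(M_star),
        n_hit=hit,
        n_universe=len(U),
    )


def metrics_from_labels(
    y_true, y_pred, ids=None, loss: float = float("nan")
) -> MetricsReport:
    """Convenience: build the M / M* / U sets from label vectors."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if ids is None:
        ids = np.arange(len(y_true))
    ids = np.asarray(ids)
    return compute_metrics(
        set(ids[y_pred == 1]), set(ids[y_true == 1]), set(ids), loss=loss
    )


# ---------------------------------------------------------------------------
# cross-validation


def _fit_fold(ds: AugmentedDataset, fold: FoldSplit, clf_params: dict, seed: int,
              with_history: bool = False):
    groups = ds.groups
    train_mask = np.isin(groups, fold.train_cell_ids)
    test_mask = np.isin(groups, fold.test_cell_ids)
    # leakage check: asserted, not assumed
    overlap = set(groups[train_mask]) & set(groups[test_mask])
    if overlap:
        raise RuntimeError(f"cell leakage across the fold boundary: {overlap}")
    clf = ShallowCNNClassifier(seed=seed, **clf_params)
    val = (ds.images[test_mask], ds.labels[test_mask]) if with_history else None
    clf.fit(ds.images[train_mask], ds.labels[train_mask], validation_data=val)
    return clf, train_mask, test_mask


def _fold_report(clf, ds, test_mask) -> tuple[MetricsReport, MetricsReport]:
    ids = ds.manifest["image_id"].to_numpy()[test_mask]
    y = ds.labels[test_mask]
    proba = clf.predict_proba(ds.images[test_mask])[:, 1]
    pred = (proba > 0.5).astype(int)
    image_level = metrics_from_labels(y, pred, ids=ids, loss=bce_loss(y, proba))
    # secondary: one vote per cell by majority over its images
    df = pd.DataFrame(
        {"cell_id": ds.groups[test_mask], "y": y, "pred": pred}
    )
    per_cell = df.groupby("cell_id").agg(
        y=("y", "first"), vote=("pred", lambda p: int(p.mean() > 0.5))
    )
    cell_level = metrics_from_labels(
        per_cell["y"].to_numpy(), per_cell["vote"].to_numpy(),
        ids=per_cell.index.to_numpy(),
    )
    return image_level, cell_level


@dataclass
class CrossValResult:
    fold_reports: list[MetricsReport]
    cell_reports: list[MetricsReport] = field(repr=False)
    summary: pd.DataFrame = field(repr=False)
    folds: list[FoldSplit] = field(repr=False)
    histories: list[dict] = field(default_factory=list, repr=False)

    @property
    def mean_accuracy(self) -> float:
        return float(self.summary.loc["mean", "accuracy"])


def _summarize(reports: list[MetricsReport]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in reports])
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=0)}).T


def cross_validate(
    ds: AugmentedDataset,
    k: int = 5,
    seed: int = 0,
    clf_params: dict | None = None,
    keep_history: bool = False,
) -> CrossValResult:
    """Grouped stratified k-fold CV; a fresh model is trained per fold.

    Metrics are image-level (primary) and cell-level majority vote
    (secondary); the summary holds their across-fold mean and sd.
    """
    clf_params = dict(clf_params or {})
    cells = ds.manifest.drop_duplicates("cell_id")[["cell_id", "label"]]
    ss = np.random.SeedSequence(seed)
    fold_seed, *train_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                               ss.spawn(k + 1)]
    folds = make_folds(cells, k, seed=fold_seed)
    fold_reports, cell_reports, histories = [], [], []
    for fold, tseed in zip(folds, train_seeds):
        clf, _, test_mask = _fit_fold(
            ds, fold, clf_params, tseed, with_history=keep_history
        )
        image_level, cell_level = _fold_report(clf, ds, test_mask)
        fold_reports.append(image_level)
        cell_reports.append(cell_level)
        if keep_history:
            histories.append(clf.history_)
    return CrossValResult(
        fold_reports=fold_reports,
        cell_reports=cell_reports,
        summary=_summarize(fold_reports),
        folds=folds,
        histories=histories,
    )


# ---------------------------------------------------------------------------
# grid search


def grid_search(
    ds: AugmentedDataset,
    grid: GridSpec | None = None,
    k: int = 5,
    seed: int = 0,
    clf_params: dict | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over the (optimizer, rho, beta, epsilon) grid.

    Each (optimizer, learning rate, batch size) cell is trained once per
    fold up to max(epoch_grid) with per-epoch validation, and every epoch
    value in the grid is read off as a checkpoint — matching a per-epoch
    learning-curve protocol rather than retraining per epoch value.
    The learning rate is not searched for Adadelta.  Best configuration per
    optimizer: highest mean validation accuracy, ties broken by lower mean
    validation loss, then smaller epoch count.

    Returns (best TrainConfig-like dict per optimizer, long results table).
    """
    grid = grid or GridSpec()
    clf_params = dict(clf_params or {})
    clf_params.pop("optimizer", None)
    rows = []
    best: dict[str, dict] = {}
    max_epochs = max(grid.epoch_grid)
    for opt in grid.optimizers:
        lrs = (1.0,) if opt == "adadelta" else grid.learning_rates
        for lr, bs in itertools.product(lrs, grid.batch_sizes):
            params = dict(
                clf_params,
                optimizer=opt,
                learning_rate=lr,
                batch_size=bs,
                epochs=max_epochs,
            )
            cv = cross_validate(
                ds, k=k, seed=seed, clf_params=params, keep_history=True
            )
            for eps in grid.epoch_grid:
                ep = eps - 1  # epoch checkpoints are 1-based counts
                accs = [h["val_acc"][min(ep, len(h["val_acc"]) - 1)]
                        for h in cv.histories]
                losses = [h["val_loss"][min(ep, len(h["val_loss"]) - 1)]
                          for h in cv.histories]
                rows.append(
                    {
                        "optimizer": opt,
                        "learning_rate": lr,
                        "batch_size": bs,
                        "epochs": eps,
                        "val_accuracy_mean": float(np.mean(accs)),
                        "val_accuracy_sd": float(np.std(accs)),
                        "val_loss_mean": float(np.mean(losses)),
                        "val_loss_sd": float(np.std(losses)),
                    }
                )
    table = pd.DataFrame(rows)
    for opt in grid.optimizers:
        sub = table[table["optimizer"] == opt].sort_values(
            by=["val_accuracy_mean", "val_loss_mean", "epochs"],
            ascending=[False, True, True],
        )
        top = sub.iloc[0]
        best[opt] = {
            "optimizer": opt,
            "learning_rate": float(top["learning_rate"]),
            "batch_size": int(top["batch_size"]),
            "epochs": int(top["epochs"]),
        }
    return best, table


# ---------------------------------------------------------------------------
# cross-domain


def cross_domain_evaluate(
    clf: ShallowCNNClassifier, ds: AugmentedDataset
) -> MetricsReport:
    """Score a bright-field-trained model on fluorescence images, no retraining."""
    if len(ds.images) == 0:
        raise ValueError("fluorescent evaluation set is empty")
    y = ds.labels
    proba = clf.predict_proba(ds.images)[:, 1]
    pred = (proba > 0.5).astype(int)
    return metrics_from_labels(
        y, pred, ids=ds.manifest["image_id"].to_numpy(), loss=bce_loss(y, proba)
    )
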