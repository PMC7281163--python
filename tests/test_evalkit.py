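"""Folds, set-based metrics, cross-validation wiring and grid-search shape."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import confusion_matrix

import sonodeform as sd
from sonodeform.evalkit import GridSpec, GroupStratifiedCellKFold


def _cells(n_per_class=20):
    return pd.DataFrame(
        {
            "cell_id": [f"inv_{i}" for i in range(n_per_class)]
            + [f"non_{i}" for i in range(n_per_class)],
            "label": [1] * n_per_class + [0] * n_per_class,
        }
    )


class TestFolds:
    def test_canonical_40_cell_design(self):
        folds = sd.make_folds(_cells(20), k=5, seed=0)
        for f in folds:
            assert len(f.train_cell_ids) == 32
            assert len(f.test_cell_ids) == 8

    def test_partition_property(self):
        cells = _cells(20)
        folds = sd.make_folds(cells, k=5, seed=3)
        test_union = set().union(*(f.test_cell_ids for f in folds))
        assert test_union == set(cells["cell_id"])
        for a in folds:
            for b in folds:
                if a.fold_index != b.fold_index:
                    assert not set(a.test_cell_ids) & set(b.test_cell_ids)

    def test_stratified_test_composition(self):
        folds = sd.make_folds(_cells(20), k=5, seed=1)
        for f in folds:
            inv = sum(c.startswith("inv") for c in f.test_cell_ids)
            assert inv == 4 and len(f.test_cell_ids) - inv == 4

    def test_deterministic_for_seed(self):
        a = sd.make_folds(_cells(10), k=5, seed=42)
        b = sd.make_folds(_cells(10), k=5, seed=42)
        assert a == b

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError):
            sd.make_folds(_cells(2), k=5, seed=0)
        with pytest.raises(ValueError):
            sd.make_folds(_cells(5), k=1, seed=0)

    def test_sklearn_splitter_no_group_leakage(self):
        groups = np.repeat([f"c{i}" for i in range(12)], 7)
        y = np.repeat([1, 0] * 6, 7)
        cv = GroupStratifiedCellKFold(n_splits=3, seed=0)
        seen_test_groups = set()
        for train_idx, test_idx in cv.split(None, y, groups):
            tr, te = set(groups[train_idx]), set(groups[test_idx])
            assert not tr & te
            seen_test_groups |= te
        assert seen_test_groups == set(groups)


class TestMetrics:
    def test_perfect_prediction(self):
        U = set(range(10))
        M = set(range(5))
        rep = sd.compute_metrics(M, M, U)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_hand_worked_sets(self):
        """|M ∩ M*|=3, |M|=4, |M*|=5, |U|=10: p=.75, r=.60, a=.70."""
        U = set(range(10))
        M_star = {0, 1, 2, 3, 4}
        M = {2, 3, 4, 9}
        rep = sd.compute_metrics(M, M_star, U)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.60)
        assert rep.accuracy == pytest.approx(0.70)
        assert rep.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_reported_best_row_internally_consistent(self):
        """F1 computed from p=0.96, r=0.99 lands on 0.97 to two decimals."""
        f1 = 2 * 0.96 * 0.99 / (0.96 + 0.99)
        assert round(f1, 2) == 0.97

    def test_against_confusion_matrix_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            rep = sd.metrics_from_labels(y_true, y_pred)
            tn, fp, fn, tp = confusion_matrix(
                y_true, y_pred, labels=[0, 1]
            ).ravel()
            assert rep.accuracy == pytest.approx((tp + tn) / n, abs=1e-12)
            if tp + fp:
                assert rep.precision == pytest.approx(tp / (tp + fp), abs=1e-12)
            if tp + fn:
                assert rep.recall == pytest.approx(tp / (tp + fn), abs=1e-12)
            if rep.precision + rep.recall > 0:
                expect = (2 * rep.precision * rep.recall
                          / (rep.precision + rep.recall))
                assert rep.f1 == pytest.approx(expect, abs=1e-12)

    def test_empty_sets_warn(self):
        with pytest.warns(UserWarning, match="precision"):
            rep = sd.compute_metrics(set(), {1}, {1, 2})
        assert rep.precision == 0.0 and rep.f1 == 0.0
        with pytest.warns(UserWarning, match="recall"):
            rep = sd.compute_metrics({1}, set(), {1, 2})
        assert rep.recall == 0.0

    def test_subset_precondition(self):
        with pytest.raises(ValueError):
            sd.compute_metrics({99}, set(), {1, 2})


@pytest.fixture(scope="module")
def cv_result(small_augmented):
    return sd.cross_validate(
        small_augmented,
        k=4,
        seed=0,
        clf_params=dict(conv_filters=(4, 4, 4), fc_width=8, epochs=2,
                        batch_size=8),
        keep_history=True,
    )


class TestCrossValidate:
    def test_one_report_per_fold(self, cv_result):
        assert len(cv_result.fold_reports) == 4
        assert len(cv_result.cell_reports) == 4
        assert {"mean", "sd"} == set(cv_result.summary.index)

    def test_fold_universe_counts(self, cv_result, small_augmented):
        per_cell = 6  # 5 augmented + original
        for rep in cv_result.fold_reports:
            assert rep.n_universe == 2 * per_cell  # 1+1 test cells per fold

    def test_histories_recorded(self, cv_result):
        for h in cv_result.histories:
            assert len(h["val_acc"]) == len(h["epoch"]) == 2


def test_grid_cardinality_matches_stepped_ranges():
    """x10 over [0.00025, 0.25], x2 over [1, 32], +20 over [20, 300]."""
    grid = GridSpec()
    assert grid.learning_rates == (0.00025, 0.0025, 0.025, 0.25)
    assert grid.batch_sizes == (1, 2, 4, 8, 16, 32)
    assert grid.epoch_grid == tuple(range(20, 301, 20))
    assert grid.n_configurations("adam") == 4 * 6 * 15 == 360
    assert grid.n_configurations("adadelta") == 90


def test_grid_search_single_point_returns_it(small_augmented):
    grid = GridSpec(
        learning_rates=(0.0025,), batch_sizes=(8,), epoch_grid=(2,),
        optimizers=("adam",),
    )
    best, table = sd.grid_search(
        small_augmented, grid=grid, k=2, seed=0,
        clf_params=dict(conv_filters=(4, 4, 4), fc_width=8),
    )
    assert best["adam"] == {
        "optimizer": "adam", "learning_rate": 0.0025, "batch_size": 8,
        "epochs": 2,
    }
    assert set(table.columns) >= {
        "optimizer", "learning_rate", "batch_size", "epochs",
        "val_accuracy_mean", "val_accuracy_sd", "val_loss_mean", "val_loss_sd",
    }


def test_cross_domain_shift_direction(small_config, small_augmented):
    """A bright-field-trained model scores at least as well on its own
    training images as on fluorescence images (appearance shift hurts)."""
    import dataclasses

    fluor_cfg = dataclasses.replace(
        small_config, fluorescence_mode=True, n_cells_per_class=3, seed=12
    )
    records = sd.generate_dataset(fluor_cfg)
    assert len(records) == 6 and all(r.fluorescent for r in records)
    images, manifest = sd.combine_dataset(records)
    fluor = sd.augment_dataset(
        images, manifest, sd.AugmentConfig(n_augment_per_cell=5, seed=3)
    )
    clf = sd.ShallowCNNClassifier(
        conv_filters=(4, 4, 4), fc_width=8, epochs=4, batch_size=8, seed=0
    )
    clf.fit(small_augmented.images, small_augmented.labels)
    own = sd.cross_domain_evaluate(clf, small_augmented)
    shifted = sd.cross_domain_evaluate(clf, fluor)
    assert own.accuracy >= shifted.accuracy
    # Table-shaped report: all four metrics plus loss are populated
    assert set(shifted.as_dict()) == {"accuracy", "precision", "recall",
                                      "f1", "loss"}


def test_cross_domain_requires_nonempty(small_augmented):
    clf = sd.ShallowCNNClassifier(
        conv_filters=(4, 4, 4), fc_width=8, epochs=1, batch_size=8, seed=0
    )
    clf.fit(small_augmented.images, small_augmented.labels)
    empty = sd.AugmentedDataset(
        images=np.zeros((0, 48, 48, 3), np.uint8),
        manifest=small_augmented.manifest.iloc[:0],
    )
    with pytest.raises(ValueError):
        sd.cross_domain_evaluate(clf, empty)
    rep = sd.cross_domain_evaluate(clf, small_augmented)
    assert 0.0 <= rep.accuracy <= 1.0
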