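"""Cross-validation splitting, the metric formula suite against exact
rational arithmetic, ROC against the rank-statistic oracle, and training
bookkeeping."""

import dataclasses
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from burnganext.config import SynthConfig, TrainingHyperparams
from burnganext.data import generate_dataset, records_to_arrays
from burnganext.errors import ConfigurationError, InputError, UsageError
from burnganext.evaluate import (
    confusion_matrix,
    holdout_split,
    kfold_split,
    metrics_from_cm,
    roc_curve_ovr,
    run_cv_experiment,
    train_model,
)
from burnganext.model import build_model
from conftest import tiny_model_config


def rational_metrics_oracle(cm, mode="standard"):
    """Formula-by-formula transcription with exact Fractions."""
    cm = np.asarray(cm, dtype=object)
    total = int(sum(sum(row) for row in cm))
    k = cm.shape[0]
    out = {}
    for i in range(k):
        tp = int(cm[i][i])
        fn = int(sum(cm[i])) - tp
        fp = int(sum(cm[j][i] for j in range(k))) - tp
        tn = total - tp - fn - fp
        row = {}
        row["accuracy"] = Fraction(tp + tn, total)
        row["precision"] = Fraction(tp, tp + fp) if tp + fp else None
        row["recall"] = Fraction(tp, tp + fn) if tp + fn else None
        if row["precision"] is None or row["recall"] is None or \
                (row["precision"] + row["recall"]) == 0:
            row["f1"] = None
        else:
            row["f1"] = 2 * row["precision"] * row["recall"] / (row["precision"] + row["recall"])
        row["sensitivity"] = row["recall"]
        if mode == "standard":
            row["specificity"] = Fraction(tn, tn + fp) if tn + fp else None
        else:
            row["specificity"] = Fraction(tn, tp + tn) if tp + tn else None
        out[i] = row
    return out


class TestKFold:
    def test_fold_sizes(self):
        folds = kfold_split(range(100), k=5, seed=0)
        assert all(len(f.val_ids) == 20 for f in folds)
        assert all(len(f.train_ids) == 80 for f in folds)

    def test_partition_property(self):
        ids = [f"img{i}" for i in range(53)]
        folds = kfold_split(ids, k=5, seed=1)
        union = [i for f in folds for i in f.val_ids]
        assert sorted(union) == sorted(ids)
        for f in folds:
            assert not set(f.val_ids) & set(f.train_ids)

    def test_deterministic_under_seed(self):
        a = kfold_split(range(40), k=5, seed=3)
        b = kfold_split(range(40), k=5, seed=3)
        assert a == b
        c = kfold_split(range(40), k=5, seed=4)
        assert a != c

    def test_stratification(self):
        labels = [0] * 50 + [1] * 50
        for fold in kfold_split(range(100), labels, k=5, seed=0):
            val_labels = [labels[i] for i in fold.val_ids]
            assert val_labels.count(0) == 10 and val_labels.count(1) == 10

    def test_too_few_items_rejected(self):
        with pytest.raises(InputError):
            kfold_split(range(3), k=5)


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 1], [0, 1, 2, 1], 3)
        np.testing.assert_array_equal(cm, np.diag([1, 2, 1]))

    def test_hand_counted_example(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 2]])

    def test_total_conservation(self, rng):
        y = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        assert confusion_matrix(y, p, 4).sum() == 200

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            confusion_matrix([0, 3], [0, 1], 3)


class TestMetricsFromCm:
    def test_worked_binary_example(self):
        cm = np.array([[9, 1], [1, 9]])  # class 1: TP=9, FP=1, FN=1, TN=9
        rep = metrics_from_cm(cm)
        for m in ("precision", "recall", "f1", "sensitivity", "specificity", "accuracy"):
            assert rep.per_class[1][m] == pytest.approx(90.0)

    def test_literal_specificity_mode(self):
        cm = np.array([[9, 1], [1, 9]])
        rep = metrics_from_cm(cm, mode="literal")
        assert rep.per_class[1]["specificity"] == pytest.approx(50.0)
        assert metrics_from_cm(cm).per_class[1]["specificity"] == pytest.approx(90.0)

    def test_perfect_diagonal_all_hundred(self):
        rep = metrics_from_cm(np.diag([5, 3, 7]))
        for cls in rep.per_class.values():
            for v in cls.values():
                assert v == pytest.approx(100.0)
        assert rep.overall_accuracy == pytest.approx(100.0)

    def test_recall_equals_sensitivity_always(self, rng):
        for _ in range(200):
            k = rng.integers(2, 5)
            cm = rng.integers(0, 15, (k, k))
            if cm.sum() == 0:
                continue
            rep = metrics_from_cm(cm)
            for cls in rep.per_class.values():
                if np.isnan(cls["recall"]):
                    assert np.isnan(cls["sensitivity"])
                else:
                    assert cls["recall"] == cls["sensitivity"]

    @pytest.mark.parametrize("mode", ["standard", "literal"])
    def test_rational_arithmetic_oracle(self, rng, mode):
        for _ in range(300):
            k = int(rng.integers(2, 5))
            cm = rng.integers(0, 12, (k, k))
            if cm.sum() == 0:
                continue
            rep = metrics_from_cm(cm, mode=mode)
            oracle = rational_metrics_oracle(cm, mode)
            for i in range(k):
                for m, frac in oracle[i].items():
                    got = rep.per_class[i][m]
                    if frac is None:
                        assert np.isnan(got)
                        assert (i, m) in rep.undefined or m == "f1"
                    else:
                        assert got == pytest.approx(float(frac) * 100, abs=1e-9)

    def test_zero_denominator_flagged_not_zeroed(self):
        cm = np.array([[5, 0], [0, 0]])  # class 1 never true nor predicted
        rep = metrics_from_cm(cm)
        assert np.isnan(rep.per_class[1]["precision"])
        assert (1, "precision") in rep.undefined

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            metrics_from_cm(np.zeros((3, 3), dtype=int))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hnp.arrays(np.int64, (3, 3), elements=st.integers(0, 30)))
    def test_metric_bounds_property(self, cm):
        """All defined statistics lie in [0, 100]."""
        if cm.sum() == 0:
            return
        rep = metrics_from_cm(cm)
        for cls in rep.per_class.values():
            for v in cls.values():
                assert np.isnan(v) or 0.0 <= v <= 100.0
        assert 0.0 <= rep.overall_accuracy <= 100.0


def mann_whitney_auc(y, s):
    """Pairwise-comparison (rank-statistic) AUC oracle."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_ranking(self):
        curves = roc_curve_ovr([0, 0, 1, 1], np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
        assert curves[0].auc == pytest.approx(1.0)
        assert curves[1].auc == pytest.approx(1.0)

    def test_constant_scores_chance_level(self):
        scores = np.full((20, 2), 0.5)
        y = [0, 1] * 10
        curves = roc_curve_ovr(y, scores)
        assert curves[0].auc == pytest.approx(0.5)

    def test_rank_statistic_oracle(self, rng):
        for _ in range(25):
            y = rng.integers(0, 2, 20)
            if y.min() == y.max():
                continue
            s = rng.random(20)
            curves = roc_curve_ovr(y, np.column_stack([1 - s, s]))
            assert curves[1].auc == pytest.approx(mann_whitney_auc(y, s), abs=1e-9)

    def test_single_class_truth_flagged(self):
        curves = roc_curve_ovr([1, 1, 1], np.array([[0.2, 0.8]] * 3))
        assert np.isnan(curves[0].auc) and np.isnan(curves[1].auc)

    def test_monotone_from_origin_to_one(self, rng):
        y = rng.integers(0, 2, 30)
        s = rng.random(30)
        curve = roc_curve_ovr(y, np.column_stack([1 - s, s]))[1]
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()


class TestTrainModel:
    def test_zero_learning_rate_leaves_weights(self, rng, tiny_config):
        net = build_model(tiny_config, seed=0)
        before = [p.data.copy() for p in net.parameters()]
        x = rng.random((8, 3, 24, 24), dtype=np.float32)
        y = rng.integers(0, 3, 8)
        train_model(net, x, y, TrainingHyperparams(learning_rate=0.0, epochs=2, seed=0))
        for b, p in zip(before, net.parameters()):
            np.testing.assert_allclose(p.data, b, atol=1e-12)

    def test_single_batch_single_step(self, rng, tiny_config):
        net = build_model(tiny_config, seed=0)
        x = rng.random((32, 3, 24, 24), dtype=np.float32)
        y = rng.integers(0, 3, 32)
        hist = train_model(net, x, y, TrainingHyperparams(epochs=1, batch_size=32, seed=0))
        assert hist["steps"] == [1]

    def test_arity_mismatch_rejected(self, rng):
        net = build_model(tiny_model_config(num_classes=2), seed=0)
        x = rng.random((4, 3, 24, 24), dtype=np.float32)
        with pytest.raises(ConfigurationError):
            train_model(net, x, np.array([0, 1, 2, 1]), TrainingHyperparams(epochs=1))


def make_solid_color_records(n_per_class=15, size=24):
    """Labels encoded in a solid color: a perfectly separable toy set."""
    from burnganext.data import ImageRecord

    colors = {"superficial": (255, 0, 0), "deep_dermal": (0, 255, 0),
              "full_thickness": (0, 0, 255)}
    records = []
    for label, col in colors.items():
        for i in range(n_per_class):
            px = np.tile(np.array(col, np.uint8), (size, size, 1))
            records.append(ImageRecord(px, label, "synthetic", f"{label}-{i}"))
    return records


@pytest.fixture(scope="module")
def toy_cv_result():
    records = make_solid_color_records()
    cfg = tiny_model_config(num_classes=3)
    hp = TrainingHyperparams(learning_rate=5e-3, epochs=4, batch_size=16, seed=0)
    return run_cv_experiment(records, "degree", cfg, hp, k=5, seed=0)


class TestRunCV:

    def test_separable_toy_set_all_folds_perfect(self, toy_cv_result):
        for rep in toy_cv_result.fold_reports:
            for m, v in rep.macro.items():
                assert v == pytest.approx(100.0), (m, v)

    def test_average_row_is_mean_of_folds(self, toy_cv_result):
        table = toy_cv_result.table()
        np.testing.assert_allclose(
            table.iloc[:-1].mean(axis=0), table.iloc[-1], atol=0.01
        )

    def test_table_layout(self, toy_cv_result):
        table = toy_cv_result.table()
        assert list(table.columns) == [
            "Precision", "Recall", "F1-score", "Sensitivity", "Specificity", "Accuracy"
        ]
        assert list(table.index) == [f"Fold{i}" for i in range(1, 6)] + ["Average"]

    def test_run_log_records_policy(self, toy_cv_result):
        log = toy_cv_result.run_log
        assert log["augmentation_policy"] == "none"
        assert "config_sha256" in log and log["k"] == 5

    def test_task_arity_checked(self):
        records = make_solid_color_records(5)
        with pytest.raises(ConfigurationError):
            run_cv_experiment(
                records, "graft", tiny_model_config(num_classes=3),
                TrainingHyperparams(epochs=1), k=2,
            )

    def test_graft_task_binary(self):
        records = make_solid_color_records(6)
        cfg = tiny_model_config(num_classes=2)
        hp = TrainingHyperparams(learning_rate=5e-3, epochs=2, batch_size=9, seed=0)
        res = run_cv_experiment(records, "graft", cfg, hp, k=2, seed=0)
        assert all(cm.shape == (2, 2) for cm in res.fold_cms)

    def test_unknown_task_rejected(self):
        with pytest.raises(UsageError):
            run_cv_experiment([], "severity", tiny_model_config(), TrainingHyperparams())


class TestHoldout:
    def test_80_20_fraction(self):
        split = holdout_split(range(200), [0, 1] * 100, seed=0)
        assert len(split.val_ids) == 40
        assert len(split.train_ids) == 160
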