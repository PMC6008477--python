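import numpy as np
import pandas as pd
import pytest

from mcgkit.classify import (
    confusion_matrix,
    evaluate_loocv,
    loocv_split,
    majority_vote,
    metrics,
    train_predict,
)
from mcgkit.config import PipelineConfig


def _table(n_subjects=5, segs_per_subject=3, n_features=4, seed=0):
    """Linearly separable 2-class feature table, subjects alternate classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        label = "a" if s % 2 == 0 else "b"
        shift = 0.0 if label == "a" else 8.0
        for e in range(segs_per_subject):
            rows.append(
                {
                    "subject_id": f"s{s}",
                    "episode": e,
                    "label": label,
                    **{
                        f"f{k}": shift + rng.standard_normal()
                        for k in range(n_features)
                    },
                }
            )
    return pd.DataFrame(rows)


class TestLOOCVSplit:
    def test_one_fold_per_subject(self):
        table = _table(5)
        folds = list(loocv_split(table))
        assert len(folds) == 5
        assert {s for s, _, _ in folds} == set(table["subject_id"])

    def test_fold_sizes_and_partition(self):
        table = _table(5, segs_per_subject=3)
        all_test = []
        for subject, train_idx, test_idx in loocv_split(table):
            assert len(test_idx) == 3
            assert set(train_idx).isdisjoint(test_idx)
            assert set(table.iloc[test_idx]["subject_id"]) == {subject}
            assert subject not in set(table.iloc[train_idx]["subject_id"])
            all_test.extend(test_idx)
        assert sorted(all_test) == list(range(len(table)))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            list(loocv_split(_table(1)))


class TestTrainPredict:
    @pytest.mark.parametrize("clf", ["ksvm", "rf"])
    def test_separable_data_perfect(self, clf):
        table = _table(6, segs_per_subject=4)
        x = table[[c for c in table.columns if c.startswith("f")]].to_numpy()
        y = table["label"].to_numpy()
        cfg = PipelineConfig(rf_n_estimators=50)
        pred, conf = train_predict(x[:16], y[:16], x[16:], clf, seed=0, config=cfg)
        np.testing.assert_array_equal(pred, y[16:])
        assert conf.shape == pred.shape

    def test_seed_determinism(self):
        table = _table(6, segs_per_subject=4, seed=3)
        x = table[[c for c in table.columns if c.startswith("f")]].to_numpy()
        y = table["label"].to_numpy()
        cfg = PipelineConfig(rf_n_estimators=50)
        p1, _ = train_predict(x[:16], y[:16], x[16:], "rf", seed=7, config=cfg)
        p2, _ = train_predict(x[:16], y[:16], x[16:], "rf", seed=7, config=cfg)
        np.testing.assert_array_equal(p1, p2)

    def test_duplicated_training_rows_same_predictions_ksvm(self):
        # DERIVED oracle: direct refit on the duplicated set.
        table = _table(6, segs_per_subject=4, seed=4)
        x = table[[c for c in table.columns if c.startswith("f")]].to_numpy()
        y = table["label"].to_numpy()
        cfg = PipelineConfig(svm_c_grid=(10.0,))  # fixed C: no inner CV
        p1, _ = train_predict(x[:16], y[:16], x[16:], "ksvm", config=cfg)
        x_dup = np.vstack([x[:16], x[:16]])
        y_dup = np.concatenate([y[:16], y[:16]])
        p2, _ = train_predict(x_dup, y_dup, x[16:], "ksvm", config=cfg)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_train_rejected(self):
        x = np.zeros((4, 2))
        with pytest.raises(ValueError, match="single class"):
            train_predict(x, np.array(["a"] * 4), x, "ksvm")


class TestMajorityVote:
    def test_simple_majority(self):
        assert majority_vote(["a", "a", "b"]) == "a"

    def test_single_segment(self):
        assert majority_vote(["a"]) == "a"

    def test_tie_broken_by_confidence(self):
        assert majority_vote(["a", "b"], confidences=[0.2, 0.9]) == "b"
        assert majority_vote(["a", "b"], confidences=[0.9, 0.2]) == "a"

    def test_tie_without_confidence_lowest_label(self):
        assert majority_vote(["b", "a"]) == "a"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestMetrics:
    def test_perfect_two_class(self):
        m = metrics(np.array([[40, 0], [0, 23]]), ["pos", "neg"])
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0
        assert m["acc"] == 1.0

    def test_two_class_arithmetic(self):
        # DERIVED oracle: direct arithmetic on the counts (disease row first)
        m = metrics(np.array([[39, 1], [0, 24]]), ["pos", "neg"])
        assert m["sensitivity"] == pytest.approx(39 / 40)  # 0.975
        assert m["specificity"] == 1.0
        assert m["acc"] == pytest.approx(63 / 64)

    def test_three_class_diagonal(self):
        m = metrics(np.diag([10, 10, 10]), ["a", "b", "c"])
        assert m["acc"] == 1.0
        assert all(v == 1.0 for v in m["f1_per_class"].values())
        assert m["f1_mean"] == 1.0

    def test_f1_matches_hand_computation(self):
        cm = np.array([[8, 2], [1, 9]])
        m = metrics(cm, ["a", "b"])
        precision_a, recall_a = 8 / 9, 8 / 10
        f1_a = 2 * precision_a * recall_a / (precision_a + recall_a)
        assert m["f1_per_class"]["a"] == pytest.approx(f1_a)

    def test_undefined_metric_is_nan_not_zero(self):
        m = metrics(np.array([[0, 5], [0, 5]]), ["a", "b"])
        assert np.isnan(m["f1_per_class"]["a"])  # precision 0/0
        assert np.isnan(m["f1_mean"])

    def test_row_sums_are_class_counts(self):
        cm = confusion_matrix(
            ["a", "a", "b", "b", "b"], ["a", "b", "b", "b", "a"], ["a", "b"]
        )
        np.testing.assert_array_equal(cm.sum(axis=1), [2, 3])
        np.testing.assert_array_equal(cm, [[1, 1], [1, 2]])


class TestEvaluateLOOCV:
    def test_separable_table_perfect_both_classifiers(self):
        table = _table(6, segs_per_subject=3)
        cfg = PipelineConfig(rf_n_estimators=50)
        for clf in ("ksvm", "rf"):
            report = evaluate_loocv(table, clf, seed=0, config=cfg)
            assert report.segment_metrics["acc"] == 1.0
            assert report.vote_metrics["acc"] == 1.0
            assert report.n_subjects == 6
            assert report.n_segments == 18

    def test_report_serializes(self):
        table = _table(4, segs_per_subject=2)
        cfg = PipelineConfig(rf_n_estimators=20)
        report = evaluate_loocv(table, "rf", seed=0, config=cfg)
        payload = report.to_dict()
        assert "with_majority_voting" in payload
        assert "without_majority_voting" in payload

    def test_majority_vote_fixes_minority_errors(self):
        # definitional check: a recording whose majority of segments are
        # correct is correct after voting
        seg_preds = ["a", "a", "b"]
        assert majority_vote(seg_preds) == "a"
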