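"""Subject-wise cross-validated classification and evaluation metrics.

Feature tables (one row per 10 s segment) are evaluated with
leave-one-person-out cross-validation: each fold holds out every segment of
one subject.  Classifiers are a kernel SVM (RBF, regularisation chosen by a
small inner grid search on the training fold) and a random forest; features
are z-scored with training-fold statistics only.  Per-recording labels are
obtained by majority voting over the segment predictions, ties broken by the
larger summed prediction confidence, then by the lexicographically smallest
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .assembly import META_COLUMNS
from .config import PipelineConfig

__all__ = [
    "CLASSIFIERS",
    "EvaluationReport",
    "loocv_split",
    "make_classifier",
    "train_predict",
    "majority_vote",
    "confusion_matrix",
    "metrics",
    "evaluate_loocv",
]

CLASSIFIERS = ("ksvm", "rf")


def loocv_split(
    table: pd.DataFrame,
) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
    """Yield (held-out subject, train row indices, test row indices).

    Every segment of the held-out subject is test; all other subjects'
    segments are train.  Requires at least two subjects.
    """
    subjects = table["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("leave-one-person-out needs at least 2 subjects")
    positions = np.arange(len(table))
    for subject in subjects:
        mask = (table["subject_id"] == subject).to_numpy()
        yield subject, positions[~mask], positions[mask]


def make_classifier(
    name: str, seed: int = 0, config: Optional[PipelineConfig] = None
):
    """Build an unfitted classifier pipeline (z-scoring included)."""
    config = config or PipelineConfig()
    if name == "ksvm":
        svc = SVC(kernel="rbf", gamma=config.svm_gamma)
        if len(config.svm_c_grid) > 1:
            estimator = GridSearchCV(
                svc,
                param_grid={"C": list(config.svm_c_grid)},
                cv=config.svm_inner_cv,
                n_jobs=1,
            )
        else:
            svc.set_params(C=config.svm_c_grid[0])
            estimator = svc
        return Pipeline([("scale", StandardScaler()), ("clf", estimator)])
    if name == "rf":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    RandomForestClassifier(
                        n_estimators=config.rf_n_estimators, random_state=seed
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def train_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    classifier: str = "ksvm",
    seed: int = 0,
    config: Optional[PipelineConfig] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on the training fold and predict the test fold.

    Returns (predicted labels, per-segment confidence of the predicted
    label).  Confidences are |decision function| for the SVM and the modal
    class probability for the forest; they only serve vote tie-breaking.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training fold contains a single class")
    model = make_classifier(classifier, seed, config)
    model.fit(train_x, train_y)
    pred = model.predict(test_x)
    if classifier == "rf":
        proba = model.predict_proba(test_x)
        conf = proba.max(axis=1)
    else:
        df = model.decision_function(test_x)
        conf = np.abs(df) if df.ndim == 1 else np.max(df, axis=1)
    return pred, np.asarray(conf, dtype=float)


def majority_vote(
    labels: Sequence, confidences: Optional[Sequence[float]] = None
):
    """Modal label of one recording's segment predictions.

    Ties: the tied label with the larger summed confidence wins; with no
    confidences (or a further tie) the lexicographically smallest label wins.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("majority_vote needs at least one segment label")
    counts: dict = {}
    scores: dict = {}
    for i, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        if confidences is not None:
            scores[lab] = scores.get(lab, 0.0) + float(confidences[i])
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    if confidences is not None:
        best = max(scores[lab] for lab in tied)
        tied = [lab for lab in tied if scores[lab] == best]
    return min(tied, key=str)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, labels: Sequence
) -> np.ndarray:
    """K x K confusion matrix; rows = true class, columns = predicted."""
    index = {lab: k for k, lab in enumerate(labels)}
    out = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        out[index[t], index[p]] += 1
    return out


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(confusion: np.ndarray, labels: Sequence) -> dict:
    """Evaluation metrics from a confusion matrix.

    Always reports ``acc`` (trace over total), per-class one-vs-rest F1 and
    their mean.  For two classes, also sensitivity/specificity with the
    first row treated as the positive (disease) class.  Undefined ratios
    (zero denominators) are reported as ``nan``, never as 0.
    """
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    out: dict = {
        "labels": [str(l) for l in labels],
        "confusion": confusion.tolist(),
        "acc": float(np.trace(confusion) / total),
    }
    f1: dict[str, float] = {}
    for k, lab in enumerate(labels):
        tp = confusion[k, k]
        fn = confusion[k].sum() - tp
        fp = confusion[:, k].sum() - tp
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        f1[str(lab)] = _safe_div(2 * precision * recall, precision + recall)
    out["f1_per_class"] = f1
    out["f1_mean"] = float(np.mean(list(f1.values())))
    if len(labels) == 2:
        tp, fn = confusion[0, 0], confusion[0, 1]
        fp, tn = confusion[1, 0], confusion[1, 1]
        out["sensitivity"] = _safe_div(tp, tp + fn)
        out["specificity"] = _safe_div(tn, tn + fp)
    return out


@dataclass
class EvaluationReport:
    """Cross-validated results with and without majority voting."""

    classifier: str
    labels: list[str]
    segment_metrics: dict
    vote_metrics: dict
    n_subjects: int
    n_segments: int

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "labels": self.labels,
            "n_subjects": self.n_subjects,
            "n_segments": self.n_segments,
            "without_majority_voting": self.segment_metrics,
            "with_majority_voting": self.vote_metrics,
        }


def evaluate_loocv(
    table: pd.DataFrame,
    classifier: str = "ksvm",
    seed: int = 0,
    config: Optional[PipelineConfig] = None,
    label_order: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Leave-one-person-out evaluation of a feature table.

    ``label_order`` fixes the confusion-matrix row order (first label is the
    positive class in two-class metrics); default is sorted order.
    """
    config = config or PipelineConfig()
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    x = table[feature_cols].to_numpy(float)
    y = table["label"].to_numpy()
    if label_order is None:
        label_order = sorted(np.unique(y).tolist())

    seg_true: list = []
    seg_pred: list = []
    rec_true: list = []
    rec_pred: list = []
    n_subjects = 0
    for subject, train_idx, test_idx in loocv_split(table):
        n_subjects += 1
        pred, conf = train_predict(
            x[train_idx], y[train_idx], x[test_idx], classifier, seed, config
        )
        seg_true.extend(y[test_idx])
        seg_pred.extend(pred)
        rec_true.append(y[test_idx][0])
        rec_pred.append(majority_vote(list(pred), list(conf)))

    return EvaluationReport(
        classifier=classifier,
        labels=[str(l) for l in label_order],
        segment_metrics=metrics(
            confusion_matrix(seg_true, seg_pred, label_order), label_order
        ),
        vote_metrics=metrics(
            confusion_matrix(rec_true, rec_pred, label_order), label_order
        ),
        n_subjects=n_subjects,
        n_segments=len(seg_true),
    )
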