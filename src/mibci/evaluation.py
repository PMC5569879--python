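"""Accuracy bookkeeping: confusion matrices and classifier comparison."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .classify import KNNSVMClassifier
from .montage import CLASS_ORDER


@dataclass
class ConfusionMatrix:
    """4 x 4 confusion counts, rows = true class, columns = predicted,
    both in canonical order (R, RF, LH, RS)."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER
    per_class_accuracy: np.ndarray = field(init=False)
    overall_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError(f"counts must be a non-negative {k} x {k} matrix")
        row_sums = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            self.per_class_accuracy = np.where(
                row_sums > 0, np.diag(self.counts) / np.maximum(row_sums, 1), np.nan
            )
        total = self.counts.sum()
        self.overall_accuracy = float(np.trace(self.counts) / total) if total else float("nan")

    @classmethod
    def from_labels(
        cls, y_true, y_pred, class_order: tuple[str, ...] = CLASS_ORDER
    ) -> "ConfusionMatrix":
        pos = {c: i for i, c in enumerate(class_order)}
        counts = np.zeros((len(class_order), len(class_order)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[pos[t], pos[p]] += 1
        return cls(counts=counts, class_order=class_order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


def evaluate_predictions(y_true, y_pred) -> ConfusionMatrix:
    """Aggregate predictions into a canonical-order confusion matrix."""
    return ConfusionMatrix.from_labels(y_true, y_pred)


def evaluate(model, test, pipeline_config=None) -> ConfusionMatrix:
    """End-to-end evaluation of a fitted pipeline model on a test Dataset.

    Runs preprocessing, feature extraction and prediction per trial (see
    :mod:`mibci.pipeline` for the model bundle), deterministic given fixed
    model and data. Also accepts precomputed ``(features, labels)`` pairs
    together with a fitted :class:`KNNSVMClassifier`.
    """
    if isinstance(test, tuple) and isinstance(model, KNNSVMClassifier):
        features, labels = test
        return evaluate_predictions(labels, model.predict(features))
    from .pipeline import evaluate_bundle  # local import: avoid cycle

    return evaluate_bundle(model, test, pipeline_config)


def compare_classifiers(
    subject_sets: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    roster: dict | None = None,
    model_factory=None,
) -> pd.DataFrame:
    """Accuracy table across subjects for a roster of classifiers.

    ``subject_sets`` holds one ``(X_train, y_train, X_test, y_test)`` tuple
    per subject (identical features and splits for every classifier).
    Roster values may be the strings ``"knn"``, ``"svm"``, ``"knn-svm"``
    (three decision rules read off ONE fitted hybrid model per subject), an
    sklearn estimator (cloned per subject), or a callable
    ``(X_tr, y_tr, X_te) -> predictions``. Returns one row per classifier
    with per-subject accuracies, the mean, and the across-subject standard
    deviation (n - 1 denominator).
    """
    if roster is None:
        roster = {"KNN": "knn", "SVM": "svm", "KNN-SVM": "knn-svm"}
    if model_factory is None:
        model_factory = lambda: KNNSVMClassifier(k=5)

    hybrid_models = None
    if any(isinstance(v, str) for v in roster.values()):
        hybrid_models = [model_factory().fit(x, y) for x, y, _, _ in subject_sets]

    rows = {}
    for name, entry in roster.items():
        accs = []
        for s, (x_tr, y_tr, x_te, y_te) in enumerate(subject_sets):
            if isinstance(entry, str):
                model = hybrid_models[s]
                pred = {
                    "knn": model.predict_knn_only,
                    "svm": model.predict_svm_only,
                    "knn-svm": model.predict,
                }[entry](x_te)
            elif callable(entry) and not hasattr(entry, "fit"):
                pred = entry(x_tr, y_tr, x_te)
            else:
                pred = clone(entry).fit(x_tr, y_tr).predict(x_te)
            accs.append(float(np.mean(np.asarray(pred, dtype=object) == np.asarray(y_te, dtype=object))))
        rows[name] = accs
    subjects = [f"S{i + 1}" for i in range(len(subject_sets))]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=subjects)
    frame["mean"] = frame[subjects].mean(axis=1)
    frame["sd"] = frame[subjects].std(axis=1, ddof=1) if len(subjects) > 1 else 0.0
    return frame


__all__ = ["ConfusionMatrix", "evaluate_predictions", "evaluate", "compare_classifiers"]
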