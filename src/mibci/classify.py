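"""Hybrid KNN-SVM classifier for motor-imagery feature vectors.

Two-stage decision rule: a cosine-distance K-nearest-neighbor stage produces
a rough shortlist of at most two candidate classes (robust on crossed or
overlapping feature clouds); if the shortlist is unanimous the sample is
classified directly, otherwise the one-against-one support-vector machine
trained on exactly those two classes makes the final call (good small-sample
generalization at the margin).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .montage import CLASS_ORDER


@dataclass
class RoughResult:
    """KNN stage output: 1-2 shortlisted classes with descending weights."""

    shortlist: tuple[str, ...]
    weights: tuple[float, ...]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine angle distance 1 - u.v / (|u||v|), in [0, 2]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("undefined direction: zero vector has no cosine distance")
    return float(1.0 - u @ v / (nu * nv))


def _canonical_rank(label: str) -> int:
    return CLASS_ORDER.index(label) if label in CLASS_ORDER else len(CLASS_ORDER)


class KNNSVMClassifier(BaseEstimator, ClassifierMixin):
    """Cosine-KNN shortlist followed by a pairwise SVM decision.

    Parameters
    ----------
    k : neighbor count for the rough stage (default 5).
    kernel : SVM kernel for the pairwise classifiers ("rbf" or "linear").
    C : SVM regularization strength.
    svm_gamma : RBF bandwidth; "scale" = inverse feature-variance scaling.
    weighting : class weight in the rough stage — "similarity" sums
        (1 - cosine distance) over a class's neighbors, "count" counts them.
    preprocess : feature preprocessing fitted on the training split only:
        "standardize" (per-dimension z-score), "l2" (unit-norm rows, makes
        the whole decision scale-invariant with a linear kernel), or "none".

    Attributes (set by fit)
    -----------------------
    classes_ : class labels in canonical order.
    train_features_ : preprocessed training features (the KNN memory).
    train_labels_ : matching labels.
    pair_classifiers_ : dict mapping unordered class pairs to fitted SVCs.
    """

    def __init__(
        self,
        k: int = 5,
        kernel: str = "rbf",
        C: float = 1.0,
        svm_gamma: str | float = "scale",
        weighting: str = "similarity",
        preprocess: str = "standardize",
    ):
        self.k = k
        self.kernel = kernel
        self.C = C
        self.svm_gamma = svm_gamma
        self.weighting = weighting
        self.preprocess = preprocess

    # -- preprocessing -----------------------------------------------------

    def _pre_fit(self, X: np.ndarray) -> np.ndarray:
        if self.preprocess == "standardize":
            self.scaler_ = StandardScaler().fit(X)
            return self.scaler_.transform(X)
        self.scaler_ = None
        return self._pre_apply(X)

    def _pre_apply(self, X: np.ndarray) -> np.ndarray:
        if self.preprocess == "standardize":
            return self.scaler_.transform(X)
        if self.preprocess == "l2":
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("undefined direction: zero feature vector")
            return X / norms
        if self.preprocess == "none":
            return X
        raise ValueError(f"unknown preprocess {self.preprocess!r}")

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y) -> "KNNSVMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if self.k < 1 or self.k > X.shape[0]:
            raise ValueError(f"k={self.k} must be in [1, n_samples={X.shape[0]}]")
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) < 2:
            raise ValueError("incomplete training set: need at least two classes")
        if np.any(counts < 2):
            few = [str(l) for l, c in zip(labels, counts) if c < 2]
            raise ValueError(f"incomplete training set: fewer than 2 trials for {few}")
        self.classes_ = np.array(sorted(labels, key=_canonical_rank), dtype=object)
        Xt = self._pre_fit(X)
        self.train_features_ = Xt
        self.train_labels_ = y
        self.pair_classifiers_ = {}
        for ci, cj in combinations(self.classes_, 2):
            mask = (y == ci) | (y == cj)
            svc = SVC(kernel=self.kernel, C=self.C, gamma=self.svm_gamma)
            svc.fit(Xt[mask], y[mask])
            self.pair_classifiers_[frozenset((ci, cj))] = svc
        return self

    def _rough(self, xt: np.ndarray) -> RoughResult:
        dists = np.array([cosine_distance(xt, f) for f in self.train_features_])
        order = np.argsort(dists, kind="stable")[: self.k]
        weights: dict[str, float] = {}
        for idx in order:
            lab = self.train_labels_[idx]
            w = (1.0 - dists[idx]) if self.weighting == "similarity" else 1.0
            weights[lab] = weights.get(lab, 0.0) + w
        ranked = sorted(weights.items(), key=lambda kv: (-kv[1], _canonical_rank(kv[0])))
        top = ranked[:2]
        return RoughResult(
            shortlist=tuple(lab for lab, _ in top),
            weights=tuple(w for _, w in top),
        )

    def knn_rough(self, sample: np.ndarray) -> RoughResult:
        """Rough KNN shortlist for one (raw, unpreprocessed) feature vector."""
        xt = self._pre_apply(np.asarray(sample, dtype=float)[None, :])[0]
        return self._rough(xt)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xt = self._pre_apply(X)
        out = []
        for xt in Xt:
            rough = self._rough(xt)
            if len(rough.shortlist) == 1:
                out.append(rough.shortlist[0])
            else:
                svc = self.pair_classifiers_[frozenset(rough.shortlist)]
                out.append(svc.predict(xt[None, :])[0])
        return np.array(out, dtype=object)

    # -- baselines sharing the same fitted model ---------------------------

    def predict_knn_only(self, X) -> np.ndarray:
        """Plain weighted-KNN decision (top-1 class weight)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array(
            [self._rough(xt).shortlist[0] for xt in self._pre_apply(X)], dtype=object
        )

    def predict_svm_only(self, X) -> np.ndarray:
        """One-against-one SVM majority vote over all six pair classifiers."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xt = self._pre_apply(X)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        pos = {c: i for i, c in enumerate(self.classes_)}
        for svc in self.pair_classifiers_.values():
            for i, lab in enumerate(svc.predict(Xt)):
                votes[i, pos[lab]] += 1
        # ties resolve to the earliest class in canonical order (argmax)
        return self.classes_[np.argmax(votes, axis=1)]


def fit(train_features, train_labels, k: int = 5, **svm_params) -> KNNSVMClassifier:
    """Functional wrapper: fit a :class:`KNNSVMClassifier`."""
    return KNNSVMClassifier(k=k, **svm_params).fit(train_features, train_labels)


def knn_rough(sample, model: KNNSVMClassifier) -> RoughResult:
    """Functional wrapper around :meth:`KNNSVMClassifier.knn_rough`."""
    return model.knn_rough(sample)


def predict(model: KNNSVMClassifier, sample) -> str:
    """Functional wrapper: classify one feature vector."""
    return str(model.predict(np.asarray(sample)[None, :])[0])


__all__ = [
    "RoughResult",
    "KNNSVMClassifier",
    "cosine_distance",
    "fit",
    "knn_rough",
    "predict",
]
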