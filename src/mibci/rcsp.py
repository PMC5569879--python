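"""Regularized common spatial patterns (R-CSP) with generic learning.

CSP finds spatial filters w maximizing the variance ratio of two classes by
jointly diagonalizing their average covariance matrices. With few training
trials the covariance estimates are unstable; R-CSP shrinks them twice:

* beta in [0, 1] shrinks the subject's class covariance toward a "generic"
  covariance pooled from the OTHER subjects' training trials (generic
  learning — inter-subject regularization),
* gamma in [0, 1] shrinks toward a scaled identity (trace-preserving
  Ledoit-Wolf-style bias correction for small samples).

With beta = gamma = 0 the method reduces exactly to classical CSP. For four
classes the one-vs-one scheme builds six pairwise filter banks; each trial
is projected through every bank and summarized by Q = 2*alpha normalized
log-variance features, giving 6*Q (= 24 by default) dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import StratifiedKFold

from .montage import CLASS_ORDER, Dataset, Trial
from .wcca import DegenerateCovarianceError


class ZeroEnergyTrialError(ValueError):
    """A trial with no signal energy has no normalized covariance."""


class IncompleteTrainingSetError(ValueError):
    """A class required for the pairwise banks has no training trials."""


class DegenerateProjectionError(ValueError):
    """A projected component has zero variance; log-feature undefined."""


def pair_order(classes: tuple[str, ...] = CLASS_ORDER) -> list[tuple[str, str]]:
    """The fixed unordered-pair order: combinations in canonical class order."""
    return list(combinations(classes, 2))


@dataclass(frozen=True)
class RCSPConfig:
    """R-CSP hyperparameters.

    beta : shrinkage toward the generic (other-subjects) covariance, [0, 1].
    gamma : shrinkage toward a scaled identity, [0, 1].
    alpha : retained filter columns per end of the eigenvalue spectrum;
        each pairwise bank keeps Q = 2*alpha filters.
    """

    beta: float = 0.0
    gamma: float = 0.0
    alpha: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0 and 0.0 <= self.gamma <= 1.0):
            raise ValueError("beta and gamma must lie in [0, 1]")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")


@dataclass
class ClassCovarianceSummary:
    """Sufficient statistics for one class's regularized covariance.

    S_sum is the sum of per-trial normalized covariances over the subject's
    own M training trials; S_hat_sum sums over the M_hat generic trials
    pooled from the other subjects. Each addend has unit trace, so
    trace(S_sum) = M.
    """

    label: str
    S_sum: np.ndarray
    M: int
    S_hat_sum: np.ndarray | None = None
    M_hat: int = 0

    def __post_init__(self) -> None:
        if self.S_hat_sum is None:
            self.S_hat_sum = np.zeros_like(self.S_sum)


@dataclass
class SpatialFilterBank:
    """Six pairwise N x Q projection matrices in the fixed pair order."""

    filters: dict[tuple[str, str], np.ndarray]
    config: RCSPConfig
    pairs: list[tuple[str, str]] = field(default_factory=pair_order)

    @property
    def n_features(self) -> int:
        return sum(w.shape[1] for w in self.filters.values())


# ---------------------------------------------------------------------------
# Covariance estimation
# ---------------------------------------------------------------------------


def normalized_covariance(e: np.ndarray) -> np.ndarray:
    """Trace-normalized sample covariance S = E E' / trace(E E') of a trial."""
    e = np.asarray(e, dtype=float)
    if e.ndim != 2 or e.shape[1] < 2:
        raise ValueError("trial must be an N x T matrix with T >= 2")
    c = e @ e.T
    tr = float(np.trace(c))
    if tr <= 0:
        raise ZeroEnergyTrialError("zero-energy trial has no normalized covariance")
    return c / tr


def regularized_covariance(
    summary: ClassCovarianceSummary, config: RCSPConfig
) -> np.ndarray:
    """Doubly regularized average spatial covariance for one class.

    First-level shrinkage mixes own and generic covariance sums,
    Sigma(beta) = ((1-beta) S_c + beta S_hat_c) / ((1-beta) M + beta M_hat);
    second-level shrinkage mixes toward a scaled identity preserving the
    trace, Sigma(beta, gamma) = (1-gamma) Sigma(beta)
    + (gamma / N) trace(Sigma(beta)) I.
    """
    beta, gamma = config.beta, config.gamma
    denom = (1.0 - beta) * summary.M + beta * summary.M_hat
    if denom <= 0:
        raise ValueError("degenerate covariance denominator: no effective trials")
    sigma_b = ((1.0 - beta) * summary.S_sum + beta * summary.S_hat_sum) / denom
    n = sigma_b.shape[0]
    sigma = (1.0 - gamma) * sigma_b + (gamma / n) * np.trace(sigma_b) * np.eye(n)
    return (sigma + sigma.T) / 2.0


# ---------------------------------------------------------------------------
# CSP filter construction
# ---------------------------------------------------------------------------


def _eigh_desc(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition, eigenvalues descending, deterministic
    eigenvector signs (largest-magnitude entry positive)."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w, v = w[::-1], v[:, ::-1]
    for i in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, i])))
        if v[j, i] < 0:
            v[:, i] = -v[:, i]
    return w, v


def csp_pair_filters(
    sigma1: np.ndarray,
    sigma2: np.ndarray,
    alpha: int = 2,
    return_details: bool = False,
):
    """Pairwise CSP filters from two class covariances.

    The composite Sigma = Sigma1 + Sigma2 is eigendecomposed (descending),
    whitened by P = Lambda^{-1/2} U', the whitened Sigma1 eigendecomposed
    (descending) into B Lambda1 B', and the full projection W0 = B' P formed.
    The first and last ``alpha`` rows of W0 — the filters at the extremes of
    the eigenvalue spectrum, where the two classes' variance ratio is most
    discriminative — are retained, returned as an N x Q matrix W so that
    Z = W' E has Q rows.
    """
    sigma1 = np.asarray(sigma1, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    n = sigma1.shape[0]
    if 2 * alpha > n:
        raise ValueError(f"2*alpha={2 * alpha} exceeds channel count {n}")
    lam, u = _eigh_desc(sigma1 + sigma2)
    if lam[-1] <= 0 or lam[-1] < lam[0] * 1e-12:
        raise DegenerateCovarianceError("degenerate covariance: composite not positive definite")
    p = (u / np.sqrt(lam)).T  # Lambda^{-1/2} U'
    s1t = p @ sigma1 @ p.T
    lam1, b = _eigh_desc(s1t)
    w0 = b.T @ p  # rows are spatial filters
    idx = list(range(alpha)) + list(range(n - alpha, n))
    w = w0[idx].T  # N x Q, columns are the retained filters
    if return_details:
        return w, {"P": p, "B": b, "lam_composite": lam, "lam1": lam1, "W0": w0}
    return w


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def features_from_covariance(c: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Log-variance features from a trial's channel covariance matrix.

    var(w' E) = w' Cov(E) w, so the 6*Q feature vector can be computed from
    the N x N channel covariance alone — the fast path used by the grid
    search, exactly equal to :func:`extract_features` on the raw trial.
    """
    blocks = []
    for pair in bank.pairs:
        w = bank.filters[pair]
        v = np.einsum("iq,ij,jq->q", w, c, w)
        total = v.sum()
        if np.any(v <= 0) or total <= 0:
            raise DegenerateProjectionError("degenerate projection: zero-variance component")
        blocks.append(np.log(v / total))
    return np.concatenate(blocks)


def extract_features(e: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Project a trial through all six banks; per bank the feature is
    y_q = log(var(z_q) / sum_q var(z_q)) over the Q projected rows."""
    e = np.asarray(e, dtype=float)
    first = next(iter(bank.filters.values()))
    if e.shape[0] != first.shape[0]:
        raise ValueError(f"trial has {e.shape[0]} rows; bank expects {first.shape[0]}")
    return features_from_covariance(np.cov(e), bank)


# ---------------------------------------------------------------------------
# Bank construction with generic learning
# ---------------------------------------------------------------------------


def _class_cov_sums(
    trials: list[Trial] | list[np.ndarray], labels: list[str] | None = None
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for i, t in enumerate(trials):
        if isinstance(t, Trial):
            lab, e = t.label, t.data
        else:
            lab, e = labels[i], t
        s = normalized_covariance(e)
        if lab in sums:
            sums[lab] += s
            counts[lab] += 1
        else:
            sums[lab] = s.copy()
            counts[lab] = 1
    return sums, counts


def build_summaries(
    own_trials: list[Trial],
    generic_trials: list[Trial] | None = None,
    classes: tuple[str, ...] = CLASS_ORDER,
) -> dict[str, ClassCovarianceSummary]:
    """Per-class covariance sufficient statistics from own + generic trials."""
    own_sums, own_counts = _class_cov_sums(own_trials)
    gen_sums, gen_counts = _class_cov_sums(generic_trials or [])
    missing = [c for c in classes if c not in own_sums]
    if missing:
        raise IncompleteTrainingSetError(f"incomplete training set: no trials for {missing}")
    out = {}
    for c in classes:
        out[c] = ClassCovarianceSummary(
            label=c,
            S_sum=own_sums[c],
            M=own_counts[c],
            S_hat_sum=gen_sums.get(c),
            M_hat=gen_counts.get(c, 0),
        )
    return out


def bank_from_summaries(
    summaries: dict[str, ClassCovarianceSummary],
    config: RCSPConfig,
    classes: tuple[str, ...] = CLASS_ORDER,
) -> SpatialFilterBank:
    """Build the pairwise filter bank from precomputed class summaries."""
    filters = {}
    for c1, c2 in pair_order(classes):
        s1 = regularized_covariance(summaries[c1], config)
        s2 = regularized_covariance(summaries[c2], config)
        filters[(c1, c2)] = csp_pair_filters(s1, s2, config.alpha)
    return SpatialFilterBank(filters=filters, config=config, pairs=pair_order(classes))


def build_filter_bank(
    own: Dataset,
    generic: list[Dataset] | None = None,
    config: RCSPConfig = RCSPConfig(),
) -> SpatialFilterBank:
    """One-vs-one R-CSP bank from a subject's training split.

    ``generic`` datasets contribute only their TRAINING trials to the pooled
    covariance sums (per class), never raw concatenated signals.
    """
    gen_trials: list[Trial] = []
    for d in generic or []:
        gen_trials.extend(d.train_trials)
    summaries = build_summaries(own.train_trials, gen_trials)
    return bank_from_summaries(summaries, config)


class RCSPTransformer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: trials in, 6*Q log-variance features out.

    ``fit`` expects ``X`` as an (n_trials, N, T) array (or list of N x T
    matrices) and ``y`` as class labels; pass the pooled other-subject
    training trials via ``generic_X`` / ``generic_y`` to enable generic
    learning. ``transform`` accepts trials of any length T.
    """

    def __init__(self, beta: float = 0.0, gamma: float = 0.0, alpha: int = 2):
        self.beta = beta
        self.gamma = gamma
        self.alpha = alpha

    def fit(self, X, y, generic_X=None, generic_y=None) -> "RCSPTransformer":
        config = RCSPConfig(beta=self.beta, gamma=self.gamma, alpha=self.alpha)
        own_sums, own_counts = _class_cov_sums(list(X), list(np.asarray(y, dtype=object)))
        gen_sums, gen_counts = _class_cov_sums(
            list(generic_X) if generic_X is not None else [],
            list(np.asarray(generic_y, dtype=object)) if generic_y is not None else None,
        )
        classes = tuple(sorted(own_counts, key=lambda c: (
            CLASS_ORDER.index(c) if c in CLASS_ORDER else len(CLASS_ORDER), c)))
        if len(classes) < 2:
            raise IncompleteTrainingSetError("need at least two classes")
        summaries = {
            c: ClassCovarianceSummary(
                label=c, S_sum=own_sums[c], M=own_counts[c],
                S_hat_sum=gen_sums.get(c), M_hat=gen_counts.get(c, 0),
            )
            for c in classes
        }
        self.bank_ = bank_from_summaries(summaries, config, classes)
        self.classes_ = classes
        self.n_features_ = self.bank_.n_features
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([extract_features(e, self.bank_) for e in X])


# ---------------------------------------------------------------------------
# beta/gamma grid search
# ---------------------------------------------------------------------------


def grid_search(
    train: Dataset,
    generic: list[Dataset] | None = None,
    grid_step: float = 0.1,
    evaluator=None,
    *,
    alpha: int = 2,
    mode: str = "cv",
    n_folds: int = 5,
    test: Dataset | None = None,
    classifier_factory=None,
    seed: int = 0,
) -> tuple[tuple[float, float], np.ndarray]:
    """Exhaustive accuracy grid over (beta, gamma) in [0, 1]^2.

    Every combination on the step-``grid_step`` lattice (121 cells at the
    default step 0.1) is scored and the argmax returned; ties break toward
    smaller beta, then smaller gamma.

    ``mode="cv"`` (default) scores each cell by stratified ``n_folds``-fold
    cross-validation within the subject's training split — no test leakage.
    ``mode="paper"`` scores on the provided held-out ``test`` split instead,
    reproducing selection on the evaluation set for comparability.

    ``evaluator(F_train, y_train, F_eval, y_eval) -> accuracy`` may override
    the default KNN-SVM protocol; ``classifier_factory`` swaps the default
    classifier while keeping the fit/score plumbing.
    """
    from .classify import KNNSVMClassifier  # local: avoid import cycle at module load

    betas = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 12)
    gammas = betas.copy()

    own_trials = train.train_trials
    y = np.array([t.label for t in own_trials], dtype=object)
    S = [normalized_covariance(t.data) for t in own_trials]
    C = np.stack([np.cov(t.data) for t in own_trials])
    gen_trials: list[Trial] = []
    for d in generic or []:
        gen_trials.extend(d.train_trials)
    gen_sums, gen_counts = _class_cov_sums(gen_trials)

    classes = tuple(c for c in CLASS_ORDER if c in set(y))

    if evaluator is None:
        if classifier_factory is None:
            classifier_factory = lambda: KNNSVMClassifier(k=5)

        def evaluator(f_tr, y_tr, f_ev, y_ev):
            clf = classifier_factory().fit(f_tr, y_tr)
            return float(np.mean(clf.predict(f_ev) == y_ev))

    if mode == "cv":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros(len(y)), y))
    elif mode == "paper":
        if test is None:
            raise ValueError('mode="paper" requires a held-out test dataset')
        folds = None
    else:
        raise ValueError(f"unknown grid-search mode {mode!r}")

    def summaries_for(idx: np.ndarray) -> dict[str, ClassCovarianceSummary]:
        sums: dict[str, ClassCovarianceSummary] = {}
        for c in classes:
            sel = [i for i in idx if y[i] == c]
            if not sel:
                raise IncompleteTrainingSetError(f"incomplete training set: no trials for {c}")
            s_sum = np.sum([S[i] for i in sel], axis=0)
            sums[c] = ClassCovarianceSummary(
                label=c, S_sum=s_sum, M=len(sel),
                S_hat_sum=gen_sums.get(c), M_hat=gen_counts.get(c, 0),
            )
        return sums

    if mode == "paper":
        eval_trials = test.test_trials or test.trials
        y_ev = np.array([t.label for t in eval_trials], dtype=object)
        C_ev = np.stack([np.cov(t.data) for t in eval_trials])
        all_idx = np.arange(len(y))
        cells = [(summaries_for(all_idx), C, y, C_ev, y_ev)]
    else:
        cells = []
        for tr_idx, va_idx in folds:
            cells.append((summaries_for(tr_idx), C[tr_idx], y[tr_idx], C[va_idx], y[va_idx]))

    matrix = np.zeros((len(betas), len(gammas)))
    for i, beta in enumerate(betas):
        for j, gamma in enumerate(gammas):
            config = RCSPConfig(beta=float(beta), gamma=float(gamma), alpha=alpha)
            accs = []
            try:
                for summaries, c_tr, y_tr, c_ev, y_ev in cells:
                    bank = bank_from_summaries(summaries, config, classes)
                    f_tr = np.vstack([features_from_covariance(c, bank) for c in c_tr])
                    f_ev = np.vstack([features_from_covariance(c, bank) for c in c_ev])
                    accs.append(evaluator(f_tr, y_tr, f_ev, y_ev))
                matrix[i, j] = float(np.mean(accs))
            except Exception as exc:  # noqa: BLE001 - a failed cell scores 0
                warnings.warn(f"grid cell (beta={beta}, gamma={gamma}) failed: {exc}")
                matrix[i, j] = 0.0
    best_flat = int(np.argmax(matrix))  # row-major: smaller beta, then gamma, wins ties
    bi, gj = np.unravel_index(best_flat, matrix.shape)
    return (float(betas[bi]), float(gammas[gj])), matrix


__all__ = [
    "RCSPConfig",
    "ClassCovarianceSummary",
    "SpatialFilterBank",
    "ZeroEnergyTrialError",
    "IncompleteTrainingSetError",
    "DegenerateProjectionError",
    "pair_order",
    "normalized_covariance",
    "regularized_covariance",
    "csp_pair_filters",
    "features_from_covariance",
    "extract_features",
    "build_summaries",
    "bank_from_summaries",
    "build_filter_bank",
    "RCSPTransformer",
    "grid_search",
]
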