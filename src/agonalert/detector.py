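"""RBF-SVM segment classifier, random-feature approximation and grouped CV.

The classifier is a support vector machine with a Gaussian kernel
``k(x, y) = exp(-gamma ||x - y||^2)`` and regularization ``C = 10``, scoring
each 256-dimensional segment embedding.  Probabilities come from Platt
scaling — a sigmoid ``P(y=1|f) = 1 / (1 + exp(A f + B))`` fitted on the
decision values of an inner held-out split.

For real-time scoring the kernel machine can be replaced by a linear model in
random Fourier features: by Bochner's theorem
``(2/D) sum_i cos(w_i.x + b_i) cos(w_i.y + b_i) -> exp(-gamma ||x-y||^2)``
as the number of Monte-Carlo features D grows, with error O(1/sqrt(D)).

Cross-validation is grouped by source recording: every augmented variant of a
source stays on one side of each fold's split, so no validation file appears
in the training set under any recording condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .features import (
    fit_featurizer_flat,
    flatten_logmels,
    project_flat,
)

DEFAULT_C = 10.0


@dataclass
class DetectorModel:
    """Fitted RBF-SVM with a Platt probability calibrator.

    ``svc`` holds support vectors, dual coefficients, gamma and bias; the
    training matrix is retained so :func:`approximate` can refit a linear
    model in random-feature space on the same data.
    """

    svc: SVC
    platt_a: float
    platt_b: float
    threshold: float = 0.5
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None

    @property
    def gamma(self) -> float:
        return float(self.svc._gamma)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(np.atleast_2d(X))

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_values(X)
        return 1.0 / (1.0 + np.exp(self.platt_a * f + self.platt_b))


@dataclass
class RFFModel:
    """Linear classifier in D random Fourier features approximating the RBF-SVM."""

    omega: np.ndarray  # D x n_features, rows ~ N(0, 2*gamma*I)
    phases: np.ndarray  # D, uniform on [0, 2*pi)
    linear_weights: np.ndarray  # D
    bias: float
    gamma: float
    seed: int

    @property
    def D(self) -> int:
        return len(self.phases)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.sqrt(2.0 / self.D) * np.cos(X @ self.omega.T + self.phases)

    def kernel_approx(self, x: np.ndarray, y: np.ndarray) -> float:
        """Monte-Carlo kernel estimate z(x).z(y) for a pair of points."""
        zx = self.transform(x)[0]
        zy = self.transform(y)[0]
        return float(zx @ zy)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.linear_weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_values(X) >= 0).astype(int)


def _fit_platt(decision_values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Platt scaling: logistic fit on 1-D decision values."""
    lr = LogisticRegression(C=1e4, max_iter=1000)
    lr.fit(decision_values.reshape(-1, 1), labels)
    # sklearn models P(1) = sigmoid(w f + c); Platt's form is 1/(1+exp(A f + B))
    return -float(lr.coef_[0, 0]), -float(lr.intercept_[0])


def train(
    embeddings: np.ndarray,
    labels: np.ndarray,
    C: float = DEFAULT_C,
    gamma="scale",
    seed: int = 0,
    calibration_fraction: float = 0.2,
) -> DetectorModel:
    """Train the RBF-SVM and calibrate probabilities on an inner split.

    The sigmoid is fitted on decision values of a held-out 20% of the
    training data (scored by an SVM trained on the other 80%), then the final
    SVM is refitted on all the data.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("embeddings must be a 2-D matrix")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training data must contain both classes (labels 0 and 1)")
    X_fit, X_cal, y_fit, y_cal = train_test_split(
        X, y, test_size=calibration_fraction, random_state=seed, stratify=y
    )
    inner = SVC(C=C, kernel="rbf", gamma=gamma)
    inner.fit(X_fit, y_fit)
    a, b = _fit_platt(inner.decision_function(X_cal), y_cal)
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(X, y)
    return DetectorModel(svc, a, b, train_X=X, train_y=y)


def predict(model: DetectorModel, embedding: np.ndarray,
            threshold: float | None = None) -> tuple[int, float]:
    """Classify one embedding; returns (label, agonal probability)."""
    x = np.asarray(embedding, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    n_expected = model.svc.support_vectors_.shape[1]
    if x.shape[1] != n_expected:
        raise ValueError(f"embedding has {x.shape[1]} dims, model expects {n_expected}")
    p = float(model.probabilities(x)[0])
    thr = model.threshold if threshold is None else threshold
    return int(p >= thr), p


def predict_stream(model: DetectorModel, embeddings: np.ndarray,
                   threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction; returns (labels, probabilities)."""
    p = model.probabilities(np.atleast_2d(embeddings))
    thr = model.threshold if threshold is None else threshold
    return (p >= thr).astype(int), p


def decision_kernel_expansion(model: DetectorModel, x: np.ndarray) -> float:
    """Brute-force decision value sum_i alpha_i k(x, sv_i) + b.

    Independent of sklearn's decision path; used to verify the fitted machine.
    """
    sv = model.svc.support_vectors_
    alpha = model.svc.dual_coef_[0]
    gamma = model.gamma
    k = np.exp(-gamma * np.sum((sv - x[None, :]) ** 2, axis=1))
    return float(alpha @ k + model.svc.intercept_[0])


def approximate(model: DetectorModel, D: int, seed: int = 0) -> RFFModel:
    """Replace the kernel machine by a linear model in D random Fourier features.

    ``omega`` rows are drawn N(0, 2*gamma*I) and phases uniform on [0, 2*pi);
    the linear weights are refitted on the retained training data in feature
    space (logistic loss), rather than mapped from the dual coefficients.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if model.train_X is None:
        raise ValueError("model was trained without retaining data; cannot refit")
    rng = np.random.default_rng(seed)
    n_features = model.train_X.shape[1]
    omega = rng.normal(0.0, np.sqrt(2.0 * model.gamma), size=(D, n_features))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=D)
    rff = RFFModel(omega, phases, np.zeros(D), 0.0, model.gamma, seed)
    Z = rff.transform(model.train_X)
    lr = LogisticRegression(C=1e3, max_iter=2000)
    lr.fit(Z, model.train_y)
    rff.linear_weights = lr.coef_[0]
    rff.bias = float(lr.intercept_[0])
    return rff


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of source recordings to k folds, grouped by source_id."""

    k: int
    fold_of_source: dict  # source_id -> fold index

    def validation_sources(self, fold: int) -> set:
        return {s for s, f in self.fold_of_source.items() if f == fold}

    def check_no_leakage(self, source_ids) -> None:
        for fold in range(self.k):
            val = self.validation_sources(fold)
            train = set(source_ids) - val
            if val & train:
                raise AssertionError(f"fold {fold}: leaked sources {val & train}")


def plan_folds(source_ids, labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Deal sources of each class round-robin into k folds (shuffled).

    Guarantees both classes appear in every fold's training set whenever each
    class has at least k sources.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list] = {}
    source_label = {}
    for s, y in zip(source_ids, labels):
        source_label.setdefault(s, int(y))
    for s, y in source_label.items():
        by_class.setdefault(y, []).append(s)
    fold_of = {}
    for y, sources in sorted(by_class.items()):
        if len(sources) < k:
            raise ValueError(
                f"class {y} has only {len(sources)} sources; need >= k = {k}"
            )
        order = list(sources)
        rng.shuffle(order)
        for i, s in enumerate(order):
            fold_of[s] = i % k
    return FoldPlan(k, fold_of)


@dataclass
class CVResult:
    fold_aucs: list
    mean_auc: float
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    sensitivity: float
    specificity: float
    threshold: float
    plan: FoldPlan = field(repr=False, default=None)


def crossvalidate(
    clips,
    k: int = 10,
    seed: int = 0,
    n_components: int = 256,
    C: float = DEFAULT_C,
    threshold: float | None = None,
) -> CVResult:
    """Grouped k-fold cross-validation of the full featurize-and-classify path.

    ``clips`` carry ``meta['source_id']`` and ``meta['label']``.  Within each
    fold the PCA featurizer is refitted on training clips only, the SVM
    trained on their embeddings, and the held-out fold scored.  Reports the
    per-fold AUC and pooled sensitivity/specificity at the operating point
    (default: the threshold maximizing Youden's J on the pooled scores of
    training-fold predictions is approximated by 0.5 unless given).
    """
    clips = list(clips)
    source_ids = [c.meta["source_id"] for c in clips]
    labels = np.array([c.meta["label"] for c in clips], dtype=int)
    plan = plan_folds(source_ids, labels, k=k, seed=seed)
    plan.check_no_leakage(source_ids)
    # the log-mel transform is deterministic preprocessing, computed once;
    # the trainable PCA basis and SVM are refit per fold on training rows only
    flats = flatten_logmels(clips)
    fold_aucs = []
    pooled_scores, pooled_labels = [], []
    for fold in range(k):
        val_sources = plan.validation_sources(fold)
        tr_idx = [i for i, s in enumerate(source_ids) if s not in val_sources]
        va_idx = [i for i, s in enumerate(source_ids) if s in val_sources]
        featurizer = fit_featurizer_flat(
            flats[tr_idx], n_components=n_components, seed=seed
        )
        X_tr = project_flat(flats[tr_idx], featurizer)
        X_va = project_flat(flats[va_idx], featurizer)
        model = train(X_tr, labels[tr_idx], C=C, seed=seed)
        _, probs = predict_stream(model, X_va)
        from .evaluate import roc_auc  # deferred: evaluate imports this module

        _, auc = roc_auc(probs, labels[va_idx])
        fold_aucs.append(auc)
        pooled_scores.append(probs)
        pooled_labels.append(labels[va_idx])
    scores = np.concatenate(pooled_scores)
    y = np.concatenate(pooled_labels)
    thr = 0.5 if threshold is None else threshold
    pred = scores >= thr
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = tp / max(1, int(np.sum(y == 1)))
    spec = tn / max(1, int(np.sum(y == 0)))
    return CVResult(fold_aucs, float(np.mean(fold_aucs)), scores, y, sens, spec,
                    thr, plan)
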