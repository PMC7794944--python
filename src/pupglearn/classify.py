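"""Weighted k-NN, baseline classifier roster, CV harness and metrics.

The headline classifier is distance-weighted k-nearest neighbours (KNN-W):
neighbours vote with weight 1/d^2, a query coinciding with a training
point takes that point's class, and exact vote ties fall back to the
single nearest neighbour.

``cross_validate`` evaluates a full configuration — rank fusion, top-k
selection and kernel PCA are refitted inside every training fold, so no
selection statistic ever sees test data — and pools the per-fold confusion
matrices into integer counts.  Hypertension is the positive class:
sensitivity = TP rate on hypertension, specificity = TN rate on normal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KernelDensity, KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from pupglearn import hfsr
from pupglearn.synth import ConfigurationError

__all__ = [
    "KNNWModel",
    "KNNWClassifier",
    "knnw_fit",
    "knnw_predict",
    "baseline_roster",
    "BASELINE_NAMES",
    "PipelineConfig",
    "EvalReport",
    "cross_validate",
    "permutation_control",
]

POSITIVE_LABEL = "hypertension"
NEGATIVE_LABEL = "normal"


# ---------------------------------------------------------------------------
# Weighted k-NN
# ---------------------------------------------------------------------------

@dataclass
class KNNWModel:
    """Stored (standardized) training set for distance-weighted voting."""

    X: np.ndarray
    y: np.ndarray
    k: int
    weight: str
    metric: str
    mean_: np.ndarray
    std_: np.ndarray


def knnw_fit(X, y, k: int = 10, weight: str = "inverse_distance_squared",
             metric: str = "euclidean") -> KNNWModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ConfigurationError("X must be (N, d) with matching labels")
    if not 1 <= k <= X.shape[0]:
        raise ConfigurationError(f"k={k} outside 1..{X.shape[0]}")
    if weight not in ("inverse_distance_squared", "inverse_distance", "uniform"):
        raise ConfigurationError(f"unknown weight scheme {weight!r}")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return KNNWModel((X - mean) / std, y, k, weight, metric, mean, std)


def knnw_predict(model: KNNWModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    Q = (X - model.mean_) / model.std_
    D = cdist(Q, model.X, metric=model.metric)
    classes = np.unique(model.y)
    out = np.empty(Q.shape[0], dtype=model.y.dtype)
    k = model.k
    for i in range(Q.shape[0]):
        d = D[i]
        nn_idx = np.argpartition(d, k - 1)[:k]
        nn_idx = nn_idx[np.argsort(d[nn_idx], kind="stable")]
        dn = d[nn_idx]
        if dn[0] == 0.0:
            # zero-distance neighbours have infinite weight and decide alone
            zero = nn_idx[dn == 0.0]
            labels, counts = np.unique(model.y[zero], return_counts=True)
            out[i] = labels[np.argmax(counts)]
            continue
        if model.weight == "uniform":
            w = np.ones_like(dn)
        elif model.weight == "inverse_distance":
            w = 1.0 / dn
        else:
            w = 1.0 / dn**2
        votes = np.array([w[model.y[nn_idx] == c].sum() for c in classes])
        top = np.flatnonzero(votes == votes.max())
        if top.size == 1:
            out[i] = classes[top[0]]
        else:  # tie -> class of the single nearest neighbour
            out[i] = model.y[nn_idx[0]]
    return out


class KNNWClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper around :func:`knnw_fit` / :func:`knnw_predict`."""

    def __init__(self, k: int = 10, weight: str = "inverse_distance_squared",
                 metric: str = "euclidean"):
        self.k = k
        self.weight = weight
        self.metric = metric

    def fit(self, X, y):
        k = min(self.k, np.asarray(X).shape[0])
        self.model_ = knnw_fit(X, y, k=k, weight=self.weight, metric=self.metric)
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return knnw_predict(self.model_, X)


# ---------------------------------------------------------------------------
# Baseline roster
# ---------------------------------------------------------------------------

class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian KDE class-conditionals."""

    def __init__(self, bandwidth: str | float = "scott"):
        self.bandwidth = bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.kdes_ = []
        self.priors_ = []
        for c in self.classes_:
            Xc = X[y == c]
            self.kdes_.append(
                [KernelDensity(bandwidth=self._bw(Xc[:, j])).fit(Xc[:, [j]])
                 for j in range(X.shape[1])]
            )
            self.priors_.append(len(Xc) / len(X))
        return self

    def _bw(self, col: np.ndarray) -> float:
        if isinstance(self.bandwidth, (int, float)):
            return float(self.bandwidth)
        s = col.std()
        return max(1.06 * s * len(col) ** -0.2, 1e-3)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        logp = np.zeros((X.shape[0], len(self.classes_)))
        for ci, kdes in enumerate(self.kdes_):
            logp[:, ci] = np.log(self.priors_[ci])
            for j, kde in enumerate(kdes):
                logp[:, ci] += kde.score_samples(X[:, [j]])
        return self.classes_[np.argmax(logp, axis=1)]


def _roster(seed: int | None = 0) -> dict:
    return {
        "SVM-L": SVC(kernel="linear", random_state=seed),
        "SVM-Q": SVC(kernel="poly", degree=2, random_state=seed),
        "SVM-C": SVC(kernel="poly", degree=3, random_state=seed),
        "SVM-FG": SVC(kernel="rbf", gamma=4.0, random_state=seed),
        "SVM-MG": SVC(kernel="rbf", gamma="scale", random_state=seed),
        "KNN-F": KNeighborsClassifier(n_neighbors=1),
        "KNN-M": KNeighborsClassifier(n_neighbors=10),
        "KNN-Cos": KNeighborsClassifier(n_neighbors=10, metric="cosine"),
        "KNN-C": KNeighborsClassifier(n_neighbors=10, p=3),
        "KNN-W": KNNWClassifier(),
        "DT": DecisionTreeClassifier(random_state=seed),
        "LD": LinearDiscriminantAnalysis(),
        "LR": LogisticRegression(max_iter=2000),
        "NBG": GaussianNB(),
        "NBK": KernelNaiveBayes(),
        "Eboost": AdaBoostClassifier(
            DecisionTreeClassifier(max_depth=2), n_estimators=30, random_state=seed
        ),
        "EBT": BaggingClassifier(
            DecisionTreeClassifier(), n_estimators=30, random_state=seed
        ),
        "ESD": BaggingClassifier(
            LinearDiscriminantAnalysis(), n_estimators=30, max_features=0.5,
            bootstrap=False, bootstrap_features=False, random_state=seed,
        ),
        "ESKNN": BaggingClassifier(
            KNeighborsClassifier(n_neighbors=5), n_estimators=30, max_features=0.5,
            bootstrap=False, random_state=seed,
        ),
    }


BASELINE_NAMES = tuple(_roster())


def baseline_roster(name: str, seed: int | None = 0):
    """Return an unfitted classifier for a roster code (e.g. ``"KNN-W"``)."""
    roster = _roster(seed)
    if name not in roster:
        raise ConfigurationError(
            f"unknown classifier {name!r}; known: {sorted(roster)}"
        )
    return roster[name]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """In-fold HFSR + classifier configuration for cross-validation."""

    k_top: int = 24
    n_components: int = 5
    kernel: str = "rbf"
    gamma: float | None = None
    classifier: str = "KNN-W"
    classifier_params: dict = field(default_factory=dict)
    rank_methods: tuple = hfsr.RANK_METHODS
    use_hfsr: bool = True

    def make_classifier(self, seed: int | None = 0):
        clf = baseline_roster(self.classifier, seed)
        if self.classifier_params:
            clf = clone(clf).set_params(**self.classifier_params)
        return clf


@dataclass
class EvalReport:
    """Pooled confusion matrix and derived metrics for one configuration."""

    tp: int
    fn: int
    fp: int
    tn: int
    fold_counts: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def error(self) -> float:
        return 1.0 - self.accuracy

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "error": self.error,
            "folds": self.fold_counts,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def csv_row(self) -> dict:
        """One row in the comparison-table layout (Classifier, Acc, Sp, Sen, Err)."""
        return {
            "Classifier": self.config.get("classifier", ""),
            "Acc": round(self.accuracy, 4),
            "Sp": round(self.specificity, 4),
            "Sen": round(self.sensitivity, 4),
            "Err": round(self.error, 4),
        }


def _confusion(y_true, y_pred, positive) -> tuple[int, int, int, int]:
    pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    return tp, fn, fp, tn


def _fit_predict_fold(X_tr, y_tr, X_te, config: PipelineConfig, seed):
    if config.use_hfsr:
        table = hfsr.rank_table(X_tr, y_tr, methods=config.rank_methods)
        sel = hfsr.select_top(table["MR"].to_numpy(), config.k_top)
        model = hfsr.kpca_fit(
            X_tr[:, sel], kernel=config.kernel, gamma=config.gamma,
            n_components=config.n_components,
        )
        Z_tr = hfsr.kpca_transform(model, X_tr[:, sel])
        Z_te = hfsr.kpca_transform(model, X_te[:, sel])
    else:
        Z_tr, Z_te = X_tr, X_te
    clf = config.make_classifier(seed)
    clf.fit(Z_tr, y_tr)
    return clf.predict(Z_te)


def cross_validate(features, labels, pipeline_config: PipelineConfig | None = None,
                   folds: int = 10, seed: int = 0,
                   holdout: float | None = None,
                   positive_label=POSITIVE_LABEL) -> EvalReport:
    """Stratified k-fold (or holdout) evaluation with in-fold HFSR.

    ``holdout``: if given (e.g. 0.20 or 0.25), a single stratified
    train/test split with that test fraction replaces the k folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    config = pipeline_config or PipelineConfig()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("cross_validate expects exactly two classes")
    if positive_label not in classes:
        positive_label = classes[0]

    splits = []
    if holdout is not None:
        tr, te = train_test_split(
            np.arange(len(y)), test_size=holdout, stratify=y, random_state=seed
        )
        splits.append((tr, te))
    else:
        if folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if counts.min() < folds:
            raise ConfigurationError(
                f"smallest class ({counts.min()}) below fold count {folds}"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))

    fold_counts = []
    tp = fn = fp = tn = 0
    for tr, te in splits:
        pred = _fit_predict_fold(X[tr], y[tr], X[te], config, seed)
        c = _confusion(y[te], pred, positive_label)
        fold_counts.append({"tp": c[0], "fn": c[1], "fp": c[2], "tn": c[3]})
        tp, fn, fp, tn = tp + c[0], fn + c[1], fp + c[2], tn + c[3]

    cfg = {
        "classifier": config.classifier,
        "k_top": config.k_top,
        "n_components": config.n_components,
        "kernel": config.kernel,
        "folds": folds if holdout is None else None,
        "holdout": holdout,
        "seed": seed,
        "positive_label": str(positive_label),
    }
    return EvalReport(tp, fn, fp, tn, fold_counts, cfg)


def permutation_control(features, labels, pipeline_config=None, folds: int = 10,
                        seed: int = 0, n_permutations: int = 5) -> float:
    """Mean pooled CV accuracy after permuting the labels.

    A leakage-free pipeline on balanced data should land near chance (0.5).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    accs = []
    for p in range(n_permutations):
        perm = rng.permutation(len(y))
        rep = cross_validate(
            features, y[perm], pipeline_config, folds=folds, seed=seed + p
        )
        accs.append(rep.accuracy)
    return float(np.mean(accs))
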