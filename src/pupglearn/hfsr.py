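"""Hybrid feature selection and reduction (HFSR).

Stage 1 — rank fusion: seven feature-ranking methods score every feature's
ability to separate the two classes; each method's scores become integer
ranks 1..F (best feature = F, mid-rank for ties); the per-feature **mean
rank (MR)** over the seven methods fuses them.  A feature praised by one
method but dismissed by the rest lands mid-table — the fusion's point.
The top-k features by MR (default k = 24) are kept.

Rankers: Welch t statistic (TT), symmetric Kullback-Leibler divergence of
per-class Gaussian fits (KLD), univariate Gaussian Bhattacharyya distance
(BD), |AUC - 1/2| (ROC), Mann-Whitney |z| (MWT), mRMR greedy
selection-order (MRMR, mutual information on 10 equal-frequency bins),
and ReliefF weights (RRF, k = 10 neighbours over all samples).

Stage 2 — kernel PCA on the selected block (z-scored with training
statistics): centred kernel matrix eigendecomposition; the leading 5-17
components feed the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import cdist
from sklearn.decomposition import KernelPCA
from sklearn.metrics import roc_auc_score

from pupglearn.synth import ConfigurationError

__all__ = [
    "RANK_METHODS",
    "score_features",
    "scores_to_ranks",
    "rank_table",
    "mean_rank",
    "select_top",
    "KPCAModel",
    "kpca_fit",
    "kpca_transform",
    "COMPONENT_PRESETS",
]

RANK_METHODS = ("TT", "KLD", "BD", "ROC", "MWT", "MRMR", "RRF")

#: component-count presets S1..S6
COMPONENT_PRESETS = {"S1": 5, "S2": 7, "S3": 10, "S4": 12, "S5": 15, "S6": 17}

_EPS_VAR = 1e-18


def _class_split(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    a, b = (X[y == c] for c in classes)
    if min(len(a), len(b)) < 3:
        raise ValueError("each class needs >= 3 samples")
    return a, b


def _gauss_moments(a, b):
    mu1, mu2 = a.mean(axis=0), b.mean(axis=0)
    v1 = np.maximum(a.var(axis=0, ddof=1), _EPS_VAR)
    v2 = np.maximum(b.var(axis=0, ddof=1), _EPS_VAR)
    return mu1, mu2, v1, v2


def _zero_variance_mask(X, y) -> np.ndarray:
    return X.var(axis=0) == 0


def score_features(X, y, method: str) -> np.ndarray:
    """Per-feature discriminability scores, higher = more separating.

    X: (N, F) matrix; y: length-N labels with exactly two classes.
    Zero-variance features score 0 (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    method = method.upper()
    a, b = _class_split(X, y)
    dead = _zero_variance_mask(X, y)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance feature(s) scored 0")

    if method == "TT":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = sstats.ttest_ind(a, b, axis=0, equal_var=False).statistic
        scores = np.abs(np.nan_to_num(t))
    elif method == "KLD":
        mu1, mu2, v1, v2 = _gauss_moments(a, b)
        scores = 0.5 * (v1 / v2 + v2 / v1 - 2.0) + 0.5 * (mu1 - mu2) ** 2 * (
            1.0 / v1 + 1.0 / v2
        )
    elif method == "BD":
        mu1, mu2, v1, v2 = _gauss_moments(a, b)
        scores = 0.25 * (mu1 - mu2) ** 2 / (v1 + v2) + 0.5 * np.log(
            (v1 + v2) / (2.0 * np.sqrt(v1 * v2))
        )
    elif method == "ROC":
        y01 = (y == np.unique(y)[1]).astype(int)
        scores = np.array(
            [abs(roc_auc_score(y01, X[:, j]) - 0.5) for j in range(X.shape[1])]
        )
    elif method == "MWT":
        scores = _mann_whitney_z(a, b)
    elif method == "MRMR":
        scores = _mrmr_scores(X, y)
    elif method == "RRF":
        scores = _relieff_weights(X, y)
    else:
        raise ConfigurationError(f"unknown ranking method {method!r}")

    scores = np.asarray(scores, dtype=float)
    scores[dead] = 0.0
    return scores


def _mann_whitney_z(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|z| of the Mann-Whitney U statistic (normal approximation, tie-corrected)."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    out = np.empty(a.shape[1])
    for j in range(a.shape[1]):
        combined = np.concatenate([a[:, j], b[:, j]])
        ranks = sstats.rankdata(combined)
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        _, counts = np.unique(combined, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        out[j] = abs(u - n1 * n2 / 2.0) / np.sqrt(var_u) if var_u > 0 else 0.0
    return out


def _equal_frequency_codes(X: np.ndarray, bins: int = 10) -> np.ndarray:
    """Per-feature equal-frequency bin indices in 0..bins-1."""
    codes = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        qs = np.quantile(X[:, j], np.linspace(0, 1, bins + 1)[1:-1])
        codes[:, j] = np.searchsorted(qs, X[:, j], side="right")
    return codes


def _mutual_information(ca: np.ndarray, cb: np.ndarray, na: int, nb: int) -> float:
    joint = np.bincount(ca * nb + cb, minlength=na * nb).astype(float)
    joint = joint.reshape(na, nb) / ca.size
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def _mrmr_scores(X: np.ndarray, y: np.ndarray, bins: int = 10) -> np.ndarray:
    """Greedy mRMR (MID: relevance minus mean redundancy) ordering as scores.

    The first-selected feature receives score F, the last 1.
    """
    n, F = X.shape
    codes = _equal_frequency_codes(X, bins)
    ycodes = (y == np.unique(y)[1]).astype(np.int64)
    relevance = np.array(
        [_mutual_information(codes[:, j], ycodes, bins, 2) for j in range(F)]
    )
    selected: list[int] = []
    remaining = set(range(F))
    red_sum = np.zeros(F)
    mi_cache: dict[tuple[int, int], float] = {}

    def mi(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in mi_cache:
            mi_cache[key] = _mutual_information(codes[:, i], codes[:, j], bins, bins)
        return mi_cache[key]

    scores = np.empty(F)
    order = 0
    while remaining:
        if not selected:
            crit = {j: relevance[j] for j in remaining}
        else:
            crit = {j: relevance[j] - red_sum[j] / len(selected) for j in remaining}
        best = max(sorted(crit), key=lambda j: crit[j])
        scores[best] = F - order
        order += 1
        remaining.discard(best)
        selected.append(best)
        for j in remaining:
            red_sum[j] += mi(best, j)
    return scores


def _relieff_weights(X: np.ndarray, y: np.ndarray, k: int = 10) -> np.ndarray:
    """ReliefF weights for two classes, k nearest hits/misses, all samples.

    Features are range-normalized; distances are Manhattan.
    """
    n, F = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Z = (X - X.min(axis=0)) / span
    D = cdist(Z, Z, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    W = np.zeros(F)
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    for i in range(n):
        same = y == y[i]
        same[i] = False
        kk_hit = min(k, int(same.sum()))
        kk_miss = min(k, int((~same).sum()) - 1)
        if kk_hit < 1 or kk_miss < 1:
            continue
        hit_idx = np.where(same)[0]
        hits = hit_idx[np.argpartition(D[i, hit_idx], kk_hit - 1)[:kk_hit]]
        other = classes[classes != y[i]][0]
        miss_mask = y == other
        miss_idx = np.where(miss_mask)[0]
        misses = miss_idx[np.argpartition(D[i, miss_idx], kk_miss - 1)[:kk_miss]]
        p_miss = priors[other] / (1.0 - priors[y[i]])
        W -= np.abs(Z[i] - Z[hits]).mean(axis=0) / n
        W += p_miss * np.abs(Z[i] - Z[misses]).mean(axis=0) / n
    return W


def scores_to_ranks(scores) -> np.ndarray:
    """Integer ranks 1..F, best feature = F; ties get the mean position
    rounded half-up."""
    scores = np.asarray(scores, dtype=float)
    ranks = sstats.rankdata(scores, method="average")
    return np.floor(ranks + 0.5).astype(int)


def rank_table(X, y, feature_names=None, methods=RANK_METHODS) -> pd.DataFrame:
    """Per-method integer ranks plus the fused mean-rank column ``MR``."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    table = pd.DataFrame(index=pd.Index(feature_names, name="Feature"))
    for m in methods:
        table[m] = scores_to_ranks(score_features(X, y, m))
    table["MR"] = mean_rank(table[list(methods)])
    return table


def mean_rank(ranks) -> np.ndarray:
    """Arithmetic mean of the per-method ranks, reported to 2 decimals.

    ``ranks``: (F, n_methods) array, DataFrame, or a single feature's rank
    sequence.
    """
    if isinstance(ranks, pd.DataFrame):
        ranks = ranks.to_numpy()
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim == 1:
        return float(np.round(ranks.mean(), 2))
    return np.round(ranks.mean(axis=1), 2)


def select_top(mr, k: int = 24, feature_names=None):
    """Indices (or names) of the k features with the largest mean rank.

    Ties are broken by registry order (earlier feature wins).
    """
    if isinstance(mr, pd.Series):
        if feature_names is None:
            feature_names = list(mr.index)
        mr = mr.to_numpy()
    mr = np.asarray(mr, dtype=float)
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    k = min(k, mr.size)
    order = np.argsort(-mr, kind="stable")[:k]
    if feature_names is not None:
        return [feature_names[i] for i in order]
    return order


# ---------------------------------------------------------------------------
# Kernel PCA
# ---------------------------------------------------------------------------

@dataclass
class KPCAModel:
    """Fitted KPCA: training standardization + centred-kernel eigenbasis."""

    kernel: str
    gamma: float | None
    degree: int
    n_components: int
    mean_: np.ndarray = field(repr=False, default=None)
    std_: np.ndarray = field(repr=False, default=None)
    _kpca: KernelPCA = field(repr=False, default=None)

    @property
    def eigenvalues(self) -> np.ndarray:
        return self._kpca.eigenvalues_

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_


def kpca_fit(X, kernel: str = "rbf", gamma: float | None = None,
             n_components: int = 5, degree: int = 3) -> KPCAModel:
    """Standardize ``X`` with its own statistics, then fit kernel PCA.

    Default kernel is Gaussian RBF with gamma = 1 / (d * mean feature
    variance) computed after standardization (i.e. 1/d).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("kpca_fit needs an (N>=2, d) matrix")
    if n_components < 1:
        raise ConfigurationError("n_components must be >= 1")
    if n_components > X.shape[0]:
        raise ConfigurationError(
            f"n_components={n_components} exceeds sample count {X.shape[0]}"
        )
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    if gamma is None and kernel == "rbf":
        gamma = 1.0 / (X.shape[1] * float(Xs.var(axis=0).mean()))
    kpca = KernelPCA(
        n_components=n_components, kernel=kernel, gamma=gamma, degree=degree
    )
    kpca.fit(Xs)
    return KPCAModel(
        kernel=kernel, gamma=gamma, degree=degree, n_components=n_components,
        mean_=mean, std_=std, _kpca=kpca,
    )


def kpca_transform(model: KPCAModel, X) -> np.ndarray:
    """Out-of-sample projection with the training standardization/centering."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty((0, model.n_components))
    return model._kpca.transform(model.standardize(X))
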