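"""Filter feature selection: information gain, gain ratio, chi-square, mRMR.

All four methods score each feature against the class label independently
of any classifier, after discretizing continuous features.  Scores use
base-2 logarithms throughout:

* IG(Y,X)  = H(Y) − H(Y|X)
* GR(Y,X)  = IG(Y,X) / H(X)   (0 when H(X) = 0)
* Chi2     = Σ (O−E)²/E over the feature-bin × class contingency table
* mRMR     = greedy forward selection maximising I(x;y) − mean I(x;s) over
  already-selected s (the MID criterion)

Discretization defaults: equal-frequency with 10 bins for IG/GR/Chi2;
3 states at mean ± one standard deviation for mRMR.  Both are common
defaults for these estimators and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

METHODS = ("IG", "GR", "Chi2", "mRMR")


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_column(x: np.ndarray, method: str = "equal_frequency",
                      bins: int = 10) -> np.ndarray:
    """Map a real-valued feature to integer bin codes.

    ``equal_frequency`` uses quantile edges, ``equal_width`` uniform edges,
    ``three_state`` thresholds at mean ± one standard deviation.
    """
    x = np.asarray(x, dtype=float)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if method == "three_state":
        mu, sd = x.mean(), x.std()
        return np.digitize(x, [mu - sd, mu + sd])
    if method == "equal_frequency":
        qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
        edges = np.unique(qs)
    elif method == "equal_width":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(len(x), dtype=int)
        edges = np.linspace(lo, hi, bins + 1)[1:-1]
    else:
        raise ValueError(f"unknown discretization method: {method!r}")
    return np.digitize(x, edges)


def discretize(X: np.ndarray, method: str = "equal_frequency",
               bins: int = 10) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([discretize_column(X[:, j], method, bins)
                            for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# Information measures (bits)
# ---------------------------------------------------------------------------

def entropy(p: np.ndarray) -> float:
    """Shannon entropy −Σ p log2 p of a distribution (0·log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("distribution must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _label_entropy(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    return entropy(counts / counts.sum())


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    table = np.zeros((len(xv), len(yv)))
    np.add.at(table, (xi, yi), 1)
    return table


def info_gain(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information H(Y) − H(Y|X) in bits, for categorical x."""
    x, y = np.asarray(x), np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(np.unique(y)) < 2:
        warnings.warn("single class present; information gain is 0")
        return 0.0
    table = _contingency(x, y)
    n = table.sum()
    hy = _label_entropy(y)
    h_cond = 0.0
    for row in table:
        nx = row.sum()
        if nx:
            h_cond += (nx / n) * entropy(row / nx)
    return max(hy - h_cond, 0.0)


def gain_ratio(x: np.ndarray, y: np.ndarray) -> float:
    """IG(Y,X) / H(X); 0 by convention when X is constant.

    1 marks a feature fully determining a balanced class, 0 an irrelevant
    one.
    """
    hx = _label_entropy(np.asarray(x))
    if hx == 0.0:
        return 0.0
    return info_gain(x, y) / hx


def chi2_score(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson chi-square statistic of the feature-bin × class table."""
    table = _contingency(np.asarray(x), np.asarray(y))
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = expected > 0
    return float((((table - expected) ** 2)[mask] / expected[mask]).sum())


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric MI in bits between two categorical variables."""
    return info_gain(np.asarray(a), np.asarray(b))


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass
class RankedFeatures:
    """Per-feature relevance scores and a best-first rank order."""

    method: str
    scores: np.ndarray
    order: np.ndarray

    def top(self, n: int) -> np.ndarray:
        if n <= 0:
            raise ValueError("n must be positive")
        return self.order[:n]


def _rank_by_score(scores: np.ndarray, method: str) -> RankedFeatures:
    # stable argsort on -score => ties broken by ascending feature index
    order = np.argsort(-scores, kind="stable")
    return RankedFeatures(method, scores, order)


def mrmr_rank(Xd: np.ndarray, y: np.ndarray, k: int | None = None) -> RankedFeatures:
    """Greedy mRMR (MID): maximise I(x;y) − mean I(x; selected).

    ``Xd`` must already be discretized.  Returns the selection order and,
    as scores, each feature's criterion value at the step it was picked
    (ties broken by ascending index).  Features beyond ``k`` keep order by
    plain relevance.
    """
    Xd = np.asarray(Xd)
    n_feat = Xd.shape[1]
    if k is None:
        k = n_feat
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n_feat:
        raise ValueError("k exceeds feature count")
    relevance = np.array([mutual_information(Xd[:, j], y)
                          for j in range(n_feat)])
    selected: list[int] = []
    scores = np.full(n_feat, -np.inf)
    redundancy = np.zeros(n_feat)
    remaining = list(range(n_feat))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MI of constant columns
        for step in range(k):
            if step == 0:
                crit = relevance.copy()
            else:
                last = selected[-1]
                for j in remaining:
                    redundancy[j] += mutual_information(Xd[:, j], Xd[:, last])
                crit = relevance - redundancy / step
            best = min(remaining, key=lambda j: (-crit[j], j))
            scores[best] = crit[best]
            selected.append(best)
            remaining.remove(best)
    tail = sorted(remaining, key=lambda j: (-relevance[j], j))
    order = np.array(selected + tail)
    scores[order[k:]] = relevance[order[k:]]
    return RankedFeatures("mRMR", scores, order)


def rank_features(X: np.ndarray, y: np.ndarray, method: str = "GR", *,
                  bins: int = 10, discretization: str = "equal_frequency",
                  k: int | None = None) -> RankedFeatures:
    """Score and rank every column of ``X`` against ``y`` by one method."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if method == "mRMR":
        Xd = discretize(X, "three_state", bins=3)
        return mrmr_rank(Xd, y, k)
    Xd = discretize(X, discretization, bins)
    fn = {"IG": info_gain, "GR": gain_ratio, "Chi2": chi2_score}.get(method)
    if fn is None:
        raise ValueError(f"unknown selection method: {method!r}")
    scores = np.array([fn(Xd[:, j], y) for j in range(X.shape[1])])
    return _rank_by_score(scores, method)


def select_top(ranked: RankedFeatures, X: np.ndarray, n: int) -> np.ndarray:
    """Column-subset of ``X`` holding the n top-ranked features, rank order."""
    X = np.asarray(X)
    if n > X.shape[1]:
        raise ValueError("n exceeds feature count")
    return X[:, ranked.top(n)]


class FilterFeatureSelector(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping the four filter rankers.

    Fitting computes ``scores_``, ``ranking_`` (best-first feature indices)
    and ``support_``; ``transform`` keeps the ``n_features`` top-ranked
    columns in rank order.
    """

    def __init__(self, method: str = "GR", n_features: int = 10,
                 bins: int = 10, discretization: str = "equal_frequency"):
        self.method = method
        self.n_features = n_features
        self.bins = bins
        self.discretization = discretization

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.n_features > X.shape[1]:
            raise ValueError("n_features exceeds feature count")
        ranked = rank_features(X, y, self.method, bins=self.bins,
                               discretization=self.discretization,
                               k=min(self.n_features, X.shape[1])
                               if self.method == "mRMR" else None)
        self.scores_ = ranked.scores
        self.ranking_ = ranked.order
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[ranked.top(self.n_features)] = True
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.ranking_[:self.n_features]]

    def get_support(self) -> np.ndarray:
        return self.support_
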