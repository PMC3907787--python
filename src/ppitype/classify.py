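"""Classifiers: linear dimensionality reduction (FDA/HDA/CDA) with a Bayes
rule in the reduced space, Gaussian naive Bayes, k-nearest neighbours, and
an SVM adapter.

The LDR family learns a linear map A (d×D, d=1 by default for the
two-class problem) and classifies in the reduced space z = Ax with a
Gaussian Bayes rule (linear = pooled covariance, quadratic = per-class):

* **FDA** — Fisher's homoscedastic criterion: A spans the top eigenvectors
  of S_W⁻¹ S_B; for two classes the single direction is S_W⁻¹(m₁−m₂).
* **HDA** — the Loog–Duin heteroscedastic (Chernoff) extension of Fisher's
  criterion.  With W = S_W, π_k class priors, m̂ = W^{-1/2}(m₁−m₂) and
  Ŝ_k = W^{-1/2} S_k W^{-1/2}, A spans the top eigenvectors of

      W^{-1/2} [ m̂ m̂ᵀ − (1/(π₁π₂)) (π₁ log Ŝ₁ + π₂ log Ŝ₂) ] W^{-1/2}.

  When S₁ = S₂ the log terms vanish and the criterion reduces to FDA.
* **CDA** — direct maximisation of the two-Gaussian Chernoff distance in
  the transformed space,

      J(A) = [β(1−β)/2]·(Am)ᵀ(A S̄ Aᵀ)⁻¹(Am)
             + ½ log( |A S̄ Aᵀ| / (|A S₁ Aᵀ|^β |A S₂ Aᵀ|^{1−β}) ),

  with m = m₁−m₂, S̄ = βS₁+(1−β)S₂ and β the prior of class 1, by
  backtracking gradient ascent from the FDA solution (so J never falls
  below Fisher's).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

LDR_CRITERIA = ("fda", "hda", "cda")
BAYES_RULES = ("linear", "quadratic")

_COND_LIMIT = 1e10
_warned_ridge = False


def _regularize(S: np.ndarray) -> np.ndarray:
    """Ridge-stabilise a covariance whose conditioning exceeds 1e10."""
    global _warned_ridge
    S = np.asarray(S, dtype=float)
    D = S.shape[0]
    eig = np.linalg.eigvalsh(S)
    lo, hi = eig[0], eig[-1]
    if lo <= 0 or (hi / max(lo, 1e-300)) > _COND_LIMIT:
        lam = 1e-6 * np.trace(S) / D
        lam = max(lam, 1e-12)
        if not _warned_ridge:
            warnings.warn("ill-conditioned covariance; adding ridge")
            _warned_ridge = True
        return S + lam * np.eye(D)
    return S


@dataclass
class GaussianClassStats:
    """Sample priors, means and covariances of a two-class dataset."""

    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray           # (2, D)
    covs: np.ndarray            # (2, D, D)

    @property
    def S_W(self) -> np.ndarray:
        """Prior-weighted pooled within-class covariance."""
        return np.einsum("k,kij->ij", self.priors, self.covs)

    @property
    def S_B(self) -> np.ndarray:
        m = self.means[0] - self.means[1]
        return np.outer(m, m)

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray) -> "GaussianClassStats":
        X = np.asarray(X, dtype=float)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("two classes required")
        priors, means, covs = [], [], []
        for c in classes:
            Xc = X[y == c]
            priors.append(len(Xc) / len(X))
            means.append(Xc.mean(axis=0))
            covs.append(np.atleast_2d(np.cov(Xc, rowvar=False, bias=True))
                        if len(Xc) > 1 else np.zeros((X.shape[1],) * 2))
        return cls(classes, np.array(priors), np.array(means), np.array(covs))


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 1e-12, None)
    return (vecs / np.sqrt(vals)) @ vecs.T


def _sym_logm(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 1e-12, None)
    return (vecs * np.log(vals)) @ vecs.T


def _top_eigvecs(M: np.ndarray, d: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh((M + M.T) / 2)
    return vecs[:, np.argsort(vals)[::-1][:d]].T


def fda_transform(stats: GaussianClassStats, d: int) -> np.ndarray:
    """Rows = top-d eigenvectors of S_W⁻¹ S_B."""
    Sw = _regularize(stats.S_W)
    # generalized symmetric eigenproblem via whitening
    Wih = _inv_sqrt(Sw)
    A = _top_eigvecs(Wih @ stats.S_B @ Wih, d) @ Wih
    return _orthonormalize(A)


def hda_transform(stats: GaussianClassStats, d: int) -> np.ndarray:
    """Top-d eigenvectors of the two-class Chernoff criterion matrix."""
    Sw = _regularize(stats.S_W)
    Wih = _inv_sqrt(Sw)
    p1, p2 = stats.priors
    m_hat = Wih @ (stats.means[0] - stats.means[1])
    S1h = Wih @ stats.covs[0] @ Wih
    S2h = Wih @ stats.covs[1] @ Wih
    inner = np.outer(m_hat, m_hat) - (p1 * _sym_logm(S1h)
                                      + p2 * _sym_logm(S2h)) / (p1 * p2)
    # `inner` lives in whitened coordinates; map eigenvectors back with Wih
    A = _top_eigvecs(inner, d) @ Wih
    return _orthonormalize(A)


def _orthonormalize(A: np.ndarray) -> np.ndarray:
    # row space is what matters; QR keeps it while bounding conditioning
    Q, _ = np.linalg.qr(A.T)
    return Q.T


def chernoff_objective(A: np.ndarray, stats: GaussianClassStats) -> float:
    """Transformed-space Chernoff distance J(A) (see module docstring)."""
    A = np.atleast_2d(A)
    beta = float(stats.priors[0])
    m = stats.means[0] - stats.means[1]
    S1, S2 = stats.covs
    Sbar = beta * S1 + (1 - beta) * S2
    ASA = A @ Sbar @ A.T
    try:
        sol = np.linalg.solve(ASA, A @ m)
    except np.linalg.LinAlgError:
        return -np.inf
    term1 = 0.5 * beta * (1 - beta) * float((A @ m) @ sol)
    s, ld_bar = np.linalg.slogdet(ASA)
    s1, ld1 = np.linalg.slogdet(A @ S1 @ A.T)
    s2, ld2 = np.linalg.slogdet(A @ S2 @ A.T)
    if s <= 0 or s1 <= 0 or s2 <= 0:
        return -np.inf
    term2 = 0.5 * (ld_bar - beta * ld1 - (1 - beta) * ld2)
    return term1 + term2


def cda_transform(stats: GaussianClassStats, d: int, *, max_iter: int = 500,
                  tol: float = 1e-8, fd_step: float = 1e-6
                  ) -> tuple[np.ndarray, list[float]]:
    """Maximise the Chernoff objective by backtracking gradient ascent.

    Initialised at the FDA solution; the step is halved until J increases,
    so the recorded objective path is non-decreasing and the final J is
    >= J(A_FDA).  Returns (A, objective path).
    """
    A = fda_transform(stats, d)
    shape = A.shape
    path = [chernoff_objective(A, stats)]

    def J(flat: np.ndarray) -> float:
        return chernoff_objective(flat.reshape(shape), stats)

    x = A.ravel().copy()
    step = 1.0
    for _ in range(max_iter):
        grad = np.empty_like(x)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = fd_step
            grad[i] = (J(x + e) - J(x - e)) / (2 * fd_step)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            break
        improved = False
        trial_step = step
        for _ in range(40):
            x_new = x + trial_step * grad / gnorm
            j_new = J(x_new)
            if j_new > path[-1]:
                improved = True
                break
            trial_step /= 2
        if not improved:
            break
        x = _orthonormalize(x_new.reshape(shape)).ravel()
        j_val = J(x)
        # re-orthonormalization preserves the row space, hence J
        path.append(max(j_val, path[-1]))
        step = min(trial_step * 2, 1.0)
        if path[-1] - path[-2] < tol:
            break
    else:
        warnings.warn("CDA gradient ascent hit the iteration cap")
    return x.reshape(shape), path


class LDRClassifier(ClassifierMixin, BaseEstimator):
    """Linear dimensionality reduction + Gaussian Bayes classifier.

    Parameters
    ----------
    criterion : 'fda', 'hda' or 'cda'.
    bayes : 'linear' (pooled covariance) or 'quadratic' (per-class).
    n_components : reduced dimension d (default 1 for two classes).
    """

    def __init__(self, criterion: str = "fda", bayes: str = "quadratic",
                 n_components: int = 1, max_iter: int = 500,
                 tol: float = 1e-8):
        self.criterion = criterion
        self.bayes = bayes
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.criterion not in LDR_CRITERIA:
            raise ValueError(f"unknown criterion: {self.criterion!r}")
        if self.bayes not in BAYES_RULES:
            raise ValueError(f"unknown bayes rule: {self.bayes!r}")
        stats = GaussianClassStats.fit(X, y)
        d = self.n_components
        if d > X.shape[1]:
            raise ValueError("n_components exceeds feature count")
        if self.criterion == "fda":
            A = fda_transform(stats, d)
        elif self.criterion == "hda":
            A = hda_transform(stats, d)
        else:
            A, self.objective_path_ = cda_transform(
                stats, d, max_iter=self.max_iter, tol=self.tol)
        self.transform_ = A
        self.classes_ = stats.classes
        Z = X @ A.T
        zstats = GaussianClassStats.fit(Z, y)
        self.priors_ = zstats.priors
        self.means_ = zstats.means
        self.covs_ = np.array([_regularize(S) for S in zstats.covs])
        self.pooled_cov_ = _regularize(zstats.S_W)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "transform_")
        return np.asarray(X, dtype=float) @ self.transform_.T

    def _log_posteriors(self, X) -> np.ndarray:
        Z = self.transform(X)
        out = np.empty((len(Z), 2))
        for k in range(2):
            S = self.covs_[k] if self.bayes == "quadratic" else self.pooled_cov_
            sign, logdet = np.linalg.slogdet(S)
            diff = Z - self.means_[k]
            maha = np.einsum("ij,ij->i", diff @ np.linalg.inv(S), diff)
            out[:, k] = np.log(self.priors_[k]) - 0.5 * logdet - 0.5 * maha
        return out

    def decision_function(self, X) -> np.ndarray:
        """Log posterior odds of the positive (last) class."""
        lp = self._log_posteriors(X)
        return lp[:, 1] - lp[:, 0]

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._log_posteriors(X), axis=1)]


class GaussianNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes with per-feature univariate Gaussian likelihoods.

    A variance floor (``var_smoothing`` times the largest feature variance)
    keeps degenerate features finite.
    """

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        eps = self.var_smoothing * max(X.var(axis=0).max(), 1e-12)
        self.theta_, self.var_, self.priors_ = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) == 0:
                raise ValueError(f"class {c!r} has no training samples")
            self.theta_.append(Xc.mean(axis=0))
            self.var_.append(Xc.var(axis=0) + eps)
            self.priors_.append(len(Xc) / len(X))
        self.theta_ = np.array(self.theta_)
        self.var_ = np.array(self.var_)
        self.priors_ = np.array(self.priors_)
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        jll = np.empty((len(X), len(self.classes_)))
        for k in range(len(self.classes_)):
            ll = -0.5 * (np.log(2 * np.pi * self.var_[k])
                         + (X - self.theta_[k]) ** 2 / self.var_[k])
            jll[:, k] = np.log(self.priors_[k]) + ll.sum(axis=1)
        return jll

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "theta_")
        jll = self._joint_log_likelihood(X)
        return jll[:, -1] - jll[:, 0]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "theta_")
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


class KNearestNeighbors(ClassifierMixin, BaseEstimator):
    """Euclidean k-NN majority vote; a vote tie falls back to the label of
    the single nearest neighbour.  k defaults to 1."""

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.k > len(X):
            raise ValueError("k exceeds training size")
        self.X_, self.y_ = X, y
        self.classes_ = np.unique(y)
        return self

    def _neighbor_labels(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        D = cdist(np.asarray(X, dtype=float), self.X_)
        order = np.argsort(D, axis=1, kind="stable")[:, :self.k]
        return self.y_[order]

    def predict(self, X) -> np.ndarray:
        nb = self._neighbor_labels(X)
        out = []
        for row in nb:
            vals, counts = np.unique(row, return_counts=True)
            winners = vals[counts == counts.max()]
            out.append(winners[0] if len(winners) == 1 else row[0])
        return np.array(out)

    def decision_function(self, X) -> np.ndarray:
        """Vote fraction for the positive (last) class, minus 1/2."""
        nb = self._neighbor_labels(X)
        pos = self.classes_[-1]
        return (nb == pos).mean(axis=1) - 0.5


class SVMClassifier(ClassifierMixin, BaseEstimator):
    """Thin adapter over sklearn's SVC with a polynomial kernel (library
    defaults), provided as a baseline; not re-implemented here."""

    def __init__(self, kernel: str = "poly"):
        self.kernel = kernel

    def fit(self, X, y):
        from sklearn.svm import SVC

        self._svc = SVC(kernel=self.kernel).fit(X, y)
        self.classes_ = self._svc.classes_
        return self

    def predict(self, X):
        return self._svc.predict(X)

    def decision_function(self, X):
        return self._svc.decision_function(X)


def make_classifier(spec: str) -> BaseEstimator:
    """Build a classifier from a compact spec string.

    ``'ldr-fda-quadratic'``, ``'ldr-cda-linear'``, ``'nb'``, ``'knn'``,
    ``'knn-5'``, ``'svm'``.
    """
    parts = spec.lower().split("-")
    if parts[0] == "ldr":
        crit = parts[1] if len(parts) > 1 else "fda"
        bayes = parts[2] if len(parts) > 2 else "quadratic"
        bayes = {"q": "quadratic", "l": "linear"}.get(bayes, bayes)
        return LDRClassifier(criterion=crit, bayes=bayes)
    if parts[0] == "nb":
        return GaussianNaiveBayes()
    if parts[0] == "knn":
        k = int(parts[1]) if len(parts) > 1 else 1
        return KNearestNeighbors(k=k)
    if parts[0] == "svm":
        return SVMClassifier()
    raise ValueError(f"unknown classifier spec: {spec!r}")


LDR_VARIANTS = tuple(f"ldr-{c}-{b}" for c in LDR_CRITERIA for b in BAYES_RULES)
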