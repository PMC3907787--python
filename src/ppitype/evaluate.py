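"""Evaluation: stratified k-fold CV with pooled accuracy, ROC/AUC, and the
cutoff / top-k-selection sweep experiments.

Accuracy is pooled over folds, acc = (TP + TN) / N, with the obligate
class counted positive.  Standardization and feature selection, when
enabled, are fitted on each training fold only (a "full-dataset" ranking
mode exists for comparison with protocols that rank once up front).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .classify import LDR_VARIANTS, make_classifier
from .features import FeatureMatrix, build_matrix
from .selection import FilterFeatureSelector, RankedFeatures, rank_features
from .structure import Complex

POSITIVE_LABEL = "obligate"


def _positive_class(classes: np.ndarray):
    return POSITIVE_LABEL if POSITIVE_LABEL in classes else classes[-1]


@dataclass
class CVResult:
    """Pooled confusion counters and per-sample scores from one CV run."""

    folds: int
    tp: int
    tn: int
    fp: int
    fn: int
    scores: np.ndarray
    y_true: np.ndarray
    seed: int
    positive: object = POSITIVE_LABEL
    fold_counts: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def cross_validate(X: np.ndarray, y: np.ndarray, classifier, *,
                   folds: int = 10, seed: int = 0, standardize: bool = True,
                   selection: str | None = None, n_features: int | None = None,
                   selection_mode: str = "fold") -> CVResult:
    """Stratified k-fold CV with per-fold preprocessing.

    ``classifier`` is an estimator instance or a spec string accepted by
    :func:`ppitype.classify.make_classifier`.  With ``selection`` set, the
    ranker runs inside each training fold (``selection_mode='fold'``) or
    once on the full data (``'full'``, leaky by design, for comparison).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if isinstance(classifier, str):
        classifier = make_classifier(classifier)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` samples")
    pos = _positive_class(classes)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    tp = tn = fp = fn = 0
    fold_counts = []
    full_ranked: RankedFeatures | None = None
    if selection is not None and selection_mode == "full":
        full_ranked = rank_features(X, y, selection, k=n_features
                                    if selection == "mRMR" else None)
    for train, test in skf.split(X, y):
        Xtr, Xte = X[train], X[test]
        if selection is not None:
            if full_ranked is not None:
                cols = full_ranked.top(n_features)
            else:
                sel = FilterFeatureSelector(selection, n_features).fit(
                    Xtr, y[train])
                cols = sel.ranking_[:n_features]
            Xtr, Xte = Xtr[:, cols], Xte[:, cols]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        est = clone(classifier).fit(Xtr, y[train])
        pred = est.predict(Xte)
        if hasattr(est, "decision_function"):
            sc = np.asarray(est.decision_function(Xte), dtype=float)
            if est.classes_[-1] != pos:  # orient scores toward the positive
                sc = -sc
        else:
            sc = (pred == pos).astype(float)
        scores[test] = sc
        yt = y[test]
        ftp = int(np.sum((pred == pos) & (yt == pos)))
        ftn = int(np.sum((pred != pos) & (yt != pos)))
        ffp = int(np.sum((pred == pos) & (yt != pos)))
        ffn = int(np.sum((pred != pos) & (yt == pos)))
        tp, tn, fp, fn = tp + ftp, tn + ftn, fp + ffp, fn + ffn
        fold_counts.append((ftp, ftn, ffp, ffn))
    return CVResult(folds, tp, tn, fp, fn, scores, y.copy(), seed, pos,
                    fold_counts)


@dataclass
class RocCurve:
    """TPR/FPR arrays over a descending threshold sweep, AUC by trapezoid."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            positive=None) -> RocCurve:
    """ROC curve and AUC from per-sample scores.

    Thresholds sweep the unique score values from high to low; tied scores
    move as one group, so the curve is the standard step/diagonal path and
    the trapezoidal AUC equals the Mann–Whitney U normalisation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("ROC needs both classes present")
    pos = positive if positive is not None else _positive_class(classes)
    is_pos = labels == pos
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = is_pos[order]
    # group boundaries where the score changes
    distinct = np.where(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, len(sorted_scores) - 1]
    tps = np.cumsum(sorted_pos)[idx]
    fps = np.cumsum(~sorted_pos)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(sorted_scores[idx], tpr, fpr, auc)


def cv_table(results: dict[str, CVResult]) -> pd.DataFrame:
    rows = [{"classifier": name, "accuracy": r.accuracy, "tp": r.tp,
             "tn": r.tn, "fp": r.fp, "fn": r.fn, "n": r.n, "seed": r.seed}
            for name, r in results.items()]
    return pd.DataFrame(rows)


def ldr_max_accuracy(X: np.ndarray, y: np.ndarray, *, folds: int = 10,
                     seed: int = 0, **kw) -> tuple[str, CVResult]:
    """Best of the six LDR variants (3 criteria x 2 Bayes rules).

    Reported as the maximum over variants, the convention used when a
    single LDR number summarises the family.
    """
    best_name, best = None, None
    for spec in LDR_VARIANTS:
        res = cross_validate(X, y, spec, folds=folds, seed=seed, **kw)
        if best is None or res.accuracy > best.accuracy:
            best_name, best = spec, res
    return best_name, best


def cutoff_sweep(complexes: list[Complex], cutoffs, classifier="nb", *,
                 feature_kind: str = "AT",
                 energy_kind: str = "electrostatic", folds: int = 10,
                 seed: int = 0, dielectric: str | float = 1.0,
                 ldr_max: bool = False) -> pd.DataFrame:
    """Recompute contacts, features and CV accuracy per distance cutoff.

    Returns one row per cutoff with the pooled accuracy and the mean
    per-complex contact count (monotone in the cutoff).
    """
    from .interface import find_contacts

    rows = []
    for cutoff in cutoffs:
        fm = build_matrix(complexes, feature_kind=feature_kind,
                          energy_kind=energy_kind, cutoff=cutoff,
                          dielectric=dielectric)
        if ldr_max:
            name, res = ldr_max_accuracy(fm.X, fm.labels, folds=folds,
                                         seed=seed)
        else:
            name = classifier if isinstance(classifier, str) else type(
                classifier).__name__
            res = cross_validate(fm.X, fm.labels, classifier, folds=folds,
                                 seed=seed)
        mean_contacts = float(np.mean(
            [len(find_contacts(c, cutoff)) for c in complexes]))
        rows.append({"cutoff": cutoff, "accuracy": res.accuracy,
                     "classifier": name, "mean_contacts": mean_contacts})
    return pd.DataFrame(rows)


def selection_sweep(fm: FeatureMatrix | None, method: str, ns, classifier,
                    *, X=None, y=None, folds: int = 10, seed: int = 0,
                    selection_mode: str = "fold") -> pd.DataFrame:
    """CV accuracy for top-n feature subsets plus a no-selection baseline.

    The baseline row (n = all features, method 'none') comes first; the
    remaining rows follow ``ns`` in order.
    """
    if fm is not None:
        X, y = fm.X, fm.labels
    X = np.asarray(X, dtype=float)
    base = cross_validate(X, y, classifier, folds=folds, seed=seed)
    rows = [{"method": "none", "n": X.shape[1], "accuracy": base.accuracy}]
    for n in ns:
        res = cross_validate(X, y, classifier, folds=folds, seed=seed,
                             selection=method, n_features=int(n),
                             selection_mode=selection_mode)
        rows.append({"method": method, "n": int(n), "accuracy": res.accuracy})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_roc(curves: dict[str, RocCurve], path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in curves.items():
        ax.plot(c.fpr, c.tpr, label=f"{name} (AUC={c.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate (1 - specificity)")
    ax.set_ylabel("True positive rate (sensitivity)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep(df: pd.DataFrame, xcol: str, path: str,
               xlabel: str | None = None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(df[xcol], df["accuracy"], "o-")
    ax.set_xlabel(xlabel or xcol)
    ax.set_ylabel("Pooled CV accuracy")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
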