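"""Classifiers: FDA closed form, HDA/CDA oracles, Bayes rules, NB, k-NN."""

import numpy as np
import pytest
from scipy.stats import norm

from ppitype.classify import (GaussianClassStats, GaussianNaiveBayes,
                              KNearestNeighbors, LDRClassifier,
                              chernoff_objective, cda_transform,
                              fda_transform, hda_transform, make_classifier)
from ppitype.synthetic import GaussianDatasetSpec, make_gaussian_dataset


def _angle(u, v):
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    return float(np.arccos(min(1.0, abs(float(u @ v)))))


def _stats(m1, m2, S1, S2, p1=0.5):
    return GaussianClassStats(np.array([0, 1]), np.array([p1, 1 - p1]),
                              np.array([m1, m2], float),
                              np.array([S1, S2], float))


def test_fda_direction_closed_form_spherical():
    X, y = make_gaussian_dataset(GaussianDatasetSpec(
        n_per_class=1000, dim=3, mean1=[3, 1, 0], seed=0))
    st = GaussianClassStats.fit(X, y)
    a = fda_transform(st, 1)[0]
    d = np.linalg.solve(st.S_W, st.means[0] - st.means[1])
    assert _angle(a, d) < 1e-6


def test_fda_direction_closed_form_anisotropic():
    S = np.array([[4.0, 1.2, 0], [1.2, 1.0, 0.3], [0, 0.3, 2.0]])
    X, y = make_gaussian_dataset(GaussianDatasetSpec(
        n_per_class=2000, dim=3, mean1=[2, 0, 1], cov0=S, cov1=S, seed=1))
    st = GaussianClassStats.fit(X, y)
    a = fda_transform(st, 1)[0]
    d = np.linalg.solve(st.S_W, st.means[0] - st.means[1])
    assert _angle(a, d) < 1e-6


def test_rotation_equivariance_of_predictions():
    X, y = make_gaussian_dataset(GaussianDatasetSpec(
        n_per_class=300, dim=4, mean1=[2, 1, 0, 0], seed=2))
    rng = np.random.default_rng(0)
    Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    for crit in ("fda", "hda", "cda"):
        clf = LDRClassifier(crit, "quadratic").fit(X, y)
        clf_rot = LDRClassifier(crit, "quadratic").fit(X @ Q.T, y)
        np.testing.assert_array_equal(clf.predict(X),
                                      clf_rot.predict(X @ Q.T))


def test_hda_reduces_to_fda_when_homoscedastic():
    S = np.array([[2.0, 0.6], [0.6, 1.0]])
    st = _stats([0, 0], [2, 1], S, S)
    a_f = fda_transform(st, 1)[0]
    a_h = hda_transform(st, 1)[0]
    assert _angle(a_f, a_h) < 1e-8


def test_hda_discriminates_equal_mean_heteroscedastic_data():
    """Equal means, unequal variances: FDA has no signal, HDA+quadratic does."""
    spec = GaussianDatasetSpec(n_per_class=1000, dim=2,
                               cov1=np.diag([25.0, 25.0]), seed=3)
    X, y = make_gaussian_dataset(spec)
    from ppitype.evaluate import cross_validate
    res = cross_validate(X, y, LDRClassifier("hda", "quadratic"),
                         folds=5, seed=0, standardize=False)
    assert res.accuracy > 0.8


def test_chernoff_criterion_rotation_invariant():
    st = _stats([0, 0], [1, 2], np.diag([1.0, 2.0]), np.diag([3.0, 0.5]))
    A = np.array([[0.6, 0.8]])
    th = 0.7
    Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    st_rot = _stats(Q @ st.means[0], Q @ st.means[1],
                    Q @ st.covs[0] @ Q.T, Q @ st.covs[1] @ Q.T)
    assert chernoff_objective(A @ Q.T, st_rot) == pytest.approx(
        chernoff_objective(A, st), rel=1e-9)


def test_cda_homoscedastic_matches_fda_and_mahalanobis_term():
    S = np.array([[1.5, 0.4], [0.4, 1.0]])
    st = _stats([0, 0], [2, 1], S, S)
    A, path = cda_transform(st, 1)
    a_f = fda_transform(st, 1)[0]
    assert _angle(A[0], a_f) < 1e-4
    m = st.means[0] - st.means[1]
    maha = 0.125 * float(A[0] @ m) ** 2 / float(A[0] @ S @ A[0])
    assert path[-1] == pytest.approx(maha, rel=1e-9)


def test_cda_beats_fda_and_matches_grid_search():
    st = _stats([0, 0], [0.5, 0.2], np.diag([1.0, 1.0]),
                np.diag([16.0, 1.0]))
    A, path = cda_transform(st, 1)
    j_fda = chernoff_objective(fda_transform(st, 1), st)
    assert path[-1] >= j_fda - 1e-12
    angles = np.linspace(0, np.pi, 4000)
    j_grid = max(chernoff_objective(
        np.array([[np.cos(t), np.sin(t)]]), st) for t in angles)
    assert path[-1] == pytest.approx(j_grid, abs=1e-3)


def test_cda_objective_nondecreasing():
    st = _stats([0, 0], [1, 0], np.diag([1.0, 4.0]), np.diag([9.0, 1.0]))
    _, path = cda_transform(st, 1)
    assert all(b >= a - 1e-12 for a, b in zip(path, path[1:]))


def test_cda_scale_invariant_predictions():
    X, y = make_gaussian_dataset(GaussianDatasetSpec(
        n_per_class=300, dim=2, mean1=[1, 1],
        cov1=np.diag([4.0, 0.5]), seed=4))
    clf = LDRClassifier("cda", "quadratic").fit(X, y)
    clf_sc = LDRClassifier("cda", "quadratic").fit(X * 7.5, y)
    np.testing.assert_array_equal(clf.predict(X), clf_sc.predict(X * 7.5))


def test_bayes_point_at_class_mean_and_linear_quadratic_agree():
    S = np.eye(2)
    X, y = make_gaussian_dataset(GaussianDatasetSpec(
        n_per_class=500, dim=2, mean1=[4, 0], cov0=S, cov1=S, seed=5))
    for bayes in ("linear", "quadratic"):
        clf = LDRClassifier("fda", bayes).fit(X, y)
        m0 = X[y == 0].mean(axis=0)
        assert clf.predict(m0[None, :])[0] == 0
    lin = LDRClassifier("fda", "linear").fit(X, y)
    quad = LDRClassifier("fda", "quadratic").fit(X, y)
    # equal-covariance populations: the two rules agree except near the
    # boundary where sample-covariance noise may flip a point
    agree = (lin.predict(X) == quad.predict(X)).mean()
    assert agree > 0.99


def test_quadratic_decision_threshold_matches_analytic_root():
    """1-D two-Gaussian fixture: the empirical decision flip sits at the
    root of the quadratic discriminant equation."""
    rng = np.random.default_rng(6)
    n = 4000
    x0 = rng.normal(0.0, 1.0, n)
    x1 = rng.normal(3.0, 2.0, n)
    X = np.r_[x0, x1][:, None]
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    clf = LDRClassifier("fda", "quadratic", n_components=1).fit(X, y)
    a = float(clf.transform_[0, 0])
    # class stats in z-space, as fitted
    mu = clf.means_[:, 0]
    var = np.array([clf.covs_[0, 0, 0], clf.covs_[1, 0, 0]])
    pri = clf.priors_
    # solve: log p0 - .5 log v0 - (z-m0)^2/(2 v0) = same for class 1
    A_ = 0.5 / var[1] - 0.5 / var[0]
    B_ = mu[0] / var[0] - mu[1] / var[1]
    C_ = (np.log(pri[0] / pri[1]) + 0.5 * np.log(var[1] / var[0])
          + mu[1] ** 2 / (2 * var[1]) - mu[0] ** 2 / (2 * var[0]))
    roots = np.roots([A_, B_, C_])
    roots = np.sort(roots[np.isreal(roots)].real)
    # sweep the reduced coordinate across a fine grid; every decision flip
    # must sit on an analytic root
    z = np.linspace(min(mu) - 3, max(mu) + 3, 20001)
    pred = clf.predict((z / a)[:, None]).astype(float)
    flips = z[np.where(np.diff(pred))[0]]
    assert len(flips) >= 1
    for zf in flips:
        assert np.min(np.abs(roots - zf)) < 1e-3


def test_nb_reaches_analytic_bayes_accuracy():
    """Diagonal Gaussian data: NB accuracy within 2 points of the Bayes
    accuracy of the generating model."""
    delta = 1.5
    spec = GaussianDatasetSpec(n_per_class=2500, dim=2,
                               mean1=[delta, delta], seed=7)
    X, y = make_gaussian_dataset(spec)
    half = len(X) // 2
    rng = np.random.default_rng(8)
    perm = rng.permutation(len(X))
    tr, te = perm[:half], perm[half:]
    clf = GaussianNaiveBayes().fit(X[tr], y[tr])
    acc = (clf.predict(X[te]) == y[te]).mean()
    # Bayes rule thresholds the projection on the mean difference:
    # accuracy = Phi(|m1-m0| / 2) for unit spherical covariance
    bayes_acc = norm.cdf(np.sqrt(2) * delta / 2)
    assert abs(acc - bayes_acc) < 0.02


def test_nb_memorizes_separated_training_point():
    X = np.array([[0.0, 0.0], [10.0, 10.0], [0.1, -0.1], [9.9, 10.2]])
    y = np.array(["a", "b", "a", "b"])
    clf = GaussianNaiveBayes().fit(X, y)
    np.testing.assert_array_equal(clf.predict(X), y)


def test_nb_feature_permutation_invariance(rng):
    X = rng.normal(size=(200, 6)) + rng.integers(0, 2, 200)[:, None]
    y = rng.integers(0, 2, 200)
    clf = GaussianNaiveBayes().fit(X, y)
    perm = rng.permutation(6)
    clf_p = GaussianNaiveBayes().fit(X[:, perm], y)
    np.testing.assert_array_equal(clf.predict(X), clf_p.predict(X[:, perm]))


def test_knn_identity_and_duplication_invariance(rng):
    X = rng.normal(size=(40, 3))
    y = rng.integers(0, 2, 40)
    knn = KNearestNeighbors(k=1).fit(X, y)
    np.testing.assert_array_equal(knn.predict(X), y)
    knn_dup = KNearestNeighbors(k=1).fit(np.vstack([X, X]), np.r_[y, y])
    np.testing.assert_array_equal(knn_dup.predict(X), y)


def test_knn_vote_differs_from_nearest_neighbor():
    # test point at origin: nearest is class 1 at distance 1, but the
    # 3-vote is 2 x class 0 (distance 2, 3) vs 1 x class 1
    X = np.array([[1.0, 0.0], [0.0, 2.0], [-3.0, 0.0], [10.0, 10.0]])
    y = np.array([1, 0, 0, 1])
    q = np.zeros((1, 2))
    assert KNearestNeighbors(k=1).fit(X, y).predict(q)[0] == 1
    assert KNearestNeighbors(k=3).fit(X, y).predict(q)[0] == 0


def test_knn_tie_falls_back_to_nearest():
    X = np.array([[1.0, 0.0], [0.0, 2.0]])
    y = np.array([1, 0])
    assert KNearestNeighbors(k=2).fit(X, y).predict(np.zeros((1, 2)))[0] == 1


def test_knn_k_validation(rng):
    X = rng.normal(size=(5, 2))
    y = np.array([0, 1, 0, 1, 0])
    with pytest.raises(ValueError):
        KNearestNeighbors(k=6).fit(X, y)


def test_knn_agrees_with_sklearn_oracle(rng):
    from sklearn.neighbors import KNeighborsClassifier

    Xtr = rng.normal(size=(100, 4))
    ytr = rng.integers(0, 2, 100)
    Xte = rng.normal(size=(50, 4))
    ours = KNearestNeighbors(k=1).fit(Xtr, ytr).predict(Xte)
    ref = KNeighborsClassifier(n_neighbors=1).fit(Xtr, ytr).predict(Xte)
    np.testing.assert_array_equal(ours, ref)


def test_nb_agrees_with_sklearn_oracle(rng):
    from sklearn.naive_bayes import GaussianNB

    Xtr = rng.normal(size=(200, 5)) + rng.integers(0, 2, 200)[:, None]
    ytr = rng.integers(0, 2, 200)
    Xte = rng.normal(size=(80, 5))
    ours = GaussianNaiveBayes().fit(Xtr, ytr).predict(Xte)
    ref = GaussianNB().fit(Xtr, ytr).predict(Xte)
    assert (ours == ref).mean() > 0.99


def test_parameter_recovery_in_reduced_space():
    """Reduced-space class moments match the generating model within 5%."""
    S0 = np.array([[2.0, 0.5], [0.5, 1.0]])
    S1 = np.array([[1.0, -0.3], [-0.3, 3.0]])
    m1 = np.array([3.0, 1.0])
    spec = GaussianDatasetSpec(n_per_class=5000, dim=2, mean1=m1,
                               cov0=S0, cov1=S1, seed=9)
    X, y = make_gaussian_dataset(spec)
    clf = LDRClassifier("fda", "quadratic").fit(X, y)
    a = clf.transform_[0]
    true_means = np.array([a @ np.zeros(2), a @ m1])
    true_vars = np.array([a @ S0 @ a, a @ S1 @ a])
    got_means = clf.means_[:, 0]
    got_vars = np.array([clf.covs_[0, 0, 0], clf.covs_[1, 0, 0]])
    np.testing.assert_allclose(got_vars, true_vars, rtol=0.05)
    scale = abs(true_means[1] - true_means[0])
    assert abs(got_means[1] - got_means[0]) == pytest.approx(scale, rel=0.05)


def test_make_classifier_specs():
    assert isinstance(make_classifier("nb"), GaussianNaiveBayes)
    assert make_classifier("knn-5").k == 5
    ldr = make_classifier("ldr-cda-l")
    assert (ldr.criterion, ldr.bayes) == ("cda", "linear")
    with pytest.raises(ValueError):
        make_classifier("forest")
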