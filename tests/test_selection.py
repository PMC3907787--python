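"""Filter selection: entropy arithmetic, GR endpoints, chi2, mRMR greedy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppitype.selection import (FilterFeatureSelector, chi2_score, discretize,
                               entropy, gain_ratio, info_gain, mrmr_rank,
                               mutual_information, rank_features, select_top)


def test_entropy_values():
    assert entropy([0.5, 0.5]) == pytest.approx(1.0)
    assert entropy([1.0, 0.0]) == pytest.approx(0.0)
    assert entropy([0.25, 0.75]) == pytest.approx(0.811278, abs=1e-6)


def test_entropy_rejects_bad_distributions():
    with pytest.raises(ValueError):
        entropy([-0.1, 1.1])
    with pytest.raises(ValueError):
        entropy([0.5, 0.4])


def test_info_gain_identical_and_independent():
    y = np.array([0, 0, 1, 1] * 25)
    assert info_gain(y, y) == pytest.approx(1.0)
    x_ind = np.repeat([0, 0, 1, 1], 25)
    y_ind = np.repeat([0, 1, 0, 1], 25)
    assert info_gain(x_ind, y_ind) == pytest.approx(0.0, abs=1e-12)


def test_info_gain_hand_computed_table():
    # 8 samples: x=0 -> y (3 zeros, 1 one); x=1 -> y (1 zero, 3 ones)
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
    # H(Y)=1; H(Y|X)= 0.5*H(3/4,1/4)*2 = 0.811278
    assert info_gain(x, y) == pytest.approx(1.0 - 0.8112781244591328)


def test_single_class_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert info_gain([0, 1, 0, 1], [1, 1, 1, 1]) == 0.0


def test_gain_ratio_endpoints_and_constant_guard():
    y = np.array([0, 0, 1, 1] * 25)
    assert gain_ratio(y, y) == pytest.approx(1.0)
    x_ind = np.repeat([0, 0, 1, 1], 25)
    y_ind = np.repeat([0, 1, 0, 1], 25)
    assert gain_ratio(x_ind, y_ind) == pytest.approx(0.0, abs=1e-12)
    assert gain_ratio(np.zeros(100), y) == 0.0


def test_chi2_hand_values_and_symmetry():
    x = np.repeat([0, 1], 5)
    y = np.repeat([0, 1], 5)
    assert chi2_score(x, y) == pytest.approx(10.0)
    x_ind = np.repeat([0, 0, 1, 1], 25)
    y_ind = np.repeat([0, 1, 0, 1], 25)
    assert chi2_score(x_ind, y_ind) == pytest.approx(0.0, abs=1e-12)
    assert chi2_score(x, 1 - y) == pytest.approx(chi2_score(x, y))


@settings(deadline=None, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 1)),
                min_size=8, max_size=60))
def test_score_bounds_on_random_tables(pairs):
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if len(np.unique(y)) < 2:
        return
    ig = info_gain(x, y)
    gr = gain_ratio(x, y)
    assert ig >= 0
    assert 0 <= gr <= 1 + 1e-12
    assert chi2_score(x, y) >= 0


@settings(deadline=None, max_examples=25)
@given(st.randoms(use_true_random=False))
def test_scores_invariant_under_sample_permutation(r):
    rng = np.random.default_rng(r.randint(0, 2 ** 31))
    x = rng.integers(0, 5, 80)
    y = rng.integers(0, 2, 80)
    if len(np.unique(y)) < 2:
        return
    perm = rng.permutation(80)
    for fn in (info_gain, gain_ratio, chi2_score):
        assert fn(x[perm], y[perm]) == pytest.approx(fn(x, y))


def test_relabeling_of_y_outranks_noise_under_all_methods(rng):
    n = 200
    y = rng.integers(0, 2, n)
    X = np.column_stack([
        rng.normal(size=n),            # noise
        y + 0.01 * rng.normal(size=n),  # deterministic relabeling (+jitter)
        rng.normal(size=n),            # noise
    ])
    for method in ("IG", "GR", "Chi2", "mRMR"):
        ranked = rank_features(X, y, method)
        assert ranked.order[0] == 1, method


def test_mrmr_first_pick_is_max_relevance(rng):
    n = 300
    y = rng.integers(0, 2, n)
    X = np.column_stack([rng.normal(size=n),
                         y + 0.05 * rng.normal(size=n),
                         rng.normal(size=n)])
    Xd = discretize(X, "three_state", 3)
    ranked = mrmr_rank(Xd, y)
    rel = [mutual_information(Xd[:, j], y) for j in range(3)]
    assert ranked.order[0] == int(np.argmax(rel))


def test_mrmr_penalizes_duplicate_features():
    """A copy of the picked feature loses to a fresh weakly-relevant one."""
    rng = np.random.default_rng(3)
    n = 400
    y = rng.integers(0, 2, n)
    strong = y ^ (rng.random(n) < 0.2)   # noisy but clearly relevant
    weak = y ^ (rng.random(n) < 0.35)    # weakly relevant, independent noise
    Xd = np.column_stack([strong, strong.copy(), weak])
    ranked = mrmr_rank(Xd, y)
    assert ranked.order[0] in (0, 1)
    assert ranked.order[1] == 2  # duplicate deferred behind the weak feature
    # exhaustive check of the MID criterion at step 2
    sel = ranked.order[0]
    crit = [mutual_information(Xd[:, j], y)
            - mutual_information(Xd[:, j], Xd[:, sel])
            for j in range(3) if j != sel]
    assert ranked.order[1] == [j for j in range(3) if j != sel][
        int(np.argmax(crit))]


def test_mrmr_full_ranking_is_permutation(rng):
    X = rng.normal(size=(60, 7))
    y = rng.integers(0, 2, 60)
    ranked = mrmr_rank(discretize(X, "three_state", 3), y, k=7)
    assert sorted(ranked.order) == list(range(7))


def test_mrmr_rejects_bad_k(rng):
    Xd = rng.integers(0, 3, (20, 4))
    y = rng.integers(0, 2, 20)
    with pytest.raises(ValueError):
        mrmr_rank(Xd, y, k=0)
    with pytest.raises(ValueError):
        mrmr_rank(Xd, y, k=5)


def test_select_top_prefix_and_full(rng):
    X = rng.normal(size=(50, 210))
    y = rng.integers(0, 2, 50)
    ranked = rank_features(X, y, "GR")
    top2 = select_top(ranked, X, 2)
    assert top2.shape == (50, 2)
    np.testing.assert_array_equal(top2, X[:, ranked.order[:2]])
    full = select_top(ranked, X, 210)
    assert sorted(ranked.order) == list(range(210))
    assert full.shape == X.shape
    with pytest.raises(ValueError):
        ranked.top(0)


def test_selector_transformer_interface(rng):
    X = rng.normal(size=(80, 12))
    y = rng.integers(0, 2, 80)
    sel = FilterFeatureSelector("Chi2", n_features=3).fit(X, y)
    Xt = sel.transform(X)
    assert Xt.shape == (80, 3)
    assert sel.get_support().sum() == 3
    np.testing.assert_array_equal(Xt, X[:, sel.ranking_[:3]])


def test_ties_broken_by_feature_index():
    y = np.array([0, 1] * 30)
    X = np.column_stack([y, y, y]).astype(float)
    ranked = rank_features(X, y, "IG")
    np.testing.assert_array_equal(ranked.order, [0, 1, 2])
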