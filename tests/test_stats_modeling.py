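import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vusannot import stats_modeling as sm_
from vusannot.synthetic import planted_step_dataset


# ---------------------------------------------------------------------------
# Spearman screen

def test_spearman_monotone_extremes():
    X = pd.DataFrame({"up": np.arange(10.0), "down": -np.arange(10.0)})
    y = np.arange(10.0) ** 2
    out = sm_.spearman_screen(X, y).set_index("covariate")
    assert out.loc["up", "rho"] == pytest.approx(1.0)
    assert out.loc["down", "rho"] == pytest.approx(-1.0)


def test_spearman_constant_flagged():
    X = pd.DataFrame({"const": np.ones(10)})
    out = sm_.spearman_screen(X, np.arange(10.0))
    assert out.loc[0, "flag"] == "constant"
    assert np.isnan(out.loc[0, "rho"])


def test_spearman_matches_exact_permutation_oracle():
    """n=8 fixture: t-approximation p agrees with exhaustive permutation."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=8)
    y = 0.9 * x + rng.normal(0, 0.6, 8)
    out = sm_.spearman_screen(pd.DataFrame({"x": x}), y)
    rho_obs, p_obs = out.loc[0, "rho"], out.loc[0, "p"]
    rx = stats.rankdata(x)
    rhos = []
    for perm in itertools.permutations(stats.rankdata(y)):
        rhos.append(np.corrcoef(rx, perm)[0, 1])
    rhos = np.array(rhos)
    exact_p = float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())
    assert rho_obs == pytest.approx(np.corrcoef(rx, stats.rankdata(y))[0, 1])
    assert p_obs == pytest.approx(exact_p, abs=0.05)


# ---------------------------------------------------------------------------
# group tests

def test_welch_identical_groups():
    res = sm_.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_welch_separated_groups():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1e-3, 5)
    b = 1 + rng.normal(0, 1e-3, 5)
    assert sm_.welch_t_test(a, b).p < 1e-6


def test_welch_closed_form_fixture():
    # a = {1,2,3,4}, b = {2,4,6,8}: t = -2.5/sqrt(5/12+5/3), Welch df = 4.412
    res = sm_.welch_t_test([1, 2, 3, 4], [2, 4, 6, 8])
    assert res.t == pytest.approx(-1.7320508, abs=1e-6)
    assert res.df == pytest.approx(4.4117647, abs=1e-6)
    assert 0.14 < res.p < 0.17


def test_welch_group_too_small():
    with pytest.raises(ValueError):
        sm_.welch_t_test([1.0], [1.0, 2.0])


def test_two_way_anova_balanced_hand_computed():
    # cell means 2/3/6/7, within-cell SS 2 each: F_A = 16, F_B = 1, F_int = 0
    values = [1, 3, 2, 4, 5, 7, 6, 8]
    a = ["a1"] * 4 + ["a2"] * 4
    b = ["b1", "b1", "b2", "b2"] * 2
    out = sm_.two_way_anova(values, a, b)
    assert out["a"][0] == pytest.approx(16.0)
    assert out["b"][0] == pytest.approx(1.0)
    assert out["interaction"][0] == pytest.approx(0.0, abs=1e-10)


def test_two_way_anova_planted_main_effect():
    rng = np.random.default_rng(1)
    a = ["x"] * 20 + ["y"] * 20
    b = (["u"] * 10 + ["v"] * 10) * 2
    values = np.where(np.array(a) == "x", 0.0, 2.0) + rng.normal(0, 0.3, 40)
    out = sm_.two_way_anova(values, a, b)
    assert out["a"][1] < 1e-6
    assert out["b"][1] > 0.05


def test_two_way_anova_empty_cell_rejected():
    with pytest.raises(ValueError):
        sm_.two_way_anova([1, 2, 3, 4], ["x", "x", "y", "y"],
                          ["u", "u", "u", "u"])


# ---------------------------------------------------------------------------
# principal-components regression

def test_pcr_collinear_covariates():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    X = pd.DataFrame({"a": x, "b": 2 * x + 5})
    with pytest.warns(UserWarning, match="singular"):
        model = sm_.pc_regression(X, rng.normal(size=30))
    assert model.n_selected == 1
    assert model.variance_fractions[0] == pytest.approx(1.0)


def test_pcr_noiseless_recovery():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    model0 = sm_.pc_regression(X, rng.normal(size=40))
    z = (X - X.mean()) / X.std(ddof=1)
    y = z.to_numpy() @ model0.loadings[:, 0]  # activity = PC1 score exactly
    model = sm_.pc_regression(X, y, var_threshold=0.99)
    assert model.adj_r2 == pytest.approx(1.0, abs=1e-9)


def test_pcr_variance_fractions_structure():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(20, 5)))
    model = sm_.pc_regression(X, rng.normal(size=20))
    assert np.all(np.diff(model.variance_fractions) <= 1e-12)
    assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    # full reconstruction from all components is exact
    z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
    assert np.allclose(z @ model.loadings @ model.loadings.T, z, atol=1e-8)


def test_pcr_selection_threshold():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(50, 4)))
    model = sm_.pc_regression(X, rng.normal(size=50), var_threshold=0.75)
    cum = np.cumsum(model.variance_fractions)
    assert cum[model.n_selected - 1] >= 0.75
    assert model.n_selected == 1 or cum[model.n_selected - 2] < 0.75


# ---------------------------------------------------------------------------
# regression tree

def test_tree_constant_response_single_node():
    X = pd.DataFrame({"x": np.arange(20.0)})
    tree = sm_.fit_tree(X, np.ones(20), seed=0)
    assert tree.root.is_terminal
    assert tree.predict(X) == pytest.approx(np.ones(20))


def test_tree_recovers_planted_step():
    X, y, truth = planted_step_dataset(seed=11)
    tree = sm_.fit_tree(X, y, seed=0)
    assert tree.root.covariate == truth["covariate"]
    assert truth["gap_low"] <= tree.root.threshold <= truth["gap_high"]


def test_tree_predictions_are_leaf_means():
    X, y, _ = planted_step_dataset(seed=5)
    tree = sm_.fit_tree(X, y, seed=0)
    pred = tree.predict(X)
    for leaf_val in np.unique(pred):
        members = pred == leaf_val
        assert y[members].mean() == pytest.approx(leaf_val)
    assert pred.min() >= y.min() and pred.max() <= y.max()


def test_tree_planted_step_monotone_routing():
    X, y, truth = planted_step_dataset(seed=7)
    tree = sm_.fit_tree(X, y, seed=0)
    pred = tree.predict(X)
    below = X["x1"].to_numpy() < truth["gap_low"]
    assert pred[below].mean() > pred[~below].mean()  # high activity below theta


def test_tree_training_fit_monotone_in_alpha():
    rng = np.random.default_rng(9)
    X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
    y = X["a"].to_numpy() + 0.5 * rng.normal(size=80)
    r2 = []
    for alpha in (0.001, 0.05, 0.5):
        tree = sm_.fit_tree(X, y, alpha=alpha, n_perm=999, seed=0)
        pred = tree.predict(X)
        r2.append(1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    assert r2[0] <= r2[1] + 1e-12 <= r2[2] + 2e-12


def test_tree_internal_nodes_significant():
    X, y, _ = planted_step_dataset(seed=3)
    tree = sm_.fit_tree(X, y, alpha=0.05, seed=0)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if not node.is_terminal:
            assert node.p_value <= 0.05
            assert node.left.n + node.right.n == node.n
            stack += [node.left, node.right]


def test_tree_requires_complete_rows():
    X = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
    with pytest.raises(ValueError):
        sm_.fit_tree(X, np.ones(3), seed=0)


def test_predict_missing_covariate_rejected():
    X, y, _ = planted_step_dataset(seed=1)
    tree = sm_.fit_tree(X, y, seed=0)
    with pytest.raises(ValueError, match="missing"):
        tree.predict(X.drop(columns=["x1"]))


# ---------------------------------------------------------------------------
# cross-validation

def test_cv_noiseless_step_is_perfect():
    X, y, _ = planted_step_dataset(n=100, noise_sd=1e-6, seed=2)
    cv = sm_.crossvalidate(X[["x1"]], y, k=10, repeats=2, n_perm=999, seed=4)
    assert cv.accuracy == pytest.approx(1.0)


def test_cv_determinism():
    X, y, _ = planted_step_dataset(seed=8, noise_sd=0.3)
    cv1 = sm_.crossvalidate(X, y, repeats=2, n_perm=499, seed=13)
    cv2 = sm_.crossvalidate(X, y, repeats=2, n_perm=499, seed=13)
    assert cv1.to_dict() == cv2.to_dict()
    assert np.array_equal(cv1.predicted, cv2.predicted)


def test_cv_counts_sum():
    X, y, _ = planted_step_dataset(seed=8)
    cv = sm_.crossvalidate(X, y, repeats=3, n_perm=499, seed=0)
    assert cv.confusion.n == 3 * len(y)


def test_cv_requires_enough_data():
    X, y, _ = planted_step_dataset(n=10, seed=0)
    with pytest.raises(ValueError):
        sm_.crossvalidate(X, y, seed=0)


# ---------------------------------------------------------------------------
# predictor evaluation

def test_evaluate_fathmm_quadrants():
    # score -0.8 with activity 0.3 (LOF) is a true positive at the -0.75 rule
    ev = sm_.evaluate_predictor([-0.8, -0.8, 0.5, 0.5],
                                [True, False, True, False], "fathmm")
    assert list(ev.quadrant) == ["TP", "FP", "FN", "TN"]
    assert ev.accuracy == pytest.approx(0.5)


def test_evaluate_polyphen_bands():
    ev = sm_.evaluate_predictor([0.1, 0.5, 0.9], [False, False, True],
                                "polyphen2")
    assert list(ev.categories) == ["benign", "possibly_damaging",
                                   "probably_damaging"]
    # only the > 0.8 call counts as damaging for the confusion matrix
    assert ev.confusion.tp == 1 and ev.confusion.tn == 2


def test_evaluate_opai_uncertain_below_default():
    ev = sm_.evaluate_predictor([0.94, 0.95], [True, True], "opai")
    assert list(ev.quadrant) == ["FN", "TP"]


def test_evaluate_missing_scores_excluded():
    ev = sm_.evaluate_predictor([np.nan, -1.0], [True, True], "fathmm")
    assert ev.n_excluded == 1
    assert ev.confusion.n == 1
    assert list(ev.quadrant) == ["excluded", "TP"]


# ---------------------------------------------------------------------------
# adjusted R^2

def test_r2_identity():
    y = np.arange(10.0)
    assert sm_.actual_vs_predicted_r2(y, y) == pytest.approx(1.0)


def test_r2_null_large_n():
    rng = np.random.default_rng(0)
    val = sm_.actual_vs_predicted_r2(rng.normal(size=2000),
                                     rng.normal(size=2000))
    assert abs(val) < 0.01


def test_r2_hand_computed_fixture():
    # actual {1,2,3,4} on predicted {1,2,3,5}: R^2 = 169/175, adj = 0.948571
    val = sm_.actual_vs_predicted_r2([1, 2, 3, 4], [1, 2, 3, 5])
    assert val == pytest.approx(0.9485714, abs=1e-6)


def test_r2_zero_variance_predictor_warns():
    with pytest.warns(UserWarning):
        assert sm_.actual_vs_predicted_r2([1, 2, 3, 4], [2, 2, 2, 2]) == 0.0
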