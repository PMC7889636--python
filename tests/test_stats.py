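"""Statistics engines against textbook oracles and simulation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from cowhemo import (CohortConfig, direct_feature_matrix, fit_plsda,
                     ks_normality, paired_asymmetry_test, stepwise_elimination,
                     two_group_ttest, ttest_from_summary, anova_on_scores)
from cowhemo.stats import DegenerateSampleError, benjamini_hochberg


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

def test_ks_on_exact_normal_quantiles_is_small():
    q = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
    res = ks_normality(q, n_mc=2000, seed=0)
    assert res.statistic < 0.1
    assert res.pvalue > 0.5


def test_ks_flags_exponential_samples():
    rng = np.random.default_rng(0)
    normal = rng.normal(size=50)
    expo = rng.exponential(size=50)
    d_norm = ks_normality(normal, n_mc=2000, seed=1).statistic
    res_exp = ks_normality(expo, n_mc=2000, seed=1)
    assert res_exp.statistic > d_norm
    assert res_exp.pvalue < 0.01


def test_ks_preconditions():
    with pytest.raises(DegenerateSampleError):
        ks_normality([1.0, 2.0])
    with pytest.raises(DegenerateSampleError):
        ks_normality([3.0, 3.0, 3.0, 3.0])


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def _matrix(a, b, feature="f"):
    return pd.DataFrame({"group": ["A"] * len(a) + ["B"] * len(b),
                         feature: np.concatenate([a, b])})


def test_identical_samples_give_t0_p1():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = two_group_ttest(_matrix(x, x), "f", "A", "B")
    assert res.statistic == 0.0 and res.pvalue == 1.0


def test_pooled_summary_ttest_matches_textbook_formula():
    """Published row: lumen area of the left ICA, control vs 2-month
    diabetes, re-tested from its summary statistics."""
    ma, sea, na = 0.12, 0.009, 10
    mb, seb, nb = 0.09, 0.005, 9
    res = ttest_from_summary(ma, sea, na, mb, seb, nb, variant="student")

    sa, sb = sea * np.sqrt(na), seb * np.sqrt(nb)
    sp2 = ((na - 1) * sa ** 2 + (nb - 1) * sb ** 2) / (na + nb - 2)
    t_hand = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p_hand = 2 * sps.t.sf(abs(t_hand), na + nb - 2)
    assert res.statistic == pytest.approx(t_hand, rel=1e-10)
    assert res.pvalue == pytest.approx(p_hand, rel=1e-10)
    assert res.df == na + nb - 2
    assert res.pvalue < 0.05  # the published comparison is significant


def test_ttest_antisymmetric_under_group_swap(rng):
    a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
    m = _matrix(a, b)
    r1 = two_group_ttest(m, "f", "A", "B")
    r2 = two_group_ttest(m, "f", "B", "A")
    assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
    assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-12)


def test_welch_variant_differs_under_heteroscedasticity(rng):
    a, b = rng.normal(0, 1, 8), rng.normal(0, 5, 20)
    m = _matrix(a, b)
    student = two_group_ttest(m, "f", "A", "B", variant="student")
    welch = two_group_ttest(m, "f", "A", "B", variant="welch")
    assert welch.df < student.df
    assert welch.pvalue != student.pvalue


def test_ttest_matrix_matches_summary_route(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1.2, 9)
    m = _matrix(a, b)
    r1 = two_group_ttest(m, "f", "A", "B")
    r2 = ttest_from_summary(a.mean(), a.std(ddof=1) / np.sqrt(10), 10,
                            b.mean(), b.std(ddof=1) / np.sqrt(9), 9)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-10)


def test_missing_feature_raises(rng):
    with pytest.raises(KeyError):
        two_group_ttest(_matrix(rng.normal(size=3), rng.normal(size=3)),
                        "nope", "A", "B")


# ---------------------------------------------------------------------------
# paired asymmetry
# ---------------------------------------------------------------------------

def _lr_matrix(left, right, group="2d"):
    return pd.DataFrame({"group": [group] * len(left),
                         "L": left, "R": right})


def test_paired_equal_sides_give_t0_p1():
    x = np.array([1.0, 2.0, 3.0])
    res = paired_asymmetry_test(_lr_matrix(x, x), "L", "R", "2d")
    assert res.statistic == 0.0 and res.pvalue == 1.0


def test_paired_constant_offset_is_degenerate():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.raises(DegenerateSampleError):
        paired_asymmetry_test(_lr_matrix(x, x - 0.5), "L", "R", "2d")


def test_paired_missing_values_break_pairing():
    left = np.array([1.0, np.nan, 3.0])
    with pytest.raises(DegenerateSampleError):
        paired_asymmetry_test(_lr_matrix(left, left + 0.1), "L", "R", "2d")


def test_asymmetry_power_pattern_across_arms(params):
    """With the packaged generator at study sizes, the paired carotid test
    rejects in the 2-month diabetic arm in most replicates and rarely in
    its control."""
    rejects = {"2c": 0, "2d": 0}
    n_rep = 40
    for rep in range(n_rep):
        m = direct_feature_matrix(CohortConfig(seed=1000 + rep), params,
                                  "steady", include_inlet_velocities=True)
        for g in rejects:
            res = paired_asymmetry_test(m, "v_CCA_L", "v_CCA_R", g)
            rejects[g] += res.pvalue <= 0.05
    assert rejects["2d"] > n_rep / 2
    assert rejects["2c"] < n_rep / 4


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def test_pls_single_signal_concentrates_weight(rng):
    n = 2000  # large n so chance noise/label correlations stay negligible
    labels = ["A"] * (n // 2) + ["B"] * (n // 2)
    X = pd.DataFrame(rng.normal(size=(n, 5)),
                     columns=[f"noise{i}" for i in range(4)] + ["signal"])
    X["signal"] = np.where(np.array(labels) == "A", -2.0, 2.0) + rng.normal(0, 0.1, n)
    model = fit_plsda(X, labels, n_components=2)
    w = model.W[:, 0]
    assert abs(w[list(X.columns).index("signal")]) > 0.99


def test_pls_single_feature_scores_proportional_to_centered_feature(rng):
    x = rng.normal(size=12)
    labels = ["A"] * 6 + ["B"] * 6
    model = fit_plsda(x.reshape(-1, 1), labels, n_components=1)
    xs = (x - x.mean()) / x.std(ddof=1)
    ratio = model.T[:, 0] / xs
    assert np.allclose(ratio, ratio[0], atol=1e-10)


def test_pls_scores_match_cross_covariance_svd_oracle(rng):
    """First component of NIPALS equals the dominant left singular vector
    of X^T Y on autoscaled data (6 x 4 example)."""
    X = rng.normal(size=(6, 4))
    labels = ["A", "A", "B", "B", "C", "C"]
    model = fit_plsda(pd.DataFrame(X), labels, n_components=2)

    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Y, classes = np.zeros((6, 3)), sorted(set(labels))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1
    Ys = Y - Y.mean(0)
    u_svd, _, _ = np.linalg.svd(Xs.T @ Ys)
    w1 = u_svd[:, 0]
    t1 = Xs @ w1
    sign = np.sign(t1 @ model.T[:, 0])
    assert np.allclose(model.T[:, 0], sign * t1, atol=1e-6)


def test_pls_scores_match_sklearn_nipals(rng):
    """Cross-check against scikit-learn's NIPALS on identically
    preprocessed inputs (X autoscaled, Y centred one-hot)."""
    from sklearn.cross_decomposition import PLSRegression
    X = rng.normal(size=(14, 6))
    labels = ["A"] * 5 + ["B"] * 5 + ["C"] * 4
    model = fit_plsda(pd.DataFrame(X), labels, n_components=2)

    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Y, classes = np.zeros((14, 3)), sorted(set(labels))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1
    Ys = Y - Y.mean(0)
    ref = PLSRegression(n_components=2, scale=False,
                        tol=1e-12, max_iter=10_000).fit(Xs, Ys)
    for k in range(2):
        sign = np.sign(ref.x_scores_[:, k] @ model.T[:, k])
        assert np.allclose(model.T[:, k], sign * ref.x_scores_[:, k], atol=1e-6)


def test_pls_score_orthogonality_and_deflation(params):
    m = direct_feature_matrix(CohortConfig(seed=2), params, "steady")
    model = fit_plsda(m.drop(columns="group"), m["group"], n_components=2)
    t1, t2 = model.T[:, 0], model.T[:, 1]
    cos = abs(t1 @ t2) / (np.linalg.norm(t1) * np.linalg.norm(t2))
    assert cos < 1e-8
    assert model.ssy_explained[1] <= model.ssy_explained[0] * 1.5  # deflation shrinks signal


def test_pls_needs_two_groups(rng):
    with pytest.raises(ValueError):
        fit_plsda(rng.normal(size=(5, 3)), ["A"] * 5)


def test_pls_predicts_separable_classes(rng):
    n = 20
    labels = ["A"] * 10 + ["B"] * 10
    X = pd.DataFrame(rng.normal(size=(n, 3)))
    X[0] = np.where(np.array(labels) == "A", -3.0, 3.0) + rng.normal(0, 0.2, n)
    model = fit_plsda(X, labels)
    assert (model.predict_class(X) == np.array(labels)).all()


# ---------------------------------------------------------------------------
# stepwise elimination
# ---------------------------------------------------------------------------

def _informative_plus_noise(rng, n_noise=10, n=40):
    labels = ["A"] * (n // 2) + ["B"] * (n // 2)
    X = pd.DataFrame(rng.normal(size=(n, n_noise + 1)),
                     columns=[f"noise{i}" for i in range(n_noise)] + ["inf"])
    X["inf"] = np.where(np.array(labels) == "A", 0.0, 3.0) + rng.normal(0, 0.5, n)
    return X, labels


def test_stepwise_removes_noise_keeps_signal():
    removed_counts, kept_signal = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X, labels = _informative_plus_noise(rng)
        res = stepwise_elimination(X, labels, seed=seed)
        removed_counts.append(11 - len(res.retained))
        kept_signal.append("inf" in res.retained)
    assert np.median(removed_counts) >= 8
    assert sum(kept_signal) >= 18


def test_stepwise_all_noise_terminates_unstable(rng):
    X = pd.DataFrame(rng.normal(size=(24, 6)))
    labels = ["A"] * 12 + ["B"] * 12
    res = stepwise_elimination(X, labels, seed=0)
    assert len(res.retained) >= 1
    assert not res.stable


def test_stepwise_infinite_tolerance_keeps_one_feature(rng):
    X, labels = _informative_plus_noise(rng, n_noise=5)
    res = stepwise_elimination(X, labels, tol=np.inf, seed=0)
    assert len(res.retained) == 1


def test_stepwise_deterministic_under_seed(rng):
    X, labels = _informative_plus_noise(rng)
    r1 = stepwise_elimination(X, labels, seed=3)
    r2 = stepwise_elimination(X, labels, seed=3)
    assert r1.retained == r2.retained


# ---------------------------------------------------------------------------
# two-way ANOVA on scores
# ---------------------------------------------------------------------------

def _scores_frame(groups, y1, y2=None):
    df = pd.DataFrame({"group": groups, "Y1": y1})
    if y2 is not None:
        df["Y2"] = y2
    return df


def test_anova_constant_scores_give_zero_f():
    groups = ["1c"] * 3 + ["1d"] * 3 + ["2c"] * 3 + ["2d"] * 3
    tab = anova_on_scores(_scores_frame(groups, np.ones(12)))
    assert (tab["F"] == 0.0).all() and (tab["pvalue"] == 1.0).all()


def test_anova_balanced_matches_hand_sums_of_squares(rng):
    """Balanced 2x2 with n=3 per cell vs a from-scratch decomposition."""
    groups = ["1c"] * 3 + ["1d"] * 3 + ["2c"] * 3 + ["2d"] * 3
    y = rng.normal(size=12)
    tab = anova_on_scores(_scores_frame(groups, y))

    arr = y.reshape(4, 3)  # cells: (1,c), (1,d), (2,c), (2,d)
    grand = y.mean()
    mean_c = np.concatenate([arr[0], arr[2]]).mean()
    mean_d = np.concatenate([arr[1], arr[3]]).mean()
    mean_1 = np.concatenate([arr[0], arr[1]]).mean()
    mean_2 = np.concatenate([arr[2], arr[3]]).mean()
    ss_path = 6 * ((mean_c - grand) ** 2 + (mean_d - grand) ** 2)
    ss_dur = 6 * ((mean_1 - grand) ** 2 + (mean_2 - grand) ** 2)
    ss_tot = ((y - grand) ** 2).sum()
    ss_res = ss_tot - ss_path - ss_dur  # additive model residual
    df_res = 12 - 3
    f_path = ss_path / (ss_res / df_res)
    f_dur = ss_dur / (ss_res / df_res)

    got = {(r["effect"]): r["F"] for _, r in tab.iterrows()}
    assert got["pathology"] == pytest.approx(f_path, rel=1e-10)
    assert got["duration"] == pytest.approx(f_dur, rel=1e-10)
    p_hand = sps.f.sf(f_path, 1, df_res)
    assert tab.loc[tab.effect == "pathology", "pvalue"].iloc[0] == pytest.approx(
        p_hand, rel=1e-10)


def test_anova_study_design_df(params):
    """At the study's 7/5/10/9 arm sizes the additive model leaves 28
    residual degrees of freedom."""
    m = direct_feature_matrix(CohortConfig(seed=0), params, "steady")
    rng = np.random.default_rng(0)
    tab = anova_on_scores(_scores_frame(list(m["group"]),
                                        rng.normal(size=len(m))))
    assert (tab["df2"] == 28).all()
    tab_i = anova_on_scores(_scores_frame(list(m["group"]),
                                          rng.normal(size=len(m))),
                            include_interaction=True)
    assert (tab_i["df2"] == 27).all()
    assert set(tab_i["effect"]) == {"pathology", "duration", "pathologyxduration"}


def test_anova_detects_late_pathology_shift():
    """A pathology shift present only at 2 months shows up as a pathology
    main effect in most replicates."""
    groups = ["1c"] * 7 + ["1d"] * 5 + ["2c"] * 10 + ["2d"] * 9
    hits = 0
    n_rep = 100
    for rep in range(n_rep):
        rng = np.random.default_rng(rep)
        y = rng.normal(size=31)
        y[22:] += 2.0  # the 2d block
        tab = anova_on_scores(_scores_frame(groups, y))
        p = tab.loc[tab.effect == "pathology", "pvalue"].iloc[0]
        hits += p <= 0.05
    assert hits > n_rep / 2


def test_anova_rejects_empty_cells():
    groups = ["1c"] * 3 + ["1d"] * 3 + ["2c"] * 3
    with pytest.raises(ValueError):
        anova_on_scores(_scores_frame(groups, np.arange(9.0)))


def test_benjamini_hochberg_monotone_and_bounded(rng):
    p = rng.uniform(size=30)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
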