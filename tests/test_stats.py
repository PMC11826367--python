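"""Statistical machinery: comparisons, odds ratios, logistic fits, ROC, kappa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from abpmkit.stats import (
    SeparationError,
    cohens_kappa,
    collinearity_diagnostics,
    compare_groups,
    fit_multivariable,
    fit_univariable,
    hosmer_lemeshow,
    nagelkerke_r2,
    odds_ratio_2x2,
    roc_analysis,
    select_predictors,
)


# ---------------------------------------------------------------------------
# 2x2 odds ratios


def test_or_printed_contingency_values():
    # sex (female-exposed) and smoking tables from a 39/40 hypertension cohort
    or_, lo, hi = odds_ratio_2x2(17, 24, 22, 16)
    assert (round(or_, 3), round(lo, 3), round(hi, 3)) == (0.515, 0.211, 1.261)
    or_, lo, hi = odds_ratio_2x2(14, 13, 25, 27)
    assert (round(or_, 3), round(lo, 3), round(hi, 3)) == (1.163, 0.459, 2.949)


def test_or_symmetric_table_is_one():
    or_, lo, hi = odds_ratio_2x2(8, 8, 8, 8)
    assert or_ == 1.0 and lo < 1.0 < hi


counts = st.integers(min_value=1, max_value=50)


@given(a=counts, b=counts, c=counts, d=counts)
def test_or_invariances(a, b, c, d):
    or_, lo, hi = odds_ratio_2x2(a, b, c, d)
    assert lo <= or_ <= hi
    # swapping both rows and both columns leaves the OR unchanged
    assert odds_ratio_2x2(d, c, b, a)[0] == pytest.approx(or_, rel=1e-12)
    # swapping exposure coding inverts it
    inv = odds_ratio_2x2(c, d, a, b)
    assert inv[0] == pytest.approx(1 / or_, rel=1e-12)
    assert inv[1] == pytest.approx(1 / hi, rel=1e-12)


def test_or_zero_cell_haldane(caplog):
    with caplog.at_level("WARNING"):
        or_, lo, hi = odds_ratio_2x2(10, 0, 5, 12)
    assert "Haldane" in caplog.text
    assert np.isfinite(or_) and lo < or_ < hi
    with pytest.raises(ValueError, match="degenerate"):
        odds_ratio_2x2(0, 0, 5, 5)


# ---------------------------------------------------------------------------
# group comparisons


def _toy_cohort(n=40, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    g = np.repeat([0, 1], n // 2)
    return pd.DataFrame(
        {
            "grp": g,
            "normalvar": rng.normal(10 + effect * g, 2),
            "skewvar": rng.lognormal(0.5 * g * effect, 1.0, n),
            "binary": rng.random(n) < 0.4,
        }
    )


def test_identical_groups_give_null_pvalues():
    half = _toy_cohort(20, seed=2).drop(columns="grp")
    cohort = pd.concat([half, half], ignore_index=True)
    cohort["grp"] = np.repeat([0, 1], len(half))
    results = compare_groups(cohort, "grp")
    for r in results:
        assert r.p_value > 0.95, r


def test_chi_square_matches_definitional_oracle():
    # smoking split 14/39 vs 13/40
    smoking = np.concatenate([np.ones(14), np.zeros(25), np.ones(13), np.zeros(27)])
    grp = np.repeat([1, 0], [39, 40])
    cohort = pd.DataFrame({"grp": grp, "smoking": smoking.astype(bool)})
    (res,) = compare_groups(cohort, "grp", ["smoking"])
    assert res.test_used == "chi_square"
    # independent hand computation: sum (O-E)^2/E over the 2x2 table
    obs = np.array([[27.0, 13.0], [25.0, 14.0]])
    exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
    chi2 = ((obs - exp) ** 2 / exp).sum()
    assert res.p_value == pytest.approx(sps.chi2.sf(chi2, 1), rel=1e-9)


def test_normality_gate_selects_tests():
    cohort = _toy_cohort(n=200, seed=3)
    results = {r.variable: r for r in compare_groups(cohort, "grp")}
    assert results["normalvar"].test_used == "t"
    assert results["skewvar"].test_used == "mann_whitney"
    assert results["binary"].test_used == "chi_square"
    assert "±" in results["normalvar"].summary_a
    assert "(" in results["skewvar"].summary_a


def test_compare_groups_errors():
    cohort = _toy_cohort(20)
    cohort["flat"] = 1.0
    with pytest.raises(ValueError, match="zero variance"):
        compare_groups(cohort, "grp", ["flat"])
    with pytest.raises(ValueError, match="two levels"):
        compare_groups(cohort.assign(grp=0), "grp")


# ---------------------------------------------------------------------------
# logistic regression


def test_univariable_binary_predictor_equals_2x2_or():
    smoking = np.concatenate([np.ones(14), np.zeros(25), np.ones(13), np.zeros(27)])
    outcome = np.repeat([1, 0], [39, 40])
    cohort = pd.DataFrame({"hmod": outcome, "smoking": smoking})
    res = fit_univariable(cohort, "hmod", "smoking")
    row = res.table.iloc[0]
    or_, lo, hi = odds_ratio_2x2(14, 13, 25, 27)
    assert row["odds_ratio"] == pytest.approx(or_, rel=1e-4)
    assert row["ci_low"] == pytest.approx(lo, rel=1e-3)
    assert row["ci_high"] == pytest.approx(hi, rel=1e-3)


def test_null_predictor_or_near_one():
    rng = np.random.default_rng(4)
    cohort = pd.DataFrame({"y": rng.integers(0, 2, 4000), "x": rng.normal(size=4000)})
    row = fit_univariable(cohort, "y", "x").table.iloc[0]
    assert row["odds_ratio"] == pytest.approx(1.0, abs=0.1)
    assert row["ci_low"] < 1 < row["ci_high"]


def test_standardization_leaves_pvalues_unchanged():
    rng = np.random.default_rng(5)
    x = rng.normal(50, 7, 300)
    y = (rng.random(300) < 1 / (1 + np.exp(-(x - 50) / 7))).astype(int)
    cohort = pd.DataFrame({"y": y, "x": x})
    p_std = fit_univariable(cohort, "y", "x", standardize=True).table.iloc[0]["p_value"]
    p_raw = fit_univariable(cohort, "y", "x", standardize=False).table.iloc[0]["p_value"]
    assert p_std == pytest.approx(p_raw, rel=1e-6)


def test_single_variable_multivariable_reduces_to_univariable():
    cohort = _toy_cohort(60, seed=6, effect=1.0).rename(columns={"grp": "y"})
    uni = fit_univariable(cohort, "y", "normalvar")
    multi = fit_multivariable(cohort, "y", ["normalvar"], hl_groups=None)
    pd.testing.assert_frame_equal(uni.table, multi.table)


def test_known_coefficient_recovered():
    rng = np.random.default_rng(7)
    beta = 0.8
    x = rng.normal(size=2000)
    y = (rng.random(2000) < 1 / (1 + np.exp(-(0.2 + beta * x)))).astype(int)
    res = fit_univariable(pd.DataFrame({"y": y, "x": x}), "y", "x", standardize=False)
    row = res.table.iloc[0]
    assert row["ci_low"] < np.exp(beta) < row["ci_high"]
    assert row["odds_ratio"] == pytest.approx(np.exp(beta), rel=0.2)


def test_null_model_calibration():
    rng = np.random.default_rng(8)
    cohort = pd.DataFrame({"y": rng.integers(0, 2, 500), "x": rng.normal(size=500)})
    res = fit_multivariable(cohort, "y", ["x"])
    assert res.nagelkerke_r2 < 0.05
    assert res.hosmer_lemeshow_p > 0.01


def test_separation_detected_and_reported():
    y = np.repeat([0, 1], 20)
    x = np.concatenate([np.random.default_rng(9).uniform(0, 1, 20),
                        np.random.default_rng(10).uniform(2, 3, 20)])
    with pytest.raises(SeparationError):
        fit_univariable(pd.DataFrame({"y": y, "x": x}), "y", "x")


def test_rank_deficiency_detected():
    rng = np.random.default_rng(11)
    x = rng.normal(size=60)
    cohort = pd.DataFrame({"y": rng.integers(0, 2, 60), "x1": x, "x2": 2 * x})
    with pytest.raises(ValueError, match="rank"):
        fit_multivariable(cohort, "y", ["x1", "x2"])


def test_hosmer_lemeshow_well_calibrated_probabilities():
    rng = np.random.default_rng(12)
    p = rng.uniform(0.1, 0.9, 2000)
    y = (rng.random(2000) < p).astype(float)
    chi2, pval = hosmer_lemeshow(y, p)
    assert pval > 0.01
    assert nagelkerke_r2(-10.0, -10.0, 100) == 0.0


def test_select_predictors_threshold_and_forced():
    res = [("a", 0.24), ("b", 0.26), ("c", 0.0001)]
    assert select_predictors(res, ()) == ["a", "c"]
    assert select_predictors(res, ("b",)) == ["a", "c", "b"]
    assert select_predictors(res, ("a",)) == ["a", "c"]  # no duplicate
    # degenerate: nothing passes, clinical set returned with warning
    assert select_predictors([("a", 0.9)], ("z",)) == ["z"]
    assert select_predictors([("a", 0.9)], ()) == []


def test_table5_style_screen():
    uni = [
        ("age", 0.855), ("gender", 0.146), ("bmi", 0.033), ("smoking", 0.75),
        ("hba1c", 0.949), ("lvef", 0.685), ("arv", 0.0001), ("aasi", 0.0001), ("ppi", 0.0001),
    ]
    assert select_predictors(uni, ()) == ["gender", "bmi", "arv", "aasi", "ppi"]


# ---------------------------------------------------------------------------
# collinearity diagnostics


def test_orthogonal_predictors_unit_vif(rng):
    X = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
    X["y"] = (rng.random(500) < 0.5).astype(int)
    diag = collinearity_diagnostics(X, ["a", "b", "c"], outcome="y")
    assert diag.vif_max == pytest.approx(1.0, abs=0.05)
    assert diag.tolerance_min == pytest.approx(1.0, abs=0.05)
    assert diag.tolerance_min == pytest.approx(1 / diag.vif_max, rel=1e-9)
    assert all(diag.flags.values())


def test_duplicated_predictor_flagged(rng):
    x = rng.normal(size=200)
    cohort = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-8, 200), "c": rng.normal(size=200)})
    diag = collinearity_diagnostics(cohort, ["a", "b", "c"])
    assert diag.vif_max > 1e6
    assert not diag.flags["vif_ok"] and not diag.flags["tolerance_ok"]


def test_vif_matches_definitional_oracle(rng):
    X = rng.normal(size=(300, 3))
    X[:, 2] = 0.7 * X[:, 0] + 0.3 * X[:, 1] + 0.5 * rng.normal(size=300)
    cohort = pd.DataFrame(X, columns=["a", "b", "c"])
    diag = collinearity_diagnostics(cohort, ["a", "b", "c"], standardize=False)
    # independent least-squares oracle for the auxiliary R² of each column
    for i, name in enumerate(["a", "b", "c"]):
        y = X[:, i]
        others = np.column_stack([np.ones(300), np.delete(X, i, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        r2 = 1 - resid.var() / y.var()
        assert diag.vif[name] == pytest.approx(1 / (1 - r2), rel=1e-6)


def test_diagnostics_require_two_predictors(rng):
    cohort = pd.DataFrame({"a": rng.normal(size=50)})
    with pytest.raises(ValueError):
        collinearity_diagnostics(cohort, ["a"])


# ---------------------------------------------------------------------------
# ROC


def test_perfect_separation_roc():
    scores = np.array([1, 2, 3, 10, 11, 12], float)
    labels = np.array([0, 0, 0, 1, 1, 1], float)
    r = roc_analysis(scores, labels)
    assert r.auc == 1.0
    assert r.sensitivity == 1.0 and r.specificity == 1.0
    assert 3 < r.cutoff <= 10


def test_null_scores_auc_half(rng):
    scores = rng.normal(size=3000)
    labels = (rng.random(3000) < 0.5).astype(float)
    r = roc_analysis(scores, labels)
    assert r.auc == pytest.approx(0.5, abs=0.04)
    assert r.ci_low < 0.5 < r.ci_high
    assert r.p_value > 0.01


def test_auc_equals_mann_whitney_identity(rng):
    scores = rng.normal(size=200) + np.repeat([0, 0.8], 100)
    labels = np.repeat([0.0, 1.0], 100)
    u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
    assert roc_analysis(scores, labels).auc == pytest.approx(u / (100 * 100), rel=1e-12)


def _brute_force_youden(scores, labels):
    best = None
    for c in np.concatenate([scores - 1e-9, scores + 1e-9, [scores.min() - 1, scores.max() + 1]]):
        pred = scores >= c
        sens = np.sum(pred & (labels == 1)) / labels.sum()
        spec = np.sum(~pred & (labels == 0)) / (len(labels) - labels.sum())
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, sens, spec)
    return best


def test_youden_cutoff_matches_exhaustive_search(rng):
    for trial in range(50):
        n = int(rng.integers(4, 11))
        scores = np.round(rng.normal(size=n), 2)
        labels = rng.integers(0, 2, n).astype(float)
        if labels.sum() in (0, n):
            continue
        r = roc_analysis(scores, labels)
        j_brute, _, _ = _brute_force_youden(scores, labels)
        assert r.sensitivity + r.specificity - 1 == pytest.approx(j_brute, abs=1e-9)
        # the reported cutoff reproduces the reported operating point
        pred = scores >= r.cutoff
        assert np.sum(pred & (labels == 1)) / labels.sum() == pytest.approx(r.sensitivity)


def test_youden_tie_breaks_toward_specificity():
    # J is tied at several thresholds; the higher-specificity cut must win
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([0.0, 1.0, 0.0, 1.0])
    r = roc_analysis(scores, labels)
    assert r.specificity == 1.0


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_analysis([1.0, 2.0], [1.0, 1.0])


def test_midpoint_cutoff_convention():
    scores = np.array([10.0, 11.0, 14.0, 15.0])
    labels = np.array([0.0, 0.0, 1.0, 1.0])
    assert roc_analysis(scores, labels).cutoff == pytest.approx(12.5)


# ---------------------------------------------------------------------------
# agreement


def test_kappa_perfect_agreement():
    a = ["x", "y", "x", "z", "y"]
    assert cohens_kappa(a, a) == 1.0


def test_kappa_closed_form_2x2():
    # agreement table: both-yes 20, a-yes-b-no 5, a-no-b-yes 10, both-no 15
    a = np.repeat([1, 1, 0, 0], [20, 5, 10, 15])
    b = np.repeat([1, 0, 1, 0], [20, 5, 10, 15])
    p_o = 35 / 50
    p_e = (25 / 50) * (30 / 50) + (25 / 50) * (20 / 50)
    assert cohens_kappa(a, b) == pytest.approx((p_o - p_e) / (1 - p_e), rel=1e-12)


def test_kappa_matches_sklearn(rng):
    from sklearn.metrics import cohen_kappa_score

    a = rng.integers(0, 3, 200)
    b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 3, 200))
    assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), rel=1e-9)


def test_kappa_independent_raters_near_zero(rng):
    a = rng.integers(0, 2, 20000)
    b = rng.integers(0, 2, 20000)
    assert cohens_kappa(a, b) == pytest.approx(0.0, abs=0.03)


def test_kappa_errors():
    with pytest.raises(ValueError):
        cohens_kappa([1, 2], [1])
    with pytest.raises(ValueError):
        cohens_kappa([1, 1], [1, 1])
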