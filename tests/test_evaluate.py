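import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gagdx.evaluate import (
    ThresholdPolicy,
    bootstrap_metrics,
    chi2_from_counts,
    cohort_characteristics,
    combined_test,
    feature_cfdna_correlation,
    roc_auc,
    sensitivity_at_specificity,
    stage_stratified_sensitivity,
    threshold_at_specificity,
)

CONTROLS = np.array([0.1, 0.2, 0.3, 0.9])
CASES = np.array([0.25, 0.8, 1.2, 1.5])
SCORES = np.concatenate([CASES, CONTROLS])
LABELS = np.array(["case"] * 4 + ["control"] * 4)


def brute_force_auc(cases, controls):
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


def brute_force_threshold(scores, labels, min_spec):
    """Exhaustive search over midpoints between sorted unique scores."""
    s = np.asarray(scores, float)
    ctrl = s[labels == "control"]
    case = s[labels == "case"]
    uniq = np.sort(np.unique(s))
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, uniq])
    best_cut, best_sens = None, -1.0
    for c in np.sort(candidates):
        if (ctrl <= c).mean() >= min_spec:
            sens = (case > c).mean()
            if sens > best_sens:
                best_cut, best_sens = c, sens
    return best_cut, best_sens


# -------------------------------------------------------------------- AUC


def test_auc_examples():
    assert roc_auc([10, 11, 12, 0, 1, 2], ["case"] * 3 + ["control"] * 3).auc == 1.0
    assert roc_auc([5.0] * 6, ["case"] * 3 + ["control"] * 3).auc == 0.5
    assert roc_auc(SCORES, LABELS).auc == pytest.approx(13 / 16)


def test_auc_rejects_single_class():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([1.0, 2.0], ["case", "case"])


def test_auc_matches_brute_force_pair_counting():
    rng = np.random.default_rng(21)
    for _ in range(200):
        n1, n0 = rng.integers(1, 26, 2)
        scores = np.round(rng.normal(0, 1, n1 + n0), 1)  # rounding induces ties
        labels = np.array(["case"] * n1 + ["control"] * n0)
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores[:n1], scores[n1:])
        )


@settings(max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(0, 1, 30)
    labels = np.array(["case"] * 12 + ["control"] * 18)
    base = roc_auc(scores, labels).auc
    assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base)
    assert roc_auc(3 * scores - 7, labels).auc == pytest.approx(base)


# -------------------------------------------------------------- thresholds


def test_threshold_examples():
    assert threshold_at_specificity(SCORES, LABELS, 1.0) == 0.9
    sens, cut = sensitivity_at_specificity(SCORES, LABELS, 1.0)
    assert (sens, cut) == (0.5, 0.9)
    assert threshold_at_specificity(SCORES, LABELS, 0.75) == 0.3
    sens, _ = sensitivity_at_specificity(SCORES, LABELS, 0.75)
    assert sens == 0.75


def test_full_specificity_with_separation_gives_full_sensitivity():
    scores = np.array([1.0, 2.0, 3.0, -1.0, -2.0])
    labels = np.array(["case"] * 3 + ["control"] * 2)
    sens, _ = sensitivity_at_specificity(scores, labels, 1.0)
    assert sens == 1.0


def test_sensitivity_non_increasing_in_specificity_floor():
    rng = np.random.default_rng(22)
    scores = rng.normal(0, 1, 60)
    labels = np.array(["case"] * 35 + ["control"] * 25)
    floors = np.linspace(0.05, 1.0, 20)
    sens = [sensitivity_at_specificity(scores, labels, f)[0] for f in floors]
    assert all(a >= b for a, b in zip(sens, sens[1:]))


def test_threshold_matches_exhaustive_search():
    rng = np.random.default_rng(23)
    for _ in range(200):
        n1, n0 = rng.integers(2, 26, 2)
        scores = np.round(rng.normal(0, 1, n1 + n0), 1)
        labels = np.array(["case"] * n1 + ["control"] * n0)
        min_spec = rng.choice([0.5, 0.75, 0.9, 0.95, 1.0])
        cut = threshold_at_specificity(scores, labels, min_spec)
        oracle_cut, oracle_sens = brute_force_threshold(scores, labels, min_spec)
        sens, _ = sensitivity_at_specificity(scores, labels, min_spec)
        assert sens == pytest.approx(oracle_sens)
        ctrl = scores[labels == "control"]
        assert (ctrl <= cut).mean() >= min_spec


# --------------------------------------------------------------- bootstrap


def test_bootstrap_determinism_and_degenerate_B():
    a = bootstrap_metrics(SCORES, LABELS, 0.75, B=200, seed=3)
    b = bootstrap_metrics(SCORES, LABELS, 0.75, B=200, seed=3)
    assert a.auc_ci == b.auc_ci and a.sensitivity_ci == b.sensitivity_ci
    one = bootstrap_metrics(SCORES, LABELS, 0.75, B=1, seed=4)
    assert one.auc_ci[0] == one.auc_ci[1]
    assert one.sensitivity_ci[0] == one.sensitivity_ci[1]


def test_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(24)
    scores = np.concatenate([rng.normal(1, 1, 85), rng.normal(0, 1, 28)])
    labels = np.array(["case"] * 85 + ["control"] * 28)
    summ = bootstrap_metrics(scores, labels, 0.95, B=1000, seed=5)
    assert summ.auc_ci[0] <= summ.auc <= summ.auc_ci[1]
    assert 0 <= summ.sensitivity_ci[0] <= summ.sensitivity_ci[1] <= 1


# ------------------------------------------------------------ combined test


def _toy_combined():
    # 4 controls + 4 cases for both modalities; crafted calls
    labels = np.array(["control"] * 4 + ["case"] * 4)
    gag = np.array([0.0, 0.1, 0.2, 0.3, 0.35, 0.05, 0.4, 0.5])
    cf = np.array([1.0, 1.1, 1.2, 1.3, 1.25, 1.0, 2.0, np.nan])
    status = np.array(["available"] * 7 + ["insufficient"])
    return gag, labels, cf, status


def test_combined_decision_logic():
    gag, labels, cf, status = _toy_combined()
    dec = combined_test(gag, labels, cfdna_scores=cf, cfdna_status=status)
    # cfDNA cut-off at 100% specificity = 1.3; GAGome at min 95% -> max ctrl = 0.3
    assert dec["cfdna_cutoff"].iloc[0] == 1.3
    assert dec["gagome_cutoff"].iloc[0] == 0.3
    d = dec.reset_index(drop=True)
    # case 4: cfDNA negative (1.25 <= 1.3), GAGome positive (0.35 > 0.3)
    assert d.loc[4, "combined_call"] == "positive" and d.loc[4, "reclassified_positive"]
    # case 5: both negative
    assert d.loc[5, "combined_call"] == "negative" and not d.loc[5, "reclassified_positive"]
    # case 6: cfDNA positive -> combined positive, not reclassified
    assert d.loc[6, "cfdna_call"] == "positive" and not d.loc[6, "reclassified_positive"]
    # case 7: insufficient cfDNA counts as negative; GAGome positive -> reclassified
    assert d.loc[7, "cfdna_call"] == "negative" and d.loc[7, "reclassified_positive"]


def test_insufficient_cfdna_with_negative_gagome_is_negative():
    labels = np.array(["control"] * 3 + ["case"])
    gag = np.array([0.5, 0.6, 0.7, 0.2])
    cf = np.array([1.0, 1.1, 1.2, np.nan])
    status = np.array(["available"] * 3 + ["insufficient"])
    dec = combined_test(gag, labels, cfdna_scores=cf, cfdna_status=status)
    assert dec["combined_call"].iloc[3] == "negative"


def test_combined_requires_controls():
    with pytest.raises(ValueError, match="controls"):
        combined_test([1.0, 2.0], np.array(["case", "case"]))


def test_specificity_budget_and_reclassification_accounting():
    rng = np.random.default_rng(25)
    n_case, n_ctrl = 85, 28
    labels = np.array(["case"] * n_case + ["control"] * n_ctrl)
    gag = np.concatenate([rng.normal(0.7, 1, n_case), rng.normal(0, 1, n_ctrl)])
    cf = np.concatenate([rng.normal(1.5, 1, n_case), rng.normal(0, 1, n_ctrl)])
    status = np.array(["available"] * len(labels))
    dec = combined_test(gag, labels, cfdna_scores=cf, cfdna_status=status,
                        gagome_policy=ThresholdPolicy(0.95), cfdna_policy=ThresholdPolicy(1.0))
    ctrl = dec[dec["group"] == "control"]
    combined_spec = (ctrl["combined_call"] == "negative").mean()
    assert combined_spec >= 0.95  # 0 FP budget (cfDNA) + <=5% budget (GAGome)
    n_comb = (dec["combined_call"] == "positive").sum()
    n_cf = (dec["cfdna_call"] == "positive").sum()
    n_recl = dec["reclassified_positive"].sum()
    assert n_comb == n_cf + n_recl


# ------------------------------------------------- stage-stratified metrics


def test_stage_stratified_sensitivity_arithmetic():
    stages = ["I"] * 9 + ["II"] * 4 + ["III"] * 6 + ["IV"] * 3
    n = len(stages)
    dec = pd.DataFrame(
        {
            "group": ["case"] * n,
            "cfdna_call": ["negative"] * n,
            "gagome_call": ["negative"] * n,
            "combined_call": (["positive"] * 5 + ["negative"] * 4   # stage I: 5/9
                              + ["positive"] * 4 + ["negative"] * 6  # II-III: 4/10
                              + ["positive"] * 3),                   # IV: 3/3
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    table = stage_stratified_sensitivity(dec, stages)
    assert table.loc["I", "combined_sensitivity"] == pytest.approx(5 / 9)
    assert round(100 * table.loc["I", "combined_sensitivity"], 1) == 55.6
    assert table.loc["II-III", "combined_sensitivity"] == pytest.approx(0.40)
    assert table.loc["IV", "combined_sensitivity"] == 1.0
    assert not table["empty"].any()


def test_empty_stratum_flagged():
    dec = pd.DataFrame(
        {"group": ["case", "control"], "cfdna_call": ["positive", "negative"],
         "gagome_call": ["positive", "negative"], "combined_call": ["positive", "negative"]},
        index=pd.Index(["a", "b"], name="sample_id"),
    )
    table = stage_stratified_sensitivity(dec, ["IV", "none"])
    assert table.loc["I", "empty"] and np.isnan(table.loc["I", "combined_sensitivity"])
    assert table.loc["IV", "combined_sensitivity"] == 1.0


# --------------------------------------------------- correlation and tests


def test_rank_correlation_properties():
    rng = np.random.default_rng(26)
    x = rng.gamma(2, 1, 50)
    feats = pd.DataFrame({"f": x})
    out = feature_cfdna_correlation(feats, pd.DataFrame({"same": x, "mono": np.exp(x)}))
    assert np.allclose(out["rho"], 1.0)
    indep = feature_cfdna_correlation(
        pd.DataFrame({"f": rng.normal(0, 1, 1000)}),
        pd.DataFrame({"g": rng.normal(0, 1, 1000)}),
    )
    assert abs(indep["rho"].iloc[0]) < 0.1


def test_correlation_requires_three_complete_pairs():
    feats = pd.DataFrame({"f": [1.0, 2.0, np.nan]})
    cf = pd.DataFrame({"g": [1.0, np.nan, 3.0]})
    with pytest.raises(ValueError, match="fewer than 3"):
        feature_cfdna_correlation(feats, cf)


def test_smoking_contingency_reproduces_published_p_value():
    chi2, dof, p = chi2_from_counts([30, 43, 12], [5, 12, 9])
    assert chi2 == pytest.approx(6.13, abs=0.005)
    assert dof == 2
    assert round(p, 3) == 0.047
    assert p == pytest.approx(np.exp(-chi2 / 2), abs=1e-12)


def test_identical_proportions_give_zero_chi2():
    chi2, dof, p = chi2_from_counts([10, 20, 30], [1, 2, 3])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=80), min_size=3, max_size=3),
       st.lists(st.integers(min_value=1, max_value=80), min_size=3, max_size=3))
def test_df2_chi2_p_equals_closed_form(a, b):
    chi2, dof, p = chi2_from_counts(a, b)
    assert dof == 2
    assert p == pytest.approx(float(np.exp(-chi2 / 2)), abs=1e-12)


def test_cohort_characteristics_table(default_cohort):
    samples, _, _ = default_cohort
    table = cohort_characteristics(samples)
    assert set(table["variable"]) == {"sex", "smoking", "age_years"}
    smoking = table[table["variable"] == "smoking"].iloc[0]
    assert smoking["test"] == "chi2" and smoking["df"] == 2
    assert table["p_value"].between(0, 1).all()
    # Welch (default) and classical Student forms both computable
    student = cohort_characteristics(samples, equal_var=True)
    assert len(student) == len(table)


def test_cohort_characteristics_requires_both_groups():
    df = pd.DataFrame({"group": ["case", "case"], "sex": ["f", "m"],
                       "smoking": ["never", "ex"], "age_years": [60, 70]})
    with pytest.raises(ValueError, match="both cases and controls"):
        cohort_characteristics(df)
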