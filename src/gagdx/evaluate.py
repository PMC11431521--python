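"""Diagnostic performance evaluation.

ROC/AUC with Mann-Whitney tie handling, threshold calibration under a
specificity floor, stratified bootstrap confidence intervals, the sequential
cfDNA → GAGome combined test with its specificity budget, stage-stratified
sensitivity, rank-correlation independence checks, and the cohort
characteristics table (Pearson χ² / t-tests).

Positivity convention throughout: a sample is positive when its score is
strictly above the cut-off, and cut-offs are calibrated by choosing the
smallest control score value whose implied specificity meets the floor
(maximal sensitivity subject to the constraint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve


# --------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    auc: float
    #: ordered (specificity, sensitivity) pairs along the ROC curve
    curve: pd.DataFrame
    tie_note: str = "ties between case and control scores count 1/2 (Mann-Whitney)"


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype == bool:
        is_case = lab
    else:
        is_case = lab == "case"
    cases, controls = s[is_case], s[~is_case]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray) -> float:
    # rank-based U statistic: exact pair counting with ties at 1/2
    pooled = np.concatenate([controls, cases])
    ranks = stats.rankdata(pooled)
    u = ranks[len(controls):].sum() - len(cases) * (len(cases) + 1) / 2.0
    return float(u / (len(cases) * len(controls)))


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC; AUC equals the Mann-Whitney P(case score > control score)."""
    cases, controls = _split_scores(scores, labels)
    auc = _auc_mann_whitney(cases, controls)
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    fpr, tpr, _ = roc_curve(y, np.concatenate([cases, controls]))
    curve = pd.DataFrame({"specificity": 1.0 - fpr, "sensitivity": tpr})
    return RocResult(auc=auc, curve=curve)


# --------------------------------------------------------------------------
# Thresholds under a specificity floor


def threshold_at_specificity(scores, labels, min_spec: float) -> float:
    """Smallest cut-off achieving specificity >= ``min_spec`` on the controls.

    Positives are scores strictly above the cut-off, so specificity at
    cut-off c is the fraction of controls <= c. The returned cut-off is a
    control score value (or -inf when the floor is vacuous), which maximizes
    sensitivity subject to the constraint.
    """
    if not 0 < min_spec <= 1:
        raise ValueError("min_spec must be in (0, 1]")
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    is_case = lab if lab.dtype == bool else lab == "case"
    controls = s[~is_case]
    if len(controls) == 0:
        raise ValueError("no controls: cut-off cannot be calibrated")
    ctrl_sorted = np.sort(controls)
    k = int(np.ceil(min_spec * len(controls)))
    if k == 0:
        return float("-inf")
    return float(ctrl_sorted[k - 1])


def sensitivity_at_specificity(scores, labels, min_spec: float) -> tuple[float, float]:
    """Sensitivity attained when the cut-off is calibrated to the floor."""
    cases, _ = _split_scores(scores, labels)
    cut = threshold_at_specificity(scores, labels, min_spec)
    return float((cases > cut).mean()), cut


# --------------------------------------------------------------------------
# Stratified bootstrap


@dataclass
class BootstrapSummary:
    """Point estimates and percentile 95% CIs from a stratified bootstrap."""

    B: int
    seed: int
    min_spec: float
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    cutoff: float
    specificity_ci: tuple[float, float] = field(default=(float("nan"), float("nan")))


def bootstrap_metrics(scores, labels, min_spec: float, B: int = 5000, seed: int = 0) -> BootstrapSummary:
    """Bootstrap AUC and sensitivity-at-specificity.

    Cases and controls are resampled separately (group sizes preserved), the
    cut-off is recalibrated inside every replicate, and 95% CIs are the
    2.5/97.5 percentiles of the replicate distribution.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cases, controls = _split_scores(scores, labels)
    n_case, n_ctrl = len(cases), len(controls)
    rng = np.random.default_rng(seed)

    case_idx = rng.integers(0, n_case, size=(B, n_case))
    ctrl_idx = rng.integers(0, n_ctrl, size=(B, n_ctrl))
    case_rs = cases[case_idx]
    ctrl_rs = np.sort(controls[ctrl_idx], axis=1)

    k = int(np.ceil(min_spec * n_ctrl))
    cutoffs = ctrl_rs[:, k - 1] if k > 0 else np.full(B, -np.inf)
    sens = (case_rs > cutoffs[:, None]).mean(axis=1)
    # specificity realized at the replicate's own cut-off
    spec = (ctrl_rs <= cutoffs[:, None]).mean(axis=1)
    aucs = np.array([_auc_mann_whitney(case_rs[b], ctrl_rs[b]) for b in range(B)])

    point_sens, cut = sensitivity_at_specificity(scores, labels, min_spec)
    return BootstrapSummary(
        B=B,
        seed=seed,
        min_spec=min_spec,
        auc=_auc_mann_whitney(cases, controls),
        auc_ci=(float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))),
        sensitivity=point_sens,
        sensitivity_ci=(float(np.percentile(sens, 2.5)), float(np.percentile(sens, 97.5))),
        cutoff=cut,
        specificity_ci=(float(np.percentile(spec, 2.5)), float(np.percentile(spec, 97.5))),
    )


# --------------------------------------------------------------------------
# Sequential combined test


@dataclass
class ThresholdPolicy:
    """Specificity floor and the strictly-above positivity rule."""

    min_specificity: float

    def __post_init__(self) -> None:
        if not 0 < self.min_specificity <= 1:
            raise ValueError("min_specificity must be in (0, 1]")


def combined_test(
    gagome_scores,
    labels,
    cfdna_scores=None,
    cfdna_status=None,
    gagome_policy: ThresholdPolicy = ThresholdPolicy(0.95),
    cfdna_policy: ThresholdPolicy = ThresholdPolicy(1.00),
    sample_ids=None,
) -> pd.DataFrame:
    """The sequential cfDNA → GAGome combined test.

    Procedure: (1) calibrate the cfDNA cut-off at a minimum 100% specificity
    on controls with an available cfDNA score; (2) calibrate the GAGome
    cut-off at a minimum 95% specificity; (3) call each score positive when
    strictly above its cut-off, with samples whose cfDNA is insufficient or
    missing treated as cfDNA-negative; (4) combined positive if at least one
    sub-call is positive; (5) flag cfDNA-negative / GAGome-positive samples
    as reclassified positives.

    Returns one row per sample: cfdna_call, gagome_call, combined_call,
    reclassified_positive, plus the group label and the cut-offs used.
    """
    g = np.asarray(gagome_scores, dtype=float)
    lab = np.asarray(labels)
    n = len(g)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    is_control = ~(lab == "case") if lab.dtype != bool else ~lab
    if not is_control.any():
        raise ValueError("no controls: cut-offs cannot be calibrated")

    gag_cut = threshold_at_specificity(g, lab, gagome_policy.min_specificity)
    gag_pos = g > gag_cut

    if cfdna_scores is None:
        cf_pos = np.zeros(n, dtype=bool)
        cf_cut = float("nan")
    else:
        cf = np.asarray(cfdna_scores, dtype=float)
        status = (
            np.asarray(cfdna_status)
            if cfdna_status is not None
            else np.where(np.isnan(cf), "missing", "available")
        )
        usable = status == "available"
        ctrl_usable = usable & is_control
        if not ctrl_usable.any():
            raise ValueError("no controls with available cfDNA: cut-off cannot be calibrated")
        cf_cut = threshold_at_specificity(
            cf[usable], lab[usable], cfdna_policy.min_specificity
        )
        cf_pos = np.zeros(n, dtype=bool)
        cf_pos[usable] = cf[usable] > cf_cut  # insufficient/missing stay negative

    combined = cf_pos | gag_pos
    reclassified = ~cf_pos & gag_pos
    return pd.DataFrame(
        {
            "group": lab,
            "cfdna_call": np.where(cf_pos, "positive", "negative"),
            "gagome_call": np.where(gag_pos, "positive", "negative"),
            "combined_call": np.where(combined, "positive", "negative"),
            "reclassified_positive": reclassified,
            "gagome_cutoff": gag_cut,
            "cfdna_cutoff": cf_cut,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


#: Reporting strata: stage I, pooled II–III, and IV.
STAGE_STRATA: dict[str, tuple[str, ...]] = {"I": ("I",), "II-III": ("II", "III"), "IV": ("IV",)}


def stage_stratified_sensitivity(
    decisions: pd.DataFrame,
    stages,
    calls: tuple[str, ...] = ("cfdna_call", "gagome_call", "combined_call"),
) -> pd.DataFrame:
    """Per-stage sensitivity of each call among cases.

    ``stages`` is aligned with ``decisions``; strata are stage I, pooled
    II–III, and IV. Empty strata get NaN sensitivity and are flagged.
    """
    st = pd.Series(np.asarray(stages), index=decisions.index)
    is_case = decisions["group"] == "case"
    rows = []
    for name, members in STAGE_STRATA.items():
        mask = is_case & st.isin(members)
        n = int(mask.sum())
        row: dict = {"stratum": name, "n_cases": n}
        for call in calls:
            if n == 0:
                row[call.replace("_call", "_sensitivity")] = float("nan")
            else:
                row[call.replace("_call", "_sensitivity")] = float(
                    (decisions.loc[mask, call] == "positive").mean()
                )
        row["empty"] = n == 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


# --------------------------------------------------------------------------
# Independence checks and cohort characteristics


def feature_cfdna_correlation(features: pd.DataFrame, cfdna: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of each feature against each cfDNA measure.

    Only pairwise-complete observations are used; fewer than 3 complete
    pairs is an error.
    """
    rows = []
    for fname in features.columns:
        for cname in cfdna.columns:
            pair = pd.concat([features[fname], cfdna[cname]], axis=1).dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for ({fname!r}, {cname!r})"
                )
            rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append(
                {"feature": fname, "cfdna_measure": cname, "rho": float(rho),
                 "p_value": float(p), "n": len(pair)}
            )
    return pd.DataFrame(rows)


def cohort_characteristics(
    samples: pd.DataFrame,
    categorical: tuple[str, ...] = ("sex", "smoking"),
    continuous: tuple[str, ...] = ("age_years",),
    equal_var: bool = False,
) -> pd.DataFrame:
    """Case-vs-control tests of the cohort table.

    Categorical variables: Pearson χ² without continuity correction, with a
    ``missing`` category excluded. Continuous variables: two-sample t-test
    (unequal-variance Welch form by default; ``equal_var=True`` for the
    classical Student form).
    """
    if "group" not in samples.columns:
        raise ValueError("samples table must have a 'group' column")
    is_case = samples["group"] == "case"
    if not is_case.any() or is_case.all():
        raise ValueError("both cases and controls are required")

    rows = []
    for var in categorical:
        sub = samples[samples[var].astype(str) != "missing"]
        table = pd.crosstab(sub[var], sub["group"] == "case")
        if (table.to_numpy().sum(axis=1) == 0).any() or table.shape[1] < 2:
            raise ValueError(f"degenerate contingency table for {var!r}")
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        if (expected == 0).any():
            raise ValueError(f"zero expected cell count for {var!r}")
        rows.append({"variable": var, "test": "chi2", "statistic": float(chi2),
                     "df": int(dof), "p_value": float(p)})
    for var in continuous:
        x = samples.loc[is_case, var].dropna().astype(float)
        z = samples.loc[~is_case, var].dropna().astype(float)
        t, p = stats.ttest_ind(x, z, equal_var=equal_var)
        rows.append({"variable": var, "test": "t", "statistic": float(t),
                     "df": float("nan"), "p_value": float(p)})
    return pd.DataFrame(rows)


def chi2_from_counts(counts_case, counts_control) -> tuple[float, int, float]:
    """Pearson χ² (no continuity correction) from two count vectors.

    Returns (statistic, df, p). For df = 2 the p-value equals exp(-χ²/2),
    the closed form of the χ²₂ survival function.
    """
    table = np.array([counts_case, counts_control], dtype=float).T
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected == 0).any():
        raise ValueError("zero expected cell count")
    return float(chi2), int(dof), float(p)
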