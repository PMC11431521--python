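"""End-to-end orchestration: simulate/load → features → screen → score →
combine → report.

The pipeline reproduces the analysis flow of a two-modality liquid-biopsy
study: expand GAGome features, keep the detectable ones, screen them with the
Bayesian ROPE rule (adjusted for batch and sample age), fit the GAGome and
cfDNA logistic scores, calibrate thresholds under the specificity budget
(cfDNA at 100%, GAGome at 95%), run the sequential combined test and report
metrics with stratified-bootstrap confidence intervals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, evaluate, features as feat
from .cohort import SimulationParams, default_params, read_cohort_csv, simulate_cohort

logger = logging.getLogger("gagdx")


@dataclass
class PipelineConfig:
    """Everything one run needs; fully serializable for provenance."""

    simulation: SimulationParams | None = None
    samples_path: str | None = None
    gagome_path: str | None = None

    lod: float = 0.1
    priors: bayes.PriorSpec = field(default_factory=bayes.PriorSpec)
    mcmc: bayes.McmcConfig = field(default_factory=bayes.McmcConfig)
    rope: bayes.RopeSpec = field(default_factory=bayes.RopeSpec)

    #: Detectable-set override; None applies the median-above-LOD rule.
    detectable_override: tuple[str, ...] | None = None
    #: Predictors of the GAGome score (batch-normalized before fitting).
    score_predictors: tuple[str, ...] = ("0S CS", "4S CS fraction")

    min_spec_gagome: float = 0.95
    min_spec_cfdna: float = 1.00
    bootstrap_B: int = 5000
    include_cfdna: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config_hash: str
    samples: pd.DataFrame
    gagome: pd.DataFrame
    features: feat.FeatureTable
    detectability: feat.DetectabilityResult
    selected_features: list[str]
    equivalence: pd.DataFrame
    gagome_model: bayes.ScoreModel
    cfdna_model: bayes.ScoreModel | None
    scores: pd.DataFrame
    decisions: pd.DataFrame | None
    metrics: dict
    report: str


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis; optionally archive all outputs under ``outdir``."""
    seeds = _stage_seeds(config.seed)

    # ---- data ------------------------------------------------------------
    if config.samples_path and config.gagome_path:
        samples, gagome = read_cohort_csv(config.samples_path, config.gagome_path)
        truth = None
        logger.info("loaded cohort: %d samples", len(samples))
    else:
        params = config.simulation or default_params()
        samples, gagome, truth = simulate_cohort(params, seed=seeds[0])
        logger.info("simulated cohort: %d samples (seed %d)", len(samples), seeds[0])
    labels = samples["group"].to_numpy()

    # ---- features ---------------------------------------------------------
    table = feat.expand_features_table(gagome)
    logger.info("expanded features: %d samples x %d features", *table.values.shape)

    det = feat.detectable_features(gagome, lod=config.lod)
    if config.detectable_override is not None:
        det = feat.DetectabilityResult(lod=config.lod, medians=det.medians)
        det.detectable = tuple(config.detectable_override)
    selected = feat.select_analysis_features(det)
    logger.info("detectable disaccharides: %s -> %d analysis features",
                list(det.detectable), len(selected))

    # ---- ROPE screen (adjusted for batch and sample age) -------------------
    covariates = samples[["batch", "sample_age_months"]]
    decisions_eq = []
    for j, name in enumerate(selected):
        avail = table.available[name]
        if not avail.all():
            logger.warning("feature %s unavailable for %d samples; screening on the rest",
                           name, int((~avail).sum()))
        idx = avail[avail].index
        z, _, _ = bayes.standardize(table.values.loc[idx, name].to_numpy())
        draws = bayes.fit_linear_group_model(
            z,
            samples.loc[idx, "group"].to_numpy(),
            covariates=covariates.loc[idx],
            priors=config.priors,
            mcmc=dataclasses.replace(config.mcmc, seed=(seeds[1] + j) % 2**31),
        )
        decisions_eq.append(bayes.rope_decision(draws, "group", config.rope, feature=name))
    equivalence = pd.DataFrame([dataclasses.asdict(d) for d in decisions_eq])
    credible = list(equivalence.loc[equivalence["credible"], "feature"]) if len(equivalence) else []
    logger.info("screen: %d/%d features credible", len(credible), len(selected))

    # ---- GAGome score -----------------------------------------------------
    predictors = list(config.score_predictors)
    not_screened = [p for p in predictors if p not in credible]
    if not_screened:
        logger.warning("score predictors not credible in this cohort's screen: %s", not_screened)
    X_gag = table.values[predictors]
    X_gag_norm = bayes.batch_normalize(X_gag, samples["batch"])
    gag_model = bayes.fit_logistic_score(
        X_gag_norm, labels, priors=config.priors,
        mcmc=dataclasses.replace(config.mcmc, seed=seeds[2]),
    )
    gag_scores = gag_model.predict(X_gag_norm)
    scores = pd.DataFrame({"gagome_score": gag_scores}, index=samples.index)

    gag_boot = evaluate.bootstrap_metrics(
        gag_scores, labels, config.min_spec_gagome, B=config.bootstrap_B, seed=seeds[3]
    )
    metrics: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_case": int((labels == "case").sum()),
        "n_control": int((labels == "control").sum()),
        "detectable": list(det.detectable),
        "n_features": int(table.values.shape[1]),
        "n_screened": len(selected),
        "credible_features": credible,
        "gagome": {
            "predictors": predictors,
            "auc": gag_boot.auc,
            "auc_ci": list(gag_boot.auc_ci),
            "sensitivity": gag_boot.sensitivity,
            "sensitivity_ci": list(gag_boot.sensitivity_ci),
            "specificity_ci": list(gag_boot.specificity_ci),
            "min_specificity": config.min_spec_gagome,
            "cutoff": gag_boot.cutoff,
            "bootstrap_B": config.bootstrap_B,
        },
    }

    # ---- cfDNA score and combined test -------------------------------------
    cf_model = None
    decisions = None
    has_cfdna = (
        config.include_cfdna
        and "cfdna_conc" in samples.columns
        and samples["cfdna_status"].eq("available").any()
    )
    if has_cfdna:
        ngs = samples["cfdna_status"] == "available"
        X_cf = pd.DataFrame(
            {
                "log cfDNA": np.log(samples.loc[ngs, "cfdna_conc"].astype(float)),
                "cfDNA variants": samples.loc[ngs, "cfdna_variants"].astype(float),
            }
        )
        if samples.loc[ngs, "group"].nunique() < 2:
            logger.warning("cfDNA subset has a single class; skipping cfDNA stage")
            has_cfdna = False
        else:
            cf_model = bayes.fit_logistic_score(
                X_cf, samples.loc[ngs, "group"].to_numpy(), priors=config.priors,
                mcmc=dataclasses.replace(config.mcmc, seed=seeds[4]),
            )
            scores["cfdna_score"] = np.nan
            scores.loc[ngs, "cfdna_score"] = cf_model.predict(X_cf)

            subset = samples["cfdna_status"] != "missing"
            decisions = evaluate.combined_test(
                scores.loc[subset, "gagome_score"].to_numpy(),
                samples.loc[subset, "group"].to_numpy(),
                cfdna_scores=scores.loc[subset, "cfdna_score"].to_numpy(),
                cfdna_status=samples.loc[subset, "cfdna_status"].to_numpy(),
                gagome_policy=evaluate.ThresholdPolicy(config.min_spec_gagome),
                cfdna_policy=evaluate.ThresholdPolicy(config.min_spec_cfdna),
                sample_ids=samples.index[subset],
            )
            logger.info("combined test on %d samples with cfDNA data", int(subset.sum()))

            cf_boot = evaluate.bootstrap_metrics(
                scores.loc[ngs, "cfdna_score"].to_numpy(),
                samples.loc[ngs, "group"].to_numpy(),
                config.min_spec_cfdna, B=config.bootstrap_B, seed=seeds[5],
            )
            sub_case = decisions["group"] == "case"
            cf_pos = decisions["cfdna_call"] == "positive"
            comb_pos = decisions["combined_call"] == "positive"
            stage_table = evaluate.stage_stratified_sensitivity(
                decisions, samples.loc[subset, "stage"].to_numpy()
            )
            reclassified = decisions["reclassified_positive"]
            cf_false_neg = sub_case & ~cf_pos
            metrics["cfdna"] = {
                "n_scored": int(ngs.sum()),
                "n_insufficient": int((samples["cfdna_status"] == "insufficient").sum()),
                "auc": cf_boot.auc,
                "auc_ci": list(cf_boot.auc_ci),
                "sensitivity_scored_subset": cf_boot.sensitivity,
                "sensitivity_ci": list(cf_boot.sensitivity_ci),
                "sensitivity_incl_insufficient": float((sub_case & cf_pos).sum() / sub_case.sum()),
                "min_specificity": config.min_spec_cfdna,
                "cutoff": cf_boot.cutoff,
            }
            metrics["combined"] = {
                "n": int(subset.sum()),
                "sensitivity": float((sub_case & comb_pos).sum() / sub_case.sum()),
                "specificity": float((~sub_case & ~comb_pos).sum() / (~sub_case).sum()),
                "reclassified_positives": int(reclassified.sum()),
                "reclassified_true_positives": int((reclassified & sub_case).sum()),
                "cfdna_false_negative_cases": int(cf_false_neg.sum()),
                "stage_sensitivity": stage_table.reset_index().to_dict(orient="records"),
            }

            # independence of score features from cfDNA measures
            corr = evaluate.feature_cfdna_correlation(
                table.values.loc[ngs, predictors],
                samples.loc[ngs, ["cfdna_conc", "cfdna_variants"]],
            )
            metrics["feature_cfdna_correlation"] = corr.to_dict(orient="records")
    if not has_cfdna:
        logger.info("cfDNA data unavailable or disabled; combined stage skipped")
        metrics["cfdna"] = None
        metrics["combined"] = None

    # ---- cohort characteristics and report ---------------------------------
    try:
        char = evaluate.cohort_characteristics(samples)
        metrics["cohort_characteristics"] = char.to_dict(orient="records")
    except (ValueError, KeyError) as exc:
        logger.warning("cohort characteristics skipped: %s", exc)
        char = None

    report = render_report(metrics, decisions, equivalence, char)
    result = PipelineResult(
        config_hash=metrics["config_hash"],
        samples=samples,
        gagome=gagome,
        features=table,
        detectability=det,
        selected_features=selected,
        equivalence=equivalence,
        gagome_model=gag_model,
        cfdna_model=cf_model,
        scores=scores,
        decisions=decisions,
        metrics=metrics,
        report=report,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        samples.to_csv(outdir / "samples.csv")
        feat.write_gagome_csv(gagome, outdir / "gagome.csv")
        feat.write_features_csv(table, outdir / "features.csv")
        equivalence.to_csv(outdir / "equivalence.csv", index=False)
        scores.to_csv(outdir / "scores.csv")
        if decisions is not None:
            decisions.to_csv(outdir / "decisions.csv")
        gag_model.to_json(outdir / "gagome_model.json")
        if cf_model is not None:
            cf_model.to_json(outdir / "cfdna_model.json")
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
        (outdir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True, default=str)
        )
        (outdir / "report.md").write_text(report)
        if truth is not None:
            (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        logger.info("outputs written to %s", outdir)
    return result


def _pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def render_report(
    metrics: dict,
    decisions: pd.DataFrame | None,
    equivalence: pd.DataFrame | None = None,
    characteristics: pd.DataFrame | None = None,
) -> str:
    """Human-readable markdown summary of one pipeline run."""
    lines = ["# GAGome + cfDNA diagnostic pipeline report", ""]
    lines.append(f"Config hash: `{metrics.get('config_hash', 'n/a')}`  |  seed: {metrics.get('seed')}")
    lines.append("")
    lines.append("## Cohort")
    n_case, n_control = metrics.get("n_case", 0), metrics.get("n_control", 0)
    if n_case + n_control == 0:
        lines += ["", "No samples."]
    else:
        lines.append(f"- {n_case} cases, {n_control} controls")
        if characteristics is not None and len(characteristics):
            lines.append("")
            lines.append("| variable | test | statistic | p |")
            lines.append("|---|---|---|---|")
            for _, r in characteristics.iterrows():
                lines.append(
                    f"| {r['variable']} | {r['test']} | {r['statistic']:.3f} | {r['p_value']:.3f} |"
                )
    lines.append("")
    lines.append("## Feature screen")
    lines.append(
        f"- {metrics.get('n_features', 0)} expanded features; detectable disaccharides: "
        f"{', '.join(metrics.get('detectable', [])) or 'none'}"
    )
    lines.append(f"- {metrics.get('n_screened', 0)} features screened; credible: "
                 f"{', '.join(metrics.get('credible_features', [])) or 'none'}")
    if equivalence is not None and len(equivalence):
        lines.append("")
        lines.append("| feature | mean | 95% CI | ROPE overlap | credible |")
        lines.append("|---|---|---|---|---|")
        for _, r in equivalence.iterrows():
            lines.append(
                f"| {r['feature']} | {r['mean']:.2f} | [{r['ci_low']:.2f}, {r['ci_high']:.2f}] "
                f"| {_pct(r['rope_overlap'])} | {'yes' if r['credible'] else 'no'} |"
            )
    lines.append("")
    g = metrics.get("gagome")
    if g:
        lines.append("## GAGome score")
        lines.append(
            f"- AUC {g['auc']:.2f} (95% CI {g['auc_ci'][0]:.2f}-{g['auc_ci'][1]:.2f}); "
            f"sensitivity {_pct(g['sensitivity'])} "
            f"(95% CI {_pct(g['sensitivity_ci'][0])}-{_pct(g['sensitivity_ci'][1])}) "
            f"at minimum {_pct(g['min_specificity'])} specificity"
        )
        lines.append("")
    c = metrics.get("cfdna")
    comb = metrics.get("combined")
    if c and comb:
        lines.append("## cfDNA score and combined test")
        lines.append(
            f"- cfDNA AUC {c['auc']:.2f} (95% CI {c['auc_ci'][0]:.2f}-{c['auc_ci'][1]:.2f}); "
            f"sensitivity {_pct(c['sensitivity_incl_insufficient'])} at minimum "
            f"{_pct(c['min_specificity'])} specificity (insufficient cfDNA counted negative)"
        )
        lines.append(
            f"- combined test (n={comb['n']}): sensitivity {_pct(comb['sensitivity'])}, "
            f"specificity {_pct(comb['specificity'])}; "
            f"{comb['reclassified_positives']} reclassified positives "
            f"({comb['reclassified_true_positives']} of them cases)"
        )
        lines.append("")
        lines.append("| stratum | n cases | cfDNA sens | GAGome sens | combined sens |")
        lines.append("|---|---|---|---|---|")
        for r in comb["stage_sensitivity"]:
            def _fmt(v):
                return "n/a" if v != v else _pct(v)
            lines.append(
                f"| {r['stratum']} | {r['n_cases']} | {_fmt(r['cfdna_sensitivity'])} "
                f"| {_fmt(r['gagome_sensitivity'])} | {_fmt(r['combined_sensitivity'])} |"
            )
    else:
        lines.append("## cfDNA score and combined test")
        lines.append("- no cfDNA data: combined stage skipped")
    if decisions is None or len(decisions) == 0:
        lines.append("")
        lines.append("No per-sample decisions (no samples entered the combined test).")
    lines.append("")
    return "\n".join(lines)
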