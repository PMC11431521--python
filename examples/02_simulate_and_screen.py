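"""Simulate a synthetic cohort and screen GAGome features with the ROPE rule.

The generator draws 85 lung-cancer cases and 28 benign controls with a higher
0S CS concentration and lower 4S CS fraction in cases, batch and sample-age
nuisance effects, and 15 disaccharides below the 0.1 µg/mL detection limit.
Each detectable-feature candidate is standardized and regressed on disease
state (adjusted for batch and sample age) with Student-t(7, 0, 2) priors; a
feature is credible when its 95% interval excludes zero and at most 10% of
the in-interval posterior mass lies in the ROPE [-0.1, 0.1].
"""

from gagdx import bayes, detectable_features, expand_features_table, select_analysis_features, simulate_cohort

samples, gagome, _ = simulate_cohort(seed=11)
det = detectable_features(gagome, lod=0.1)
selected = select_analysis_features(det)
print(f"detectable disaccharides: {det.detectable}")
print(f"analysis features: {selected}\n")

table = expand_features_table(gagome)
mcmc = bayes.McmcConfig(chains=4, iterations=2000, warmup=500, seed=1)
print(f"{'feature':18s} {'mean':>6s} {'95% interval':>16s} {'ROPE%':>6s}  credible")
for name in selected:
    z, _, _ = bayes.standardize(table.values[name].to_numpy())
    draws = bayes.fit_linear_group_model(
        z, samples["group"].to_numpy(),
        covariates=samples[["batch", "sample_age_months"]], mcmc=mcmc,
    )
    d = bayes.rope_decision(draws, "group", feature=name)
    print(f"{name:18s} {d.mean:6.2f} [{d.ci_low:6.2f}, {d.ci_high:5.2f}] "
          f"{100 * d.rope_overlap:5.1f}%  {'yes' if d.credible else 'no'}")

print(
    "\nThe group coefficient is the case-control difference in standardized"
    "\nunits. Positive means higher in cases (0S CS concentration); negative"
    "\nmeans lower (4S CS fraction). 'ROPE%' is the share of the in-interval"
    "\nposterior mass inside the negligible-effect region."
)
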