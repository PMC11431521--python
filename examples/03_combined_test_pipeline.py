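"""Run the full diagnostic pipeline and print the combined-test metrics.

Fits the GAGome score (0S CS concentration + 4S CS fraction, batch-normalized,
Bayesian logistic regression) on all 113 samples and the cfDNA score
(log concentration + variant count) on the 74 samples with sequencing data,
then applies the sequential combined test: cfDNA cut-off at minimum 100%
specificity, GAGome cut-off at minimum 95% specificity, positive if either
score is positive — spending the one allowed false positive on the GAGome arm.
"""

from gagdx import PipelineConfig, bayes, run_pipeline

config = PipelineConfig(
    seed=11,
    mcmc=bayes.McmcConfig(chains=4, iterations=2000, warmup=500),
    bootstrap_B=1000,
)
result = run_pipeline(config)
m = result.metrics

g, c, comb = m["gagome"], m["cfdna"], m["combined"]
print(f"GAGome score  : AUC {g['auc']:.2f} "
      f"(95% CI {g['auc_ci'][0]:.2f}-{g['auc_ci'][1]:.2f}), "
      f"sensitivity {100 * g['sensitivity']:.1f}% at >=95% specificity (n=113)")
print(f"cfDNA score   : AUC {c['auc']:.2f}, "
      f"sensitivity {100 * c['sensitivity_incl_insufficient']:.1f}% at 100% specificity "
      f"(n={comb['n']}, insufficient cfDNA counted negative)")
print(f"combined test : sensitivity {100 * comb['sensitivity']:.1f}%, "
      f"specificity {100 * comb['specificity']:.1f}% (n={comb['n']})")
print(f"reclassified positives (cfDNA-negative, GAGome-positive): "
      f"{comb['reclassified_positives']} ({comb['reclassified_true_positives']} cases)")
print("\nPer-stage sensitivity (combined vs cfDNA alone):")
for row in comb["stage_sensitivity"]:
    print(f"  stage {row['stratum']:6s} n={row['n_cases']:3d}  "
          f"combined {100 * row['combined_sensitivity']:5.1f}%  "
          f"cfdna {100 * row['cfdna_sensitivity']:5.1f}%")
print(
    "\nThe combined test recovers cfDNA false negatives (mostly early-stage"
    "\ncases, whose cfDNA signal is weak) while keeping the overall"
    "\nspecificity at or above 95% on the calibration controls."
)
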