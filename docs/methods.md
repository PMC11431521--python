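# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `gagdx`.

## The GAGome feature space

A measured plasma GAGome is the vector of absolute concentrations (µg/mL) of
17 disaccharides: 8 chondroitin sulfate (CS) sulfation forms (0S, 2S, 6S,
4S, 2S6S, 2S4S, 4S6S, TriS), 8 heparan sulfate (HS) forms (0S, 2S, 6S, NS,
NS6S, NS2S, 2S6S, TriS) and 1 hyaluronic acid (HA) form (0S). Expansion adds
22 derived features:

* `total CS` / `total HS` — sums of the class concentrations (µg/mL);
* 16 mass fractions — 100 · c(d) / total(class), in µg/µg%;
* `CS charge` / `HS charge` — Σ_d sulfo(d) · fraction(d)/100, a
  dimensionless summary of average class sulfation in [0, 3];
* `4S CS/0S CS` and `6S CS/0S CS` concentration ratios.

**Charge basis.** "Weighted sum of the sulfated disaccharides" could be read
over absolute concentrations or fractions; we compute it over mass fractions
(÷100), which yields a dimensionless quantity consistent with the `[-]` unit
convention and makes the charge invariant to overall class abundance.

**Unavailability instead of NaN.** Any feature whose denominator is zero or
whose constituents are missing is marked *unavailable*; downstream filters
branch on the flag rather than on NaN propagation, which keeps selection
deterministic. Below-LOD measured values are retained as reported in derived
arithmetic — the detectability rule gates which features are analyzed, not
which values enter a formula.

**Detectability and selection.** A disaccharide is detectable when its
cohort median (over present values; midpoint convention for even counts)
strictly exceeds the LOD, default 0.1 µg/mL; HA is subject to the same rule
as everything else. The analysis set derived from a detectable set D is:
concentrations of d ∈ D; fractions whose numerator is in D; ratios with both
numerator and denominator in D; a class total if at least one constituent is
in D; a class charge only if all eight constituents are in D (its formula
involves every fraction of the class). For D = {0S CS, 4S CS} this yields
exactly six features (0S CS, 4S CS, their two fractions, 4S CS/0S CS,
total CS); for all 17 detectable it yields all 39.

## Bayesian models and samplers

All coefficients (including intercepts) carry Student-t priors,
t(ν = 7, location 0, scale 2). The default MCMC protocol is four chains of
10,000 iterations with a warmup of 5,000; every fit is gated on
rank-normalized split R-hat < 1.01 and bulk ESS > 1000 (computed with arviz
on post-warmup draws only). A parameter whose draws are exactly constant and
identical across chains is treated as converged (a point mass has nothing
left to mix).

**Linear equivalence screen.** Each screened feature is standardized
(mean 0, sd 1 with denominator n−1) and modelled as a normal response with
the case/control indicator as predictor, plus experimental batch (binary,
coded 0/1 by sorted level) and sample age (months, centered — centering does
not move the group coefficient). The sampler is a Gibbs scheme in which each
t prior is represented as a gamma scale mixture of normals
(β_j | λ_j ~ N(0, s²/λ_j), λ_j ~ Gamma(ν/2, ν/2)) and the residual-scale
prior — a weakly informative half-t(3, scale 2), chosen by us since the
coefficient prior specification does not cover σ — as a nested inverse-gamma
mixture. All conditionals are exact, so draws are nearly independent and the
ESS gate is met with large margins; chains are vectorized jointly through
batched linear algebra.

**ROPE decision.** The 95% interval is the equal-tailed quantile interval of
the pooled post-warmup draws (its endpoints are order statistics, hence
invariant to draw order); a highest-density interval is available via
`RopeSpec(interval="hdi")`. The overlap statistic is the fraction of draws
inside the interval that also fall in the ROPE [−0.1, 0.1] on the
standardized scale; an interval-length-based alternative is available via
`overlap_metric="length"`. A feature is credible iff the interval excludes
zero, the overlap is ≤ 10%, and the diagnostics gate passes. No multiplicity
correction is applied across the screened features, matching the analysis
design this package implements.

**Logistic scores.** Predictors are prepared upstream (GAGome predictors
batch-normalized — per-batch centering rescaled to the pooled batch-centered
SD, which absorbs additive batch offsets and any constant shift; cfDNA
concentration log-transformed), then centered and scaled at fit time with
the constants stored in the model. The posterior is sampled by
coordinate-wise slice sampling (stepping-out and shrinkage) initialized at
the posterior mode found by BFGS, with per-coordinate widths taken from the
quasi-Newton curvature estimate. The t priors keep the posterior proper
under complete separation. The score is the posterior-mean linear predictor
— the log-odds of lung cancer — which is monotone-equivalent to the
posterior predictive probability for all ROC purposes.

## Threshold calibration and the combined test

Positivity is "score strictly above the cut-off", and the cut-off for a
specificity floor f is the smallest control score value c with
#(controls ≤ c)/n_controls ≥ f — the sensitivity-maximizing conformant
choice. The sequential combined test calibrates the cfDNA cut-off at f = 1.0
on controls with an available cfDNA score and the GAGome cut-off at f = 0.95
on all controls; insufficient or missing cfDNA yields a negative cfDNA call;
the combined call is the disjunction, and cfDNA-negative/GAGome-positive
samples are reclassified positives (so combined positives = cfDNA positives
+ reclassified positives by construction, and the controls' combined false
positives stay within 0 + ⌊5%⌋). Cut-offs are calibrated by resubstitution
on the same cohort, as in the study design this mirrors; the reported
operating points are therefore optimistic, which we document rather than
"fix".

Bootstrap CIs are percentile intervals from B = 5000 stratified replicates
(cases and controls resampled separately, preserving group sizes — the
stratification is our choice), with the cut-off recalibrated inside each
replicate. AUC uses the Mann-Whitney convention (ties count 1/2). Cohort
characteristic tests are Pearson χ² without continuity correction (missing
category excluded) and two-sample t-tests, defaulting to the
unequal-variance Welch form (the classical equal-variance form is a flag);
the GAGome–cfDNA independence check uses Spearman rank correlation, robust
to the skewed concentration scales.

## The synthetic cohort generator

The generator is the package's stand-in for the non-public study data. Its
defaults encode the study conditions: 85 cases with stage counts
I/II/III/IV = 9/6/18/52 and 28 controls; lognormal disaccharide
concentrations with control medians ≈ 0.60 µg/mL (0S CS) and 0.45 µg/mL
(4S CS) and ≈ 0.02 µg/mL for the other 15 (so exactly two disaccharides pass
the 0.1 µg/mL rule); case effects of +0.6 log-SD on 0S CS and −0.2 log-SD on
4S CS (the fraction of 4S CS falls further through the rise of total CS, so
the screen typically finds 0S CS concentration and 4S CS fraction credible
but not 4S CS concentration — the study's qualitative pattern); an additive
two-batch effect (+0.15 on the log scale, assignment independent of case
status by default, a confounded design available by parameter); a small
sample-age slope (−0.002 per month on log concentration); cfDNA
concentrations lognormal (controls ln-mean 1.8 ≈ 6 ng/mL) with
stage-dependent case shifts (0 / +0.35 / +0.6 / +0.9 on the log scale) and
negative-binomial variant counts (control mean 0.3; case means 0.5–4.5 by
stage, dispersion 1.5) — stage-dependent because cfDNA sensitivity is weak
at stage I, while the GAGome effect is stage-independent; and availability
masks of 81 samples with cfDNA concentration, 74 with variant counts and 7
insufficient. Distribution families (lognormal concentrations,
negative-binomial counts) are our choices; no generative family is given by
the study. GAGome and cfDNA values are drawn from separate child RNG
streams, so they are independent by construction and adding a component
never perturbs another's draws; a fixed seed reproduces a cohort
bit-for-bit. Age, sex and smoking marginals loosely match the study
population and feed only the cohort-characteristics table.

What the generator does **not** emulate: mass-spectrometric noise structure
(ion suppression, drift, censoring at the instrument level), correlations
among the 15 near-LOD disaccharides, survival or treatment outcomes, and any
real biological linkage between GAG metabolism and tumor DNA shedding.
Passing tests therefore demonstrate the correctness and operating
characteristics of the statistical machinery under the assumed structure,
not clinical performance on real plasma.

## Problem sizes and numerical choices

Simulation studies in the test suite use a reduced MCMC profile (four chains
of 500–1000 iterations) — adequate because the Gibbs draws are nearly
independent, so the ESS gate is still met — with 200 replicates for operating
characteristic estimates (type-I rate ≤ ~8%, power ≥ 80% at a 1-SD shift,
interval coverage 95% ± 4 points) and 1000 random instances for the
brute-force ROC/threshold oracle checks. The acceptance script runs the full
four-chain, 10,000-iteration protocol with the 5000-replicate bootstrap.
Ties in scores are handled by the Mann-Whitney 1/2 convention; candidate
cut-offs are control score values (−∞ when a floor is vacuous); medians use
the midpoint convention; stage reporting pools II–III.

## Limitations

* Thresholds and scores are developed and evaluated on the same cohort
  (resubstitution); no cross-validation or external validation is performed.
* The ROPE screen fits a normal response to possibly skewed concentration
  features; at n = 113 the group-mean contrast is robust, but extreme
  skewness would warrant a log transform upstream (the pipeline screens the
  features as provided).
* The cfDNA score requires complete predictor pairs; samples with
  concentration but no variant count contribute only as forced-negative
  calls in the combined test.
* The synthetic generator's effect sizes are calibrated to qualitative
  structure (directions, detectability, stage dependence), not to any
  quantitative distributional summary, since none is available.
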