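# Methods

`braingut` implements the analytical core of a multi-cohort gut-brain
microbiome study: quality control of species-level relative-abundance
profiles, community ecology statistics, empirical-Bayes batch
correction, per-cohort differential association pooled by random-effects
meta-analysis, a leakage-safe nested / leave-one-cohort-out (LOCO)
cross-validation classification framework, a Youden-threshold-centered
health index, and a tri-criteria consensus for core protective taxa.
This note documents the models, the choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## Data model

Profiles are samples x species matrices of relative abundances stored as
fractions; a per-sample sum below 1 is the unclassified remainder that
shotgun profilers leave. MetaPhlAn-style merged tables (percent units,
taxa in rows, full clade strings) are converted on ingest, keeping only
species-level rows (deepest rank prefix `s__`, plus SGB-style
`GGB...SGB...` placeholders, which are species-level despite lacking the
prefix). Missing metadata is preserved at read time; each statistical
operation drops only the records missing its own required fields.

## Quality control

Defaults follow the conventions of large shotgun meta-analyses: samples
need at least 10 million reads, at most 30% unclassified sequence at the
species level, and BMI <= 30 kg/m^2 (missing BMI never excludes — only
an observed violation does); studies with fewer than 10 surviving
samples are dropped whole. Species are retained when present at
>= 1e-4 relative abundance in >= 1% of samples; the two thresholds are
applied jointly (a "present" call requires clearing the abundance
cutoff), and sub-threshold values in retained species are zeroed.
Abundances are deliberately **not** renormalized after species
filtering, so absolute fractions remain comparable across filter
settings; `renormalize_after_species_filter` enables the alternative.
The audit records the *first* rule each sample failed, applied in the
order read depth, unclassified fraction, BMI, study size.

## Community ecology

Shannon diversity (natural log), Bray-Curtis and Jaccard
dissimilarities, and classical-scaling PCoA are computed directly from
their defining formulas; PCoA reports negative eigenvalues rather than
dropping them, since they flag non-Euclidean structure. One-factor
PERMANOVA partitions the sum of squared dissimilarities
(SS_total = sum over pairs of d^2 / N; SS_within summed per group with
1/n_g weights) and permutes labels freely, 999 permutations by default,
with the add-one p-value convention so zero is never reported. An
optional `strata` argument restricts permutations within strata for
pooled multi-study runs. Group-heterogeneity comparisons collect all
within-group pairwise dissimilarities per group and apply a two-sided
Wilcoxon rank-sum test; this operationalizes "community heterogeneity is
elevated in patients" — comparing case-to-control distances instead is a
different question and is not the default.

## Batch correction

The corrector is the classical empirical-Bayes location/scale model on
`log10(abundance + pseudocount)` with the disease covariate protected:
per-taxon regression on batch indicators plus the covariate,
standardization by pooled residual variance, shrinkage of per-batch
locations (normal prior) and scales (inverse-gamma, moment-matched)
toward across-batch moments, removal of the shrunken effects, and
restoration of the covariate fit and grand mean. The parametric variant
reproduces R `sva::ComBat` to the shared 1e-4 iteration tolerance (an
oracle test runs the comparison); a non-parametric empirical-prior
variant is available for data whose batch effects stray from the prior
family. Choices needing documentation:

- **Scale.** Correction operates on log10 with pseudocount 1e-5 (half
  the 1e-4 detection cutoff). The additive-shift batch model is stated
  on logs; the pseudocount keeps structural zeros finite.
- **Zeros.** Structural zeros stay zero after correction — moving an
  absent taxon to a small positive abundance would invent presence.
- **Closure.** Corrected samples are not re-closed by default (the
  additive model is defined per taxon); samples whose corrected sum
  exceeds 1 are rescaled to 1 so values remain interpretable as
  fractions, and a `reclose` flag restores the original totals instead.

Correction quality is scored by `batch_variance_reduction`: the percent
drop in batch R^2 from a Bray-Curtis PERMANOVA with study as the
factor. The harness scores any corrector's output table, not only its
own. Note that post-correction R^2 cannot fall below the chance level
of roughly (a-1)/(N-1) for a batches and N samples, which bounds the
attainable reduction on small designs.

## Differential association and meta-analysis

Each cohort is analysed per taxon with the simplest models honoring the
two standard views of a microbial feature: ordinary least squares of
`log10(abundance + pseudocount)` on the case indicator (plus optional
age/sex covariates) in abundance mode, and a logistic model of
presence/absence in prevalence mode. This is a deliberate
simplification of full mixed-model association frameworks: the package's
contribution is the cross-cohort meta-analytic design, not the
single-cohort model. On separation, the prevalence model falls back to
a weakly L2-penalized fit with a Wald p from the penalized information
matrix — a pragmatic bias-reduction stand-in that keeps estimates
finite; taxa with constant presence are flagged not-estimable and
excluded from pooling.

Cohort effects are pooled per taxon with DerSimonian-Laird:
tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with
fixed-effect weights w = 1/se^2, then inverse-variance pooling with
weights 1/(se^2 + tau^2) and a two-sided normal p. DL is the
conventional default of the standard meta-analysis packages; tau^2 is
truncated at zero (some implementations report the raw moment
estimate). Benjamini-Hochberg correction is applied within each
(disease, mode) family, threshold q < 0.1. Cross-disease
classification labels a taxon consistent-health when every significant
pooled effect is negative (lower in cases), consistent-disease when all
positive, context-dependent when signs mix; abundance and prevalence
modes are pooled and classified separately.

## Classification framework

`FeatureSelectingClassifier` is an sklearn-style estimator whose `fit`
contains the entire inner loop, so wrapping it in any outer CV is
leakage-safe by construction:

1. univariate feature ranking by rank-based AUC (|AUC - 0.5| per
   feature, computed from rank sums);
2. top-k selection over k in {16, 32, 64, 128, all} by inner 5-fold CV
   AUROC at default hyperparameters;
3. hyperparameter search by inner-CV AUROC: sequential model-based
   optimization (random-forest surrogate, upper-confidence acquisition
   over random candidates) with a plain random-search fallback at the
   same budget; the family's default configuration is always evaluated
   first so tiny budgets never underperform the defaults;
4. refit of the winning configuration on all training data.

Model families: elastic net, lasso-regularized logistic regression,
plain logistic regression (all with in-pipeline standardization fit on
training data only), random forest, and gradient-boosted trees
(`HistGradientBoostingClassifier`) carrying the conventional boosting
ranges depth [4, 12], learning rate [0.01, 0.3], iterations
[100, 1000], L2 leaf regularization [1, 20]. The univariate-AUC
filter and the k-grid are this package's choice; published pipelines
rarely state theirs.

The evaluation schemes on top: 10-times-repeated stratified 5-fold
nested CV (mean outer-fold AUROC is the unbiased estimate), LOCO CV for
diseases with >= 3 cohorts (each sample's probability comes from a model
that never saw its cohort), full-data tuning + final refit (the
resubstitution AUROC is reported but labeled optimistic), and the
three-tier battery: external-cohort robustness, cross-study
generalization (each single-study model scored on every other study;
diagonal = own nested AUROC), and cross-disease specificity (a specific
model should be at chance on diseases it never saw). The final model's
feature set is the consensus of outer-fold selections (features chosen
in >= 50% of folds). Features absent at external-validation time are
zero-imputed with a logged warning — absence of a taxon is a meaningful
zero in relative-abundance data. Abundance models train on
`log10(abundance + 1e-5)` (`log_abundance`); raw fractions are heavily
right-skewed and compose poorly in linear models.

A deliberately leaky oracle (`leaky_cv_auroc`: select on all data, then
cross-validate) exists purely as a regression control: on pure noise it
inflates AUROC well past 0.7 while the nested procedure stays at
chance. The central correctness property of the framework is exactly
this contrast.

## Health index

Given out-of-cohort disease probabilities, the operating threshold t*
maximizes Youden's J = sensitivity + specificity - 1 over midpoints
between adjacent observed probabilities (stable under infinitesimal
perturbation; ties in J break toward higher sensitivity, the
screening-oriented choice). Endpoint cuts (call-everything /
call-nothing) are included; if a probability of exactly 0 or 1 is
observed and the empirical optimum is an endpoint rule, the returned
threshold sits infinitesimally outside [0, 1] — otherwise it is
strictly interior. The per-sample index is `t* - probability`:
positive means the sample classifies healthy, with magnitude measuring
distance from the decision boundary. Training-population samples are
scored with their out-of-cohort probabilities, never by resubstitution
(the optimistic alternative is available behind a flag in
`index_for_dataset`); external samples are scored by the final model.

Evaluation: two-sided Wilcoxon rank-sum between case and control index
values; Cliff's delta with the disease-vs-health sign convention
(negative = lower in patients); Spearman correlation per clinical
phenotype with a percentile bootstrap CI over 10,000 resamples
(percentile rather than BCa — the simplest defensible interval at this
resample count). Constant inputs are reported degenerate, not raised.

## Core protective taxa

Three evidence lines intersect: (1) consistently health-enriched taxa
from the pooled differential analysis at q < 0.1; (2) index-
discriminative taxa — nonzero importance in the index's underlying
classifier (absolute coefficients for linear models, impurity decrease
for forests, total split gain for boosted trees) with a health-pointing
direction, estimated by single-feature perturbation (adding one decade
to the feature lowers mean predicted disease probability); (3)
prevalence >= 50% among healthy individuals, pooled across studies at
the 1e-4 detection cutoff (a per-cohort minimum variant exists). The
consensus is ordered by importance for deterministic output.

## Synthetic cohorts

The generator emulates a multi-study case-control design with known
truth. Per sample, each taxon's latent log-abundance is
`base_log_mean + study_log_bias + is_case * lfc + noise`; a structural-
zero mask is applied; values are exponentiated, closed to fractions and
scaled by `1 - unclassified_fraction`. Batch effects are multiplicative
per study-taxon (log-normal with sd `batch_sd`), matching the additive-
on-logs model the corrector targets. One master seed expands into
per-study substreams, so adding a study never perturbs existing ones.

Default conditions (chosen once as the package's study conditions):
3 studies of 50 cases + 50 controls, 200 species with baseline log
abundances N(-7, 1.5^2) (natural log), per-sample noise sd 0.7,
zero-inflation uniform on [0, 0.5], batch sd 0.5, disease effects of
1 log2 unit on 10 species. Two structural choices matter and are
deliberate:

- **Planted abundance effects sit on prevalent taxa** (structural
  absence capped at 5% for effect-carrying species). Abundance-mode
  signals are only well-defined on mostly-present species; a species
  absent from half the population carries a prevalence signal, which is
  a different mode. Ablation showed unrestricted zero-inflation on
  effect taxa is the single largest destroyer of multivariate signal
  (a structural zero is a far-off-scale outlier no linear score can
  ignore), capping the achievable AUROC near 0.84 even for an oracle
  that knows the planted taxa; with the cap, a 1-log2 ten-taxon effect
  is a strong, learnable signal, which is the regime the validation
  experiments are designed to probe.
- **When a protective arm is planted** (for core-taxa experiments),
  protective taxa are health-enriched, never structurally absent and
  lifted toward the abundant end (so healthy prevalence clears 50%),
  and the remaining effect taxa form the disease-enriched arm. With
  random signs, non-protective health-enriched taxa genuinely satisfy
  all three consensus criteria and "false inclusion" would be
  ill-defined.

What the generator does **not** emulate: real taxon names or phylum
composition, country/technical covariate structure, compositional
correlation networks between species, sequencing-depth-dependent
detection, or age/sex-driven effects (metadata are drawn independently
of the microbiome except for an optional case-linked symptom score).
Passing tests therefore demonstrate the *machinery* — leakage-freedom,
calibration, recovery of planted structure under batch bias and
compositional closure — not performance on real cohorts.

## Numerical and runtime choices

Tests and the acceptance script run the published workflow
(EB correction, then LOCO on log abundances) with the lasso family and
search budgets of 4-12 evaluations; the framework default budget is 30.
The experiments use the study conditions above at 200-500 features and
~100-300 samples, sizes at which every experiment completes in seconds
to a couple of minutes on one CPU while leaving the planted-signal
conclusions unchanged. PERMANOVA p-values use 999 permutations where
the p matters and 9-99 where only R^2 is consumed (R^2 is permutation-
free). The EB iteration converges at 1e-4 relative change, matching
the reference implementation; agreement with `sva::ComBat` is asserted
to that order, not machine precision. Degenerate inputs (constant
index, all-tied dissimilarities, single-cohort pooling, constant
prevalence) return flagged results rather than raising, except where an
analysis is genuinely impossible (no healthy samples, single batch, one
class), which is a hard error.

## Known limitations

- The per-cohort association models are intentionally minimal; strong
  covariate confounding or non-linear age effects are out of scope.
- The prevalence-mode separation fallback is ridge-penalized rather
  than a true Firth bias reduction.
- PERMANOVA is one-factor; multi-factor marginal designs are not
  implemented.
- Batch correction assumes every batch contains both cases and
  controls; fully confounded designs are rejected rather than
  reweighted.
- The SMBO hyperparameter search is a lightweight surrogate scheme, not
  a full Bayesian-optimization library; at the budgets used it behaves
  close to random search with a default-configuration guarantee.
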