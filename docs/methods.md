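# Methods

## The analysis

One biallelic SNP (risk allele C, reference A) is analysed against six
lipid traits (TC, TG, LDL-C, HDL-C, Apo-A, Apo-B; mmol/L) and
type-2-diabetes status in a family-structured case-control cohort.
Genotype enters every model as the additive dosage G ∈ {0, 1, 2}.

**Lipid models.** Each lipid is natural-log transformed and regressed by
OLS on dosage plus covariates (age, sex, smoking, drinking, hypertension,
coronary heart disease, BMI). The log transform is an inference rather
than a stated fact of the original analysis: multiplicative "percent
change per allele" reporting is only coherent for a log-scale slope, and
the published (β, PC) pairs satisfy PC = 100(e^β − 1) exactly at the
printed precision. A raw-scale fit remains available via
`log_transform=False`.

**Disease models.** Logistic regression of disease on dosage plus the
same covariates (Model 1), optionally adding TC, TG, LDL-C and HDL-C
(Model 2), and logistic models of disease on each lipid (per 1 mmol/L).

**Percent change.** PC = 100(e^β − 1) with the Wald interval
100(e^{β ± 1.96·SE} − 1). The 1.96 multiplier is fixed; it reproduces
the published CI bounds within rounding.

**Standard errors.** Plain SEs are the default so that single fits mirror
the published tables, whose SEs are consistent with unclustered fits.
Because the design is family-clustered (siblings correlate both in
genotype and through a shared household intercept), plain SEs undercover;
`robust="family"` switches to cluster-robust SEs grouped on family ID,
and the validation studies use that option throughout. The two agree when
the family variance component is zero (verified by a property test).

**Hardy-Weinberg QC.** 1-df Pearson chi-square of observed genotype
counts against (1−q)²N, 2q(1−q)N, q²N, no continuity correction. The
test is run on the pooled sample by default — pooled counts reconstructed
from the published genotype percentages reproduce the published P = 0.156
(we obtain 0.158 from round-to-nearest counts) more closely than
controls-only (0.173) — with a controls-only option since the original
choice is unstated. Monomorphic input is an explicit error, not χ² = 0.
A per-SNP call-rate gate (default 0.95) covers genotyping QC.

**Subgroups.** Binary splits on BMI (cutoff 24 kg/m²), smoking and
drinking; the stratifier is removed from the adjustment set within its
strata. Empty strata are skipped with a logged warning.

## Mediation

Two regressions on one shared complete-case set: the mediator (raw
mmol/L — kept untransformed for fidelity to the published OR table) on
dosage and covariates by OLS, and disease on dosage, mediator and
covariates by logistic regression. Under no exposure-mediator interaction
and the rare-outcome approximation, the natural direct/indirect effects
per allele are OR_d = e^{θ1}, OR_i = e^{θ2·β1}, OR_total = OR_d·OR_i
(exact in this closed form). With an interaction θ3 the standard
normal-mediator closed forms apply (θ3 and σ² enter, and the direct
effect is evaluated at the fitted covariate means by default).

**Proportion mediated.** The implementation uses the excess-odds form

    PM = OR_d (OR_i − 1) / (OR_d·OR_i − 1),

which is 0 when nothing is mediated and 1 when everything is. The
expression printed in the source analysis, OR_d(OR_d − 1)/(OR_d·OR_i − 1),
fails both boundary cases and yields ≈82% on the published TC row's
two-decimal ORs where ≈2.9% is printed — an evident typo. The printed
variant is retained behind `pm_formula="as-printed"` for audit. PM is
undefined (an explicit error, never a silent 0) when the total effect is
null.

**Bootstrap.** Nonparametric percentile CIs from resampling whole
families (the correct exchangeable unit here; individual-level resampling
is available). Point estimates come from the full-data statsmodels fits;
the resample refits use an internal warm-started Newton solver for speed,
cross-checked against statsmodels in the tests. Degenerate replicates are
redrawn up to a retry cap. The seed is mandatory; n_boot ≥ 200.

**Oracle.** `mc_counterfactual_oracle` simulates counterfactual mediator
values M(a′) ~ N(μ(a′, c), σ²) over a resampled covariate sample,
averages the outcome model into marginal counterfactual risks, and forms
empirical odds ratios. Each of the four risks uses independent draws so
the batch-means MC SEs honestly scale the comparison. In the rare-outcome
regime (≤1% prevalence) the oracle and the closed forms agree within MC
error; at the cohort's 38% prevalence they diverge measurably (≈0.007 on
the direct OR under the default generating values) — the documented cost
of applying logistic-OR closed forms to a common outcome, which the
original analysis implicitly accepts.

## The cohort simulator

The generator emulates the study conditions: 2885 families averaging
2.024 members (5839/2885), risk-allele frequency 0.34, founders drawn
from Hardy-Weinberg proportions with Mendelian transmission to offspring,
disease prevalence 0.38. Families are singletons (20%), pairs (57.6%;
half full-sib with latent parents, half parent-offspring), and
two-founder trios (22.4%) — sizes {1,2} alone cannot average above 2, so
some trios are required by the printed counts. Covariates are independent
draws matching the published marginals: age ~ N(57, 10²) truncated at 40,
sex Bernoulli(0.5), BMI ~ N(26.2, 4.4²), smoking 0.46, drinking 0.35,
hypertension 0.70, coronary heart disease 0.28 (case/control-weighted
published rates).

Each log-lipid is linear in centered dosage, covariates (one shared
coefficient map across lipids — the published tables give no basis for a
lipid-specific 6×7 matrix), a family intercept (SD 0.12) and noise
(log-SD 0.28–0.32; 0.55 for TG, the most dispersed lipid); baselines are
the published case/control-weighted geometric means. Per-allele log
effects default to the published adjusted estimates (TC 0.049, TG −0.018,
LDL-C 0.039, HDL-C/Apo-A/Apo-B 0.015). Disease follows the logistic
model with direct dosage effect 0.154, one designated mediator lipid (TC
by default, ln(1.06) per mmol/L, matching the published lipid→disease
estimate), and covariate effects of plausible sign and size; the
intercept is solved by root-finding so the expected prevalence over the
realised cohort equals the target. The seed is mandatory and the output
is byte-reproducible.

`SimulationTruth` reports the effects the config implies, including the
raw-scale mediator slope per allele computed analytically via moment
generating functions of the covariate marginals (numerical integration
only for the truncated-normal age term), so recovery tests have an exact,
simulation-free oracle. Three named scenarios: `paper_like` (the
defaults), `null` (all genotype effects zero), and `strong_mediation`
(TC path inflated, direct effect solved in closed form so the implied PM
is exactly 0.5; ~20k individuals).

**What the simulator does not emulate.** Proband-initiated ascertainment
(families are drawn at random — the original sampling scheme is not
quantified), linkage disequilibrium and multi-SNP structure, covariate
correlations, genotype×environment interactions, and any genuine
between-lipid residual correlation beyond the shared family intercept.
Passing recovery tests therefore demonstrate internal statistical
correctness of the estimators under the stated generating model, not
robustness to ascertainment or model misspecification in real cohorts.

## Validation studies and problem sizes

`pleiomed.validation` packages the calibration experiments the
reproduction script runs; sizes were chosen to keep Monte-Carlo error
well inside the decision margins:

* **Recovery** — 200 study-scale replicates (~5.8k individuals);
  family-robust SEs. Expected: |mean bias| of each lipid dosage
  coefficient < 0.005, CI coverage 92–98%, disease coefficient within
  0.01 of the mediation-consistent total ln(OR_d·OR_i). The marginal
  disease coefficient has no exact closed form at 38% prevalence
  (OR non-collapsibility), hence the total-effect yardstick.
* **Type-I error** — 2000 null replicates at ~2000 individuals; both
  association tests should reject at 5% ± 1.5%.
* **Bootstrap coverage** — 500 replicates (~1000 individuals each) × 500
  resamples under a *single-path* null: study-like genotype→lipid effect
  with θ2 = 0. The indirect-OR CI should cover 1 at 95% ± 3%. Under the
  complete null (β1 = θ2 = 0) the percentile bootstrap of a coefficient
  product is known to over-cover (towards ~99%), so the complete-null
  design cannot exhibit nominal coverage and the single-path null is the
  meaningful calibration target.
* **Oracle agreement** — generating-parameter models at 0.5% prevalence,
  10⁶ Monte-Carlo draws; |log-OR difference| within 3 MC SEs. The models
  are taken from the generating parameters rather than fitted, because a
  0.5%-prevalence cohort of study size holds only ~30 cases and the
  closed-form-vs-oracle question is about the transformation, not the
  fit.

## Numerical choices and degenerate inputs

* Complete-case analysis per fitted model; the two mediation regressions
  share one complete-case set.
* Constant exposure or mediator, single-class outcomes, and perfect
  separation raise `DegenerateDesignError` with a diagnostic rather than
  returning numbers.
* No multiple-testing correction across the six lipids by default,
  mirroring the original reporting; hypertension and coronary heart
  disease enter as diagnosis indicators.
* Bootstrap percentile CIs use the 2.5/97.5 empirical quantiles; PM CIs
  are computed over the replicates where PM is defined and reported as
  NaN if more than half are undefined.
* Human-readable tables round to the published precision (β 3 dp, PC/OR
  2 dp, PM 1 dp); `report.json` keeps full precision and is byte-stable
  across reruns of the same config and seed.

## Known limitations

Mixed-effects/kinship association models are out of scope (cluster-robust
SEs are the provided remedy); mediation assumes no exposure-induced
mediator-outcome confounding and handles one mediator at a time; the
OR-scale decomposition inherits the rare-outcome approximation error
quantified above; and the CI method of the original mediation table is
unstated — bootstrap is this package's choice.
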