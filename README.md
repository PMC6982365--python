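# pleiomed

Family-based pleiotropy analysis of a single biallelic SNP on lipid
traits and type-2-diabetes (T2DM) status: additive-model association with
percent-change reporting, Hardy-Weinberg QC, subgroup analyses, and a
counterfactual mediation decomposition of the genotype→disease effect
through each lipid. The package targets epidemiologists and statistical
geneticists who want a tested, reproducible implementation of this
analysis family — and, because such cohorts are typically
access-restricted, it ships a family-structured cohort simulator so every
stage can be exercised and calibrated end-to-end on synthetic data.

## The model

Genotype is coded additively as the risk-allele dosage G ∈ {0, 1, 2}.
For each lipid M (mmol/L) and disease status Y:

    ln M   = β0 + β_g·G + β_c'C + ε                      (OLS)
    logit P(Y=1) = θ0 + θ1·G + θ2·M + θ_c'C              (logistic)

with covariates C = (age, sex, smoking, drinking, hypertension, coronary
heart disease, BMI). Effects are reported as the **percent change**
PC = 100·(e^β − 1) per risk allele (or per 1 mmol/L), with Wald 95% CIs
mapped through the same transform. Hardy-Weinberg equilibrium is tested
by the 1-df Pearson chi-square against (1−q)²N, 2q(1−q)N, q²N.

The mediation decomposition combines the two regressions into natural
direct and indirect effects on the OR scale (rare-outcome closed form):

    OR_direct = e^{θ1},   OR_indirect = e^{θ2·β1},   OR_total = OR_d·OR_i

and the proportion mediated PM = OR_d(OR_i − 1)/(OR_d·OR_i − 1).
Percentile CIs come from a nonparametric bootstrap that resamples whole
families. A Monte-Carlo potential-outcome oracle cross-checks the closed
forms and quantifies the rare-outcome approximation error at the
cohort's actual 38% prevalence.

## Worked example

```python
import pleiomed as pm

cfg = pm.make_scenario("paper_like", seed=7)   # ~2885 families, q=0.34
df, truth = pm.simulate_cohort(cfg)

r = pm.fit_lipid_association(df, "TC", robust="family")
print(f"TC: beta={r.beta:.3f} (SE {r.se:.3f}), "
      f"PC={r.pc:.2f}% ({r.ci_low:.2f}, {r.ci_high:.2f}), P={r.p_value:.3g}")

med = pm.bootstrap_mediation(df, "TC", n_boot=500, seed=3)
print(f"direct OR={med.or_direct:.3f}, indirect OR={med.or_indirect:.4f}, "
      f"PM={100*med.pm:.1f}%")
```

prints (seed 7):

```
TC: beta=0.050 (SE 0.006), PC=5.18% (3.90, 6.47), P=5.45e-16
direct OR=1.183, indirect OR=1.0047, PM=2.9%
```

The lipid slope 0.050 recovers the generating per-allele log-effect 0.049
(PC ≈ +5% TC per risk allele); the mediation split says the genotype's
disease effect is almost entirely direct, with ~3% carried through TC —
the generating truth for this scenario is OR_direct 1.166, OR_indirect
1.0097.

The same analyses are available from the shell:

```bash
pleiomed simulate --scenario paper_like --seed 42 --out cohort.tsv --truth truth.json
pleiomed qc --data cohort.tsv --risk-allele C
pleiomed associate --data cohort.tsv --outcome T2DM --model 2 --robust family
pleiomed mediate --data cohort.tsv --mediator TC --boot 1000 --seed 7
pleiomed run --config pipeline.yaml
```

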