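"""Simulation-based validation studies for the analysis pipeline.

These routines quantify, under the generator's study-like conditions, the
statistical properties a user should expect of the estimators: parameter
recovery and CI coverage, type-I error of the association tests, bootstrap
coverage of the mediation intervals, and the agreement between the
closed-form natural-effect ORs and the potential-outcome Monte-Carlo
oracle.  They are what the reproduction script and the acceptance tests
run; each takes a single seed and is deterministic given it.
"""
from __future__ import annotations

import math

import numpy as np

from .association import fit_disease_association, fit_lipid_association
from .genetics import GenotypeCounts, HweResult, hwe_test
from .io import LIPIDS
from .mediation import bootstrap_mediation, mc_counterfactual_oracle, natural_effects
from .simulate import generating_mediation_models, make_scenario, make_truth, simulate_cohort

#: Published genotype distribution of the study SNP: percentages of 0/1/2
#: risk-allele carriers among 2220 cases and 3619 controls.
CASE_GENOTYPE_PCT = (39.5, 46.5, 14.0)
CONTROL_GENOTYPE_PCT = (46.4, 42.7, 10.9)
N_CASES, N_CONTROLS = 2220, 3619


def published_genotype_counts() -> GenotypeCounts:
    """Pooled genotype counts reconstructed from the published case and
    control genotype percentages (round-to-nearest)."""
    case = [round(N_CASES * p / 100) for p in CASE_GENOTYPE_PCT]
    ctrl = [round(N_CONTROLS * p / 100) for p in CONTROL_GENOTYPE_PCT]
    return GenotypeCounts(*(a + b for a, b in zip(case, ctrl)))


def published_hwe() -> HweResult:
    """HWE chi-square test on the reconstructed pooled genotype counts."""
    return hwe_test(published_genotype_counts())


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def recovery_study(seed: int, n_reps: int = 200) -> dict:
    """Parameter recovery under study-like conditions.

    Replicates the full cohort, refits the six lipid regressions and the
    disease model with family-robust SEs, and summarises the bias of each
    genotype coefficient, the empirical 95% CI coverage, and the distance
    of the mean disease coefficient from the mediation-consistent total
    effect ln(OR_total) implied by the generating parameters.
    """
    truth = make_truth(make_scenario("paper_like", seed=0))
    total = math.log(truth.or_total)
    bias = {l: [] for l in LIPIDS}
    cover = {l: [] for l in LIPIDS}
    disease = []
    n_ind = 0
    for s in _child_seeds(seed, n_reps):
        cfg = make_scenario("paper_like", seed=int(s))
        df, _ = simulate_cohort(cfg)
        n_ind = len(df)
        for lip in LIPIDS:
            r = fit_lipid_association(df, lip, robust="family")
            b = cfg.lipid_effects[lip]
            bias[lip].append(r.beta - b)
            cover[lip].append(r.beta - 1.96 * r.se <= b <= r.beta + 1.96 * r.se)
        disease.append(fit_disease_association(df, robust="family").beta)
    mean_bias = {l: float(np.mean(bias[l])) for l in LIPIDS}
    coverage = {l: float(np.mean(cover[l])) for l in LIPIDS}
    return {
        "n_reps": n_reps,
        "n_individuals": n_ind,
        "mean_bias": mean_bias,
        "coverage": coverage,
        "max_abs_bias": max(abs(v) for v in mean_bias.values()),
        "min_coverage_pct": 100.0 * min(coverage.values()),
        "max_coverage_pct": 100.0 * max(coverage.values()),
        "disease_mean_beta": float(np.mean(disease)),
        "mediation_consistent_total": total,
        "disease_total_abs_error": abs(float(np.mean(disease)) - total),
    }


def type1_error_study(seed: int, n_reps: int = 2000, n_families: int = 988) -> dict:
    """Null-scenario rejection rates at alpha = 0.05 (~2000 individuals
    per replicate) for the lipid and disease association tests, with
    family-robust SEs."""
    rej_lipid = rej_disease = 0
    n_ind = 0
    for s in _child_seeds(seed, n_reps):
        cfg = make_scenario("null", seed=int(s), n_families=n_families)
        df, _ = simulate_cohort(cfg)
        n_ind = len(df)
        rej_lipid += fit_lipid_association(df, "TC", robust="family").p_value < 0.05
        rej_disease += fit_disease_association(df, robust="family").p_value < 0.05
    return {
        "n_reps": n_reps,
        "n_individuals": n_ind,
        "lipid_rejection_pct": 100.0 * rej_lipid / n_reps,
        "disease_rejection_pct": 100.0 * rej_disease / n_reps,
    }


def bootstrap_null_coverage_study(seed: int, n_reps: int = 500,
                                  n_boot: int = 500,
                                  n_families: int = 500) -> dict:
    """Coverage of the family-bootstrap percentile CI for the indirect OR
    under a null mediated path.

    The generating model keeps the study-like genotype-lipid effect
    (beta1 != 0) but severs the mediator-disease path (theta_mediator = 0),
    so the true indirect OR is exactly 1 while the product estimate stays
    asymptotically normal; the CI should then cover 1 at its nominal 95%.
    """
    covered = 0
    n_ind = 0
    for s in _child_seeds(seed, n_reps):
        cfg = make_scenario("paper_like", seed=int(s), n_families=n_families,
                            theta_mediator=0.0)
        df, _ = simulate_cohort(cfg)
        n_ind = len(df)
        r = bootstrap_mediation(df, "TC", n_boot=n_boot, seed=int(s) // 2 + 1)
        covered += r.ci_indirect[0] <= 1.0 <= r.ci_indirect[1]
    return {
        "n_reps": n_reps,
        "n_boot": n_boot,
        "n_individuals": n_ind,
        "indirect_coverage_pct": 100.0 * covered / n_reps,
    }


def oracle_agreement_study(seed: int, n_mc: int = 1_000_000,
                           target_prevalence: float = 0.005) -> dict:
    """Closed-form natural-effect ORs vs the potential-outcome oracle in
    the rare-outcome regime where the closed forms are exact.

    Both routes consume the same generating-parameter models; the
    comparison statistic is the |log-OR difference| in Monte-Carlo SEs.
    """
    s1, s2 = (int(x) for x in _child_seeds(seed, 2))
    cfg = make_scenario("paper_like", seed=s1,
                        target_prevalence=target_prevalence)
    df, _ = simulate_cohort(cfg)
    mm, om = generating_mediation_models(cfg, df)
    ne = natural_effects(mm, om)
    orc = mc_counterfactual_oracle(mm, om, df, n_mc=n_mc, seed=s2)
    z_direct = abs(math.log(ne.or_direct) - math.log(orc.or_direct)) \
        / orc.se_log_direct
    z_indirect = abs(math.log(ne.or_indirect) - math.log(orc.or_indirect)) \
        / orc.se_log_indirect
    return {
        "n_mc": n_mc,
        "prevalence": float(df["T2DM"].mean()),
        "closed_or_direct": ne.or_direct,
        "oracle_or_direct": orc.or_direct,
        "closed_or_indirect": ne.or_indirect,
        "oracle_or_indirect": orc.or_indirect,
        "z_direct": z_direct,
        "z_indirect": z_indirect,
        "max_z": max(z_direct, z_indirect),
    }
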