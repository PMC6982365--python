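"""Mediation decomposition: closed forms, oracle, bootstrap."""
import math

import numpy as np
import pytest

import pleiomed as pm
from pleiomed.errors import (ConfigurationError, DegenerateDesignError,
                             NullTotalEffectError)
from pleiomed.mediation import (MediationAnalysis, MediatorModel, OutcomeModel,
                                fit_mediation_models, mc_counterfactual_oracle,
                                natural_effects, proportion_mediated)
from pleiomed.simulate import (SimulationConfig, generating_mediation_models,
                               make_scenario, simulate_cohort)


def _toy_models(beta1=0.2, theta1=0.15, theta2=0.4, theta3=None, sigma2=0.25):
    mm = MediatorModel(beta0=3.0, beta1=beta1, beta_cov={}, sigma2=sigma2,
                       covariates=(), covariate_means={}, n_used=100)
    om = OutcomeModel(theta0=-4.0, theta1=theta1, theta2=theta2,
                      theta_cov={}, theta3=theta3, n_used=100)
    return mm, om


class TestNaturalEffects:
    def test_blocked_mediator_path_gives_unit_indirect_or(self):
        mm, om = _toy_models(beta1=5.0, theta2=0.0)
        ne = natural_effects(mm, om)
        assert ne.or_indirect == 1.0

    def test_direct_or_is_exp_theta1(self):
        mm, om = _toy_models(theta1=0.15)
        ne = natural_effects(mm, om)
        assert ne.or_direct == pytest.approx(math.exp(0.15), rel=1e-12)
        assert ne.or_direct == pytest.approx(1.1618, abs=5e-5)

    def test_total_is_product_exactly(self):
        mm, om = _toy_models()
        ne = natural_effects(mm, om, a=2.0, a_star=0.0)
        assert ne.or_total == pytest.approx(ne.or_direct * ne.or_indirect,
                                            rel=1e-12)

    def test_identity_contrast_warns(self):
        mm, om = _toy_models()
        with pytest.warns(UserWarning):
            ne = natural_effects(mm, om, a=1.0, a_star=1.0)
        assert ne == (1.0, 1.0, 1.0)

    def test_interaction_terms_enter_closed_form(self):
        mm, om = _toy_models(theta3=0.1)
        ne = natural_effects(mm, om, a=1.0, a_star=0.0)
        mu0 = mm.beta0  # no covariates, a* = 0
        log_ord = (om.theta1 + om.theta3 * (mu0 + om.theta2 * mm.sigma2)
                   ) + 0.5 * om.theta3 ** 2 * mm.sigma2
        log_ori = om.theta2 * mm.beta1 + om.theta3 * mm.beta1
        assert math.log(ne.or_direct) == pytest.approx(log_ord, rel=1e-12)
        assert math.log(ne.or_indirect) == pytest.approx(log_ori, rel=1e-12)

    def test_interaction_zero_matches_no_interaction_form(self):
        mm, om0 = _toy_models(theta3=None)
        _, om3 = _toy_models(theta3=0.0)
        assert natural_effects(mm, om3) == pytest.approx(
            tuple(natural_effects(mm, om0)), rel=1e-12)


class TestProportionMediated:
    def test_nothing_mediated(self):
        assert proportion_mediated(1.5, 1.0) == 0.0

    def test_fully_mediated(self):
        assert proportion_mediated(1.0, 1.4) == pytest.approx(1.0)

    def test_magnitude_of_published_tc_row(self):
        # full-precision ORs of the TC row's magnitude: direct 1.047,
        # indirect 1.0014 -> about 3% mediated
        assert proportion_mediated(1.047, 1.0014) == pytest.approx(0.0302,
                                                                   abs=5e-4)

    def test_as_printed_variant_is_inconsistent(self):
        # the same row evaluated with the as-printed expression (OR^d in
        # the numerator twice) gives ~82% at 2-dp ORs — the documented typo
        assert proportion_mediated(1.04, 1.01, "as-printed") == pytest.approx(
            0.825, abs=5e-3)

    def test_null_total_effect_is_undefined(self):
        with pytest.raises(NullTotalEffectError):
            proportion_mediated(1.25, 0.8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_mediated(-1.0, 1.1)
        with pytest.raises(ValueError):
            proportion_mediated(1.1, 1.1, formula="bogus")

    def test_unit_invariance_under_mediator_rescaling(self, small_cohort):
        """mmol/L -> mg/dL rescaling leaves theta2*beta1, hence PM, fixed."""
        _, df, _ = small_cohort
        mm1, om1 = fit_mediation_models(df, "TC")
        scaled = df.copy()
        scaled["TC"] = scaled["TC"] * 38.67
        mm2, om2 = fit_mediation_models(scaled, "TC")
        ne1, ne2 = natural_effects(mm1, om1), natural_effects(mm2, om2)
        pm1 = proportion_mediated(ne1.or_direct, ne1.or_indirect)
        pm2 = proportion_mediated(ne2.or_direct, ne2.or_indirect)
        assert pm2 == pytest.approx(pm1, rel=1e-5)


class TestModelFitting:
    def test_recovery_at_large_n(self):
        cfg = make_scenario("strong_mediation", seed=55)
        df, truth = simulate_cohort(cfg)
        mm, om = fit_mediation_models(df, "TC")
        # sampling SEs at n~20k: slope ~0.02, logistic ~0.05
        assert mm.beta1 == pytest.approx(truth.mediator_slope, abs=0.06)
        assert om.theta1 == pytest.approx(cfg.theta_direct, abs=0.1)
        assert om.theta2 == pytest.approx(cfg.theta_mediator, abs=0.05)

    def test_null_mediator_path_recovered(self):
        cfg = SimulationConfig(seed=56, theta_mediator=0.0)
        df, _ = simulate_cohort(cfg)
        _, om = fit_mediation_models(df, "TC")
        assert om.theta2 == pytest.approx(0.0, abs=0.06)

    def test_constant_mediator_is_degenerate(self, small_cohort):
        _, df, _ = small_cohort
        bad = df.copy()
        bad["TC"] = 3.0
        with pytest.raises(DegenerateDesignError):
            fit_mediation_models(bad, "TC")

    def test_shared_complete_cases(self):
        cfg = SimulationConfig(seed=57, n_families=800, missing_rate=0.05)
        df, _ = simulate_cohort(cfg)
        mm, om = fit_mediation_models(df, "TC")
        assert mm.n_used == om.n_used < len(df)


class TestOracle:
    def test_null_theta2_indirect_or_near_one(self):
        mm, om = _toy_models(theta2=0.0)
        rng_cov = __import__("pandas").DataFrame(index=range(100))
        orc = mc_counterfactual_oracle(mm, om, rng_cov, n_mc=200_000, seed=1)
        assert abs(math.log(orc.or_indirect)) <= 3 * orc.se_log_indirect

    def test_rare_outcome_matches_closed_form(self):
        cfg = make_scenario("paper_like", seed=58, target_prevalence=0.005)
        df, _ = simulate_cohort(cfg)
        mm, om = generating_mediation_models(cfg, df)
        ne = natural_effects(mm, om)
        orc = mc_counterfactual_oracle(mm, om, df, n_mc=400_000, seed=2)
        zd = abs(math.log(ne.or_direct) - math.log(orc.or_direct))
        zi = abs(math.log(ne.or_indirect) - math.log(orc.or_indirect))
        assert zd <= 3 * orc.se_log_direct
        assert zi <= 3 * orc.se_log_indirect

    def test_common_outcome_divergence_is_real_and_bounded(self, paper_cohort):
        """At 38% prevalence the logistic-OR closed form and the
        risk-scale oracle measurably diverge — the documented limit of the
        rare-outcome approximation — but only by a small amount."""
        cfg, df, _ = paper_cohort
        mm, om = generating_mediation_models(cfg, df)
        ne = natural_effects(mm, om)
        orc = mc_counterfactual_oracle(mm, om, df, n_mc=400_000, seed=3)
        gap = abs(math.log(ne.or_direct) - math.log(orc.or_direct))
        assert gap > 3 * orc.se_log_direct   # statistically real
        assert gap < 0.05                    # but small in absolute terms

    def test_tiny_n_mc_rejected(self):
        mm, om = _toy_models()
        rng_cov = __import__("pandas").DataFrame(index=range(10))
        with pytest.raises(ConfigurationError):
            mc_counterfactual_oracle(mm, om, rng_cov, n_mc=10, seed=1)


class TestBootstrap:
    def test_fixed_seed_reproducible(self, small_cohort):
        _, df, _ = small_cohort
        a = pm.bootstrap_mediation(df, "TC", n_boot=200, seed=9)
        b = pm.bootstrap_mediation(df, "TC", n_boot=200, seed=9)
        assert a == b
        c = pm.bootstrap_mediation(df, "TC", n_boot=200, seed=10)
        assert c.ci_direct != a.ci_direct

    def test_seed_and_n_boot_preconditions(self, small_cohort):
        _, df, _ = small_cohort
        with pytest.raises(ConfigurationError):
            pm.bootstrap_mediation(df, "TC", n_boot=200, seed=None)
        with pytest.raises(ConfigurationError):
            pm.bootstrap_mediation(df, "TC", n_boot=50, seed=1)

    def test_point_estimates_bracketed_by_cis(self, small_cohort):
        _, df, _ = small_cohort
        r = pm.bootstrap_mediation(df, "TC", n_boot=300, seed=11)
        assert r.ci_direct[0] < r.or_direct < r.ci_direct[1]
        assert r.or_total == pytest.approx(r.or_direct * r.or_indirect,
                                           rel=1e-12)

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for nf in (400, 1600):
            cfg = SimulationConfig(seed=60, n_families=nf)
            df, _ = simulate_cohort(cfg)
            r = pm.bootstrap_mediation(df, "TC", n_boot=300, seed=61)
            widths[nf] = (r.ci_direct[1] - r.ci_direct[0],
                          r.ci_indirect[1] - r.ci_indirect[0],
                          r.ci_total[1] - r.ci_total[0])
        assert all(w400 > w1600 for w400, w1600 in zip(widths[400],
                                                       widths[1600]))

    def test_individual_resampling_option(self, small_cohort):
        _, df, _ = small_cohort
        r = pm.bootstrap_mediation(df, "TC", n_boot=200, seed=12,
                                   resample="individual")
        assert r.n_boot == 200 and np.isfinite(r.or_direct)

    def test_estimator_fitted_attributes(self, small_cohort):
        _, df, _ = small_cohort
        est = MediationAnalysis(mediator="LDL_C", n_boot=200, seed=13).fit(df)
        assert est.or_total_ == pytest.approx(
            est.or_direct_ * est.or_indirect_)
        assert est.result_.mediator == "LDL_C"
        assert est.mediator_model_.n_used == est.outcome_model_.n_used


class TestPmRecovery:
    def test_strong_mediation_pm_unbiased(self):
        """Scaled-down replicate study of the half-mediated scenario."""
        pms = []
        for s in range(8):
            cfg = make_scenario("strong_mediation", seed=900 + s)
            df, truth = simulate_cohort(cfg)
            mm, om = fit_mediation_models(df, "TC")
            ne = natural_effects(mm, om)
            pms.append(proportion_mediated(ne.or_direct, ne.or_indirect))
        assert np.mean(pms) == pytest.approx(0.5, abs=0.05)

    def test_pm_zero_when_mediator_path_blocked(self):
        pms = []
        for s in range(4):
            cfg = SimulationConfig(seed=70 + s, theta_mediator=0.0)
            df, _ = simulate_cohort(cfg)
            mm, om = fit_mediation_models(df, "TC")
            ne = natural_effects(mm, om)
            pms.append(proportion_mediated(ne.or_direct, ne.or_indirect))
        assert np.mean(pms) == pytest.approx(0.0, abs=0.05)
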