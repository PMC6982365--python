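"""Family cohort generator: pedigree structure, genotypes, phenotypes."""
import itertools

import numpy as np
import pytest

import pleiomed as pm
from pleiomed.errors import ConfigurationError
from pleiomed.genetics import GenotypeCounts, hwe_test
from pleiomed.io import LIPIDS, write_cohort
from pleiomed.simulate import (SimulationConfig, implied_mediator_slope,
                               make_scenario, make_truth, simulate_cohort,
                               simulate_families, simulate_phenotypes)


def _founders(df):
    return df[(df["PID"] == "0") & (df["MID"] == "0")]


def sib_correlation_by_enumeration(q: float) -> float:
    """Brute-force oracle: correlation of two full sibs' dosages under
    random mating, by enumerating parental genotypes (HWE weights) and all
    four transmission patterns per parent pair."""
    pg = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q * q}
    # transmission distribution of one allele from a parent with dosage g
    trans = {0: {0: 1.0}, 1: {0: 0.5, 1: 0.5}, 2: {1: 1.0}}
    e1 = e11 = e12 = 0.0
    for gp, gm in itertools.product(pg, pg):
        w = pg[gp] * pg[gm]
        kid = {}
        for ap, am in itertools.product(trans[gp], trans[gm]):
            kid[ap + am] = kid.get(ap + am, 0.0) + trans[gp][ap] * trans[gm][am]
        m1 = sum(k * p for k, p in kid.items())
        m2 = sum(k * k * p for k, p in kid.items())
        e1 += w * m1
        e11 += w * m2            # E[c1^2]; both sibs share the kid dist
        e12 += w * m1 * m1       # E[c1 c2]; sibs independent given parents
    var = e11 - e1 * e1
    return (e12 - e1 * e1) / var


class TestFamilies:
    def test_hwe_proportions_at_half(self):
        cfg = SimulationConfig(seed=1, n_families=10000, risk_allele_freq=0.5,
                               family_size_probs={1: 1.0})
        df = simulate_families(cfg)
        props = df["genotype_code"].value_counts(normalize=True)
        assert props[0] == pytest.approx(0.25, abs=0.02)
        assert props[1] == pytest.approx(0.50, abs=0.02)
        assert props[2] == pytest.approx(0.25, abs=0.02)

    def test_fixation_at_zero_frequency(self):
        cfg = SimulationConfig(seed=1, n_families=500, risk_allele_freq=0.0)
        df = simulate_families(cfg)
        assert (df["genotype_code"] == 0).all()
        assert (df["genotype"] == "A/A").all()

    def test_sibling_dosage_correlation_matches_enumeration(self):
        expected = sib_correlation_by_enumeration(0.34)
        assert expected == pytest.approx(0.5, abs=1e-12)  # any q, random mating
        cfg = SimulationConfig(seed=3, n_families=20000,
                               family_size_probs={2: 1.0})
        df = simulate_families(cfg)
        sibs = df[df["PID"].str.endswith("-PF")]
        wide = sibs.pivot_table(index="FID", columns=sibs.groupby("FID").cumcount(),
                                values="genotype_code")
        wide = wide.dropna()
        assert len(wide) > 5000
        r = np.corrcoef(wide[0], wide[1])[0, 1]
        assert r == pytest.approx(expected, abs=0.03)

    def test_founders_pass_hwe(self):
        """Rows with PID=MID=0 are independent HWE draws: their genotype
        counts should rarely reject the package's own HWE test."""
        fails = 0
        sims = 200
        for s in range(sims):
            cfg = SimulationConfig(seed=10_000 + s, n_families=600)
            founders = _founders(simulate_families(cfg))
            res = hwe_test(GenotypeCounts.from_codes(founders["genotype_code"]))
            fails += res.p_value <= 0.01
        assert fails / sims <= 0.02

    def test_family_size_mean_matches_cohort_ratio(self):
        cfg = SimulationConfig(seed=5, n_families=5000)
        df = simulate_families(cfg)
        assert len(df) / cfg.n_families == pytest.approx(2.024, abs=0.05)

    def test_mendelian_consistency_in_trios(self):
        cfg = SimulationConfig(seed=6, n_families=3000,
                               family_size_probs={3: 1.0})
        df = simulate_families(cfg)
        by_iid = df.set_index("IID")["genotype_code"]
        kids = df[df["PID"] != "0"]
        kids = kids[kids["PID"].isin(by_iid.index) & kids["MID"].isin(by_iid.index)]
        assert len(kids) > 1000
        gp = by_iid[kids["PID"]].to_numpy()
        gm = by_iid[kids["MID"]].to_numpy()
        gk = kids["genotype_code"].to_numpy()
        # a child can never carry more risk alleles than transmissible
        assert (gk <= (gp > 0).astype(int) + (gm > 0).astype(int)).all()
        assert (gk >= (gp == 2).astype(int) + (gm == 2).astype(int)).all()


class TestPhenotypes:
    def test_noise_free_limit_recovers_generating_beta(self):
        cfg = SimulationConfig(
            seed=9, n_families=400, family_sd=0.0,
            residual_sd={l: 1e-9 for l in LIPIDS},
            covariate_effects_lipid={},
        )
        df, _ = simulate_cohort(cfg)
        res = pm.fit_lipid_association(df, "TC", covariates=[])
        assert res.beta == pytest.approx(cfg.lipid_effects["TC"], abs=1e-6)

    def test_group_log_mean_difference_is_twice_beta(self):
        cfg = SimulationConfig(seed=11, n_families=2885,
                               lipid_effects={"TC": 0.05})
        df, _ = simulate_cohort(cfg)
        ln_tc = np.log(df["TC"])
        diff = (ln_tc[df["genotype_code"] == 2].mean()
                - ln_tc[df["genotype_code"] == 0].mean())
        assert diff == pytest.approx(0.10, abs=0.045)

    def test_null_genotype_disease_odds_ratio_near_one(self):
        betas = []
        for s in range(8):
            cfg = make_scenario("null", seed=500 + s, n_families=1000)
            df, _ = simulate_cohort(cfg)
            betas.append(pm.fit_disease_association(df).beta)
        assert np.mean(betas) == pytest.approx(0.0, abs=0.05)

    def test_prevalence_matches_target(self, paper_cohort):
        _, df, _ = paper_cohort
        assert df["T2DM"].mean() == pytest.approx(0.38, abs=0.03)

    def test_lipids_strictly_positive_no_missing(self, paper_cohort):
        _, df, _ = paper_cohort
        assert (df[list(LIPIDS)] > 0).all().all()
        assert not df[list(LIPIDS)].isna().any().any()

    def test_configured_missingness(self):
        cfg = SimulationConfig(seed=13, n_families=1000, missing_rate=0.1)
        df, _ = simulate_cohort(cfg)
        assert df["TC"].isna().mean() == pytest.approx(0.1, abs=0.03)
        assert (df.loc[df["genotype_code"].isna(), "genotype"] == "./.").all()

    def test_unknown_lipid_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, lipid_effects={"CHOLESTEROL": 0.1})


class TestDeterminism:
    def test_same_seed_byte_identical_tsv(self, tmp_path):
        for run in ("a", "b"):
            cfg = SimulationConfig(seed=77, n_families=300)
            df, _ = simulate_cohort(cfg)
            write_cohort(df, tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_different_seed_differs(self, tmp_path):
        frames = []
        for seed in (1, 2):
            df, _ = simulate_cohort(SimulationConfig(seed=seed, n_families=300))
            frames.append(df)
        assert not frames[0]["TC"].equals(frames[1]["TC"])


class TestScenariosAndTruth:
    def test_null_scenario_is_fully_null(self):
        cfg = make_scenario("null", seed=1)
        assert all(v == 0.0 for v in cfg.lipid_effects.values())
        assert cfg.theta_direct == 0.0 and cfg.theta_mediator == 0.0

    def test_paper_like_scenario_magnitudes(self):
        cfg = make_scenario("paper_like", seed=1)
        assert cfg.theta_direct == pytest.approx(0.154)
        assert cfg.risk_allele_freq == pytest.approx(0.34)
        assert cfg.n_families == 2885
        assert cfg.target_prevalence == pytest.approx(0.38)

    def test_strong_mediation_implies_half_mediated(self):
        truth = make_truth(make_scenario("strong_mediation", seed=1))
        assert truth.pm == pytest.approx(0.5, abs=1e-9)

    def test_unknown_scenario_raises(self):
        with pytest.raises(KeyError):
            make_scenario("bogus", seed=1)

    def test_truth_pc_identity(self):
        truth = make_truth(make_scenario("paper_like", seed=1))
        assert truth.true_pc["TC"] == pytest.approx(100 * (np.exp(0.049) - 1))
        assert truth.or_total == pytest.approx(truth.or_direct * truth.or_indirect)

    def test_implied_slope_matches_regression_slope(self):
        """Dual route: the analytic (MGF-based) mediator slope must agree
        with an empirical covariate-adjusted regression at large n."""
        cfg = make_scenario("paper_like", seed=21, n_families=12000)
        df, truth = pm.simulate_cohort(cfg)
        res = pm.LipidAssociation(lipid="TC", log_transform=False).fit(df)
        assert res.beta_ == pytest.approx(truth.mediator_slope,
                                          abs=3 * res.se_)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"risk_allele_freq": 1.5},
        {"target_prevalence": 0.0},
        {"family_size_probs": {1: 0.0}},
        {"family_size_probs": {0: 1.0}},
        {"residual_sd": {"TC": -0.1}},
        {"mediator": "GLUCOSE"},
        {"n_families": 0},
        {"missing_rate": 1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, **kwargs)

    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            SimulationConfig()  # noqa: missing required seed

    def test_slope_undefined_for_fixed_allele(self):
        cfg = SimulationConfig(seed=1, risk_allele_freq=0.0)
        with pytest.raises(ConfigurationError):
            implied_mediator_slope(cfg)


def test_phenotypes_standalone_uses_offset_stream():
    cfg = SimulationConfig(seed=31, n_families=200)
    fam = simulate_families(cfg)
    df = simulate_phenotypes(fam, cfg)
    assert "T2DM" in df and df["T2DM"].isin([0, 1]).all()
    assert df.attrs["realized_prevalence"] == pytest.approx(
        cfg.target_prevalence, abs=0.1)
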