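"""Family-structured case-control cohort simulator.

The real study cohort (≈2885 families, 5839 individuals, a biallelic SNP
with risk-allele frequency ≈0.34, six lipid traits and type-2-diabetes
status) is access-restricted, so every analysis stage in this package is
exercised on synthetic cohorts with the same statistical structure:

* founders draw genotypes from Hardy-Weinberg proportions and offspring
  receive alleles by Mendelian transmission;
* each log-lipid is linear in the risk-allele dosage, covariates and a
  shared family intercept, so genotype effects are multiplicative
  ("percent change") on the natural mmol/L scale;
* disease status follows a logistic model with a direct genotype term and
  a term through one designated mediator lipid, with the intercept tuned
  numerically so the realised prevalence matches the target (0.38 by
  default, the study's case fraction).

The generator is fully deterministic given the mandatory seed.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .errors import ConfigurationError
from .io import COHORT_COLUMNS, LIPIDS

#: Risk / reference alleles of the simulated SNP.
RISK_ALLELE = "C"
OTHER_ALLELE = "A"

_GENO_STRING = {0: "A/A", 1: "A/C", 2: "C/C"}

# Per-allele effects on ln(lipid); magnitudes follow the published
# adjusted estimates for the study SNP.
DEFAULT_LIPID_EFFECTS = {
    "TC": 0.049, "TG": -0.018, "LDL_C": 0.039,
    "HDL_C": 0.015, "APO_A": 0.015, "APO_B": 0.015,
}

# Geometric-mean lipid levels (mmol/L), matching the cohort's descriptive
# marginals (case/control weighted means).
DEFAULT_LIPID_BASELINES = {
    "TC": 3.18, "TG": 1.55, "LDL_C": 2.29,
    "HDL_C": 0.98, "APO_A": 1.12, "APO_B": 0.77,
}

# Residual SD of ln(lipid); TG is the most dispersed lipid in practice.
DEFAULT_RESIDUAL_SD = {
    "TC": 0.30, "TG": 0.55, "LDL_C": 0.32,
    "HDL_C": 0.30, "APO_A": 0.28, "APO_B": 0.28,
}

# Covariate effects on ln(lipid), shared across the six lipids.
DEFAULT_COVARIATE_EFFECTS_LIPID = {
    "age": 0.002, "sex": -0.02, "BMI": 0.004,
    "smoker": -0.01, "drinker": 0.0, "hypertension": 0.01, "CHD": 0.01,
}

# Covariate effects on the disease logit.
DEFAULT_COVARIATE_EFFECTS_DISEASE = {
    "age": 0.025, "sex": -0.35, "BMI": 0.03,
    "smoker": -0.25, "drinker": -0.35, "hypertension": 0.45, "CHD": 0.05,
}

# Marginal covariate distributions: middle-aged to elderly community
# cohort, overweight on average, with high hypertension prevalence.
DEFAULT_COVARIATE_PARAMS = {
    "age_mean": 57.0, "age_sd": 10.0, "age_min": 40.0,
    "male_p": 0.50,
    "bmi_mean": 26.2, "bmi_sd": 4.4,
    "smoker_p": 0.46, "drinker_p": 0.35,
    "hypertension_p": 0.70, "chd_p": 0.28,
}

# Family sizes: singletons, pairs (sib or parent-offspring) and
# two-parent-one-child trios; mean 2.024 ≈ 5839/2885 people per family.
DEFAULT_FAMILY_SIZE_PROBS = {1: 0.20, 2: 0.576, 3: 0.224}


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic family cohort.

    The seed is mandatory: every simulation is reproducible by
    construction and there is no silent default stream.
    """

    seed: int
    n_families: int = 2885
    family_size_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SIZE_PROBS))
    risk_allele_freq: float = 0.34
    lipid_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_LIPID_EFFECTS))
    lipid_baselines: dict = field(
        default_factory=lambda: dict(DEFAULT_LIPID_BASELINES))
    residual_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    family_sd: float = 0.12
    covariate_effects_lipid: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS_LIPID))
    covariate_effects_disease: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS_DISEASE))
    covariate_params: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    mediator: str = "TC"
    theta_direct: float = 0.154
    theta_mediator: float = math.log(1.06)
    baseline_logit: float | None = None
    target_prevalence: float = 0.38
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ConfigurationError(
                f"risk_allele_freq must lie in [0, 1], got {self.risk_allele_freq}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigurationError("target_prevalence must lie in (0, 1)")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be positive")
        if self.family_sd < 0:
            raise ConfigurationError("family_sd must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        total_mass = float(sum(self.family_size_probs.values()))
        if total_mass <= 0:
            raise ConfigurationError("family_size_dist has zero total mass")
        if any(int(s) < 1 for s in self.family_size_probs):
            raise ConfigurationError("family sizes must be >= 1")
        for name in self.lipid_effects:
            if name not in LIPIDS:
                raise ConfigurationError(f"unknown lipid {name!r} in lipid_effects")
        for name, sd in self.residual_sd.items():
            if name not in LIPIDS:
                raise ConfigurationError(f"unknown lipid {name!r} in residual_sd")
            if sd <= 0:
                raise ConfigurationError(f"residual_sd[{name!r}] must be > 0")
        if self.mediator not in LIPIDS:
            raise ConfigurationError(f"unknown mediator lipid {self.mediator!r}")


@dataclass
class SimulationTruth:
    """Generating config echoed back with the effects it implies.

    Every derived quantity here is recomputable from the config alone, so
    parameter-recovery tests have an exact oracle:

    * ``true_pc`` — per-allele percent change on each lipid,
      100·(exp(β_g) − 1);
    * ``mediator_slope`` — implied raw-scale (mmol/L per allele) linear
      slope of the mediator on dosage, via moment generating functions of
      the covariate marginals (see :func:`implied_mediator_slope`);
    * ``or_direct/or_indirect/or_total`` — natural-effect odds ratios of
      the generating model under the rare-outcome closed form;
    * ``pm`` — proportion mediated, OR^d(OR^i−1)/(OR^d·OR^i−1); ``None``
      when the total effect is null.
    """

    config: SimulationConfig
    true_pc: dict
    mediator_slope: float
    or_direct: float
    or_indirect: float
    or_total: float
    pm: float | None


def _covariate_centers(config: SimulationConfig) -> dict:
    """Centering constants used by the generator (truncated-normal mean
    for age, nominal means elsewhere)."""
    cp = config.covariate_params
    a = (cp["age_min"] - cp["age_mean"]) / cp["age_sd"]
    age_mean = float(stats.truncnorm.mean(a, np.inf, loc=cp["age_mean"],
                                          scale=cp["age_sd"]))
    return {
        "age": age_mean,
        "sex": cp["male_p"],
        "BMI": cp["bmi_mean"],
        "smoker": cp["smoker_p"],
        "drinker": cp["drinker_p"],
        "hypertension": cp["hypertension_p"],
        "CHD": cp["chd_p"],
    }


def _covariate_mgf(config: SimulationConfig, effects: dict) -> float:
    """E[exp(Σ c_j (X_j − center_j))] for independent covariate marginals.

    Bernoulli and normal terms have closed-form MGFs; the truncated-normal
    age term is integrated numerically.
    """
    cp = config.covariate_params
    centers = _covariate_centers(config)
    out = 1.0
    for name, c in effects.items():
        if c == 0.0:
            continue
        if name == "age":
            a = (cp["age_min"] - cp["age_mean"]) / cp["age_sd"]
            ex = stats.truncnorm.expect(
                lambda x: np.exp(c * x), args=(a, np.inf),
                loc=cp["age_mean"], scale=cp["age_sd"])
            out *= float(ex) * math.exp(-c * centers["age"])
        elif name == "BMI":
            out *= math.exp(0.5 * c * c * cp["bmi_sd"] ** 2)
        else:
            p = centers[name]
            out *= math.exp(-c * p) * (1.0 - p + p * math.exp(c))
    return out


def implied_mediator_slope(config: SimulationConfig, lipid: str | None = None) -> float:
    """Population linear slope (mmol/L per risk allele) of a lipid on dosage.

    The generator makes ln(lipid) linear in dosage, so the lipid itself is
    log-normal within genotype class and the covariate-adjusted least
    squares slope converges to Cov(M, G)/Var(G) (dosage is independent of
    the covariates).  With G ~ Binomial(2, q) and
    E[M | G=g] = K·exp(β_g (g − 2q)), both moments are finite sums::

        Cov(M, G) = K Σ_g P(g) (g − 2q) exp(β_g (g − 2q)),  Var(G) = 2q(1−q)

    where K collects the baseline, the covariate MGF and the log-normal
    noise factor exp((σ² + τ²)/2).
    """
    lipid = lipid or config.mediator
    q = config.risk_allele_freq
    if not 0.0 < q < 1.0:
        raise ConfigurationError("mediator slope undefined for a fixed allele")
    beta = config.lipid_effects.get(lipid, 0.0)
    sd = config.residual_sd.get(lipid, DEFAULT_RESIDUAL_SD[lipid])
    k = (config.lipid_baselines.get(lipid, DEFAULT_LIPID_BASELINES[lipid])
         * math.exp(0.5 * (sd * sd + config.family_sd ** 2))
         * _covariate_mgf(config, config.covariate_effects_lipid))
    pg = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    g = np.arange(3.0)
    cov = float(np.sum(pg * (g - 2 * q) * np.exp(beta * (g - 2 * q)))) * k
    return cov / (2.0 * q * (1.0 - q))


def _pm_corrected(or_direct: float, or_indirect: float) -> float | None:
    total = or_direct * or_indirect
    if abs(math.log(total)) < 1e-12:
        return None
    return or_direct * (or_indirect - 1.0) / (total - 1.0)


def make_truth(config: SimulationConfig) -> SimulationTruth:
    """Derive the true effect sizes implied by a config (no simulation)."""
    true_pc = {
        lip: 100.0 * math.expm1(config.lipid_effects.get(lip, 0.0))
        for lip in LIPIDS
    }
    slope = implied_mediator_slope(config)
    or_direct = math.exp(config.theta_direct)
    or_indirect = math.exp(config.theta_mediator * slope)
    return SimulationTruth(
        config=config,
        true_pc=true_pc,
        mediator_slope=slope,
        or_direct=or_direct,
        or_indirect=or_indirect,
        or_total=or_direct * or_indirect,
        pm=_pm_corrected(or_direct, or_indirect),
    )


# ---------------------------------------------------------------------------
# family structure and genotypes

def _transmit(rng, gp: np.ndarray, gm: np.ndarray) -> np.ndarray:
    """Mendelian transmission: one allele from each parent, with the risk
    allele transmitted with probability g/2."""
    return rng.binomial(1, gp / 2.0) + rng.binomial(1, gm / 2.0)


def simulate_families(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Draw pedigree structure, genotypes and covariates.

    Families are singletons, pairs or two-founder nuclear families.  A
    pair is a full-sib pair (two latent parents) or a parent-offspring
    pair (one observed founder, one latent co-parent) with equal
    probability.  Latent parents get pedigree IDs so that rows with
    PID = MID = "0" are exactly the independent Hardy-Weinberg founders.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    q = config.risk_allele_freq
    nf = config.n_families

    size_vals = np.array(sorted(int(s) for s in config.family_size_probs))
    size_p = np.array([config.family_size_probs[s] for s in size_vals], float)
    size_p = size_p / size_p.sum()
    sizes = rng.choice(size_vals, size=nf, p=size_p)
    pair_is_sib = rng.random(nf) < 0.5  # consulted for size-2 families only

    fam_idx, member, geno, pid, mid, sex = [], [], [], [], [], []

    def fid(i: int) -> str:
        return f"F{i + 1:05d}"

    # Pre-draw founder/latent genotypes family by family (python loop over
    # ~3k families; the heavy per-individual work below is vectorised).
    for i in range(nf):
        s = int(sizes[i])
        if s == 1:
            g0 = rng.binomial(2, q)
            fam_idx.append(i); member.append(1); geno.append(g0)
            pid.append("0"); mid.append("0")
            sex.append(int(rng.random() < config.covariate_params["male_p"]))
        elif s == 2 and pair_is_sib[i]:
            gp, gm = rng.binomial(2, q, size=2)
            latf, latm = f"{fid(i)}-PF", f"{fid(i)}-PM"
            for k in range(2):
                gk = int(_transmit(rng, np.array([gp]), np.array([gm]))[0])
                fam_idx.append(i); member.append(k + 1); geno.append(gk)
                pid.append(latf); mid.append(latm)
                sex.append(int(rng.random() < config.covariate_params["male_p"]))
        elif s == 2:
            gpar = rng.binomial(2, q)
            glat = rng.binomial(2, q)
            par_male = rng.random() < 0.5
            fam_idx.append(i); member.append(1); geno.append(int(gpar))
            pid.append("0"); mid.append("0"); sex.append(int(par_male))
            gk = int(_transmit(rng, np.array([gpar]), np.array([glat]))[0])
            fam_idx.append(i); member.append(2); geno.append(gk)
            par_iid = f"{fid(i)}-1"
            lat_iid = f"{fid(i)}-PL"
            pid.append(par_iid if par_male else lat_iid)
            mid.append(lat_iid if par_male else par_iid)
            sex.append(int(rng.random() < config.covariate_params["male_p"]))
        else:  # nuclear family: father, mother, s-2 children
            gfa, gmo = rng.binomial(2, q, size=2)
            fam_idx.append(i); member.append(1); geno.append(int(gfa))
            pid.append("0"); mid.append("0"); sex.append(1)
            fam_idx.append(i); member.append(2); geno.append(int(gmo))
            pid.append("0"); mid.append("0"); sex.append(0)
            for k in range(s - 2):
                gk = int(_transmit(rng, np.array([gfa]), np.array([gmo]))[0])
                fam_idx.append(i); member.append(3 + k); geno.append(gk)
                pid.append(f"{fid(i)}-1"); mid.append(f"{fid(i)}-2")
                sex.append(int(rng.random() < config.covariate_params["male_p"]))

    n = len(fam_idx)
    cp = config.covariate_params
    a = (cp["age_min"] - cp["age_mean"]) / cp["age_sd"]
    age = stats.truncnorm.rvs(a, np.inf, loc=cp["age_mean"], scale=cp["age_sd"],
                              size=n, random_state=rng)
    df = pd.DataFrame({
        "FID": [fid(i) for i in fam_idx],
        "IID": [f"{fid(i)}-{m}" for i, m in zip(fam_idx, member)],
        "PID": pid,
        "MID": mid,
        "sex": np.asarray(sex, int),           # 1 = male, 0 = female
        "age": age,
        "genotype_code": np.asarray(geno, int),
        "genotype": [_GENO_STRING[g] for g in geno],
        "BMI": rng.normal(cp["bmi_mean"], cp["bmi_sd"], size=n),
        "smoker": rng.binomial(1, cp["smoker_p"], size=n),
        "drinker": rng.binomial(1, cp["drinker_p"], size=n),
        "hypertension": rng.binomial(1, cp["hypertension_p"], size=n),
        "CHD": rng.binomial(1, cp["chd_p"], size=n),
    })
    df.attrs["n_families"] = nf
    return df


# ---------------------------------------------------------------------------
# phenotypes

_COVARIATE_COLS = ("age", "sex", "BMI", "smoker", "drinker", "hypertension", "CHD")


def _covariate_lp(df: pd.DataFrame, effects: dict, centers: dict) -> np.ndarray:
    lp = np.zeros(len(df))
    for name, c in effects.items():
        if c == 0.0:
            continue
        lp += c * (df[name].to_numpy(float) - centers[name])
    return lp


def simulate_phenotypes(
    records: pd.DataFrame, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """Fill in lipid concentrations and disease status.

    ln(lipid) = ln(baseline) + β_g·(G − 2q) + covariate terms + family
    intercept + N(0, σ); disease follows a logistic model with a direct
    dosage term and one term through the designated mediator lipid.  When
    ``baseline_logit`` is None the intercept is solved numerically so the
    expected prevalence over the realised cohort equals the target.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    df = records.copy()
    n = len(df)
    centers = _covariate_centers(config)
    g_centered = df["genotype_code"].to_numpy(float) - 2.0 * config.risk_allele_freq
    cov_lp = _covariate_lp(df, config.covariate_effects_lipid, centers)

    fam_codes, _ = pd.factorize(df["FID"])
    u = rng.normal(0.0, config.family_sd, size=fam_codes.max() + 1)[fam_codes] \
        if config.family_sd > 0 else np.zeros(n)

    for lip in LIPIDS:
        beta = config.lipid_effects.get(lip, 0.0)
        sd = config.residual_sd.get(lip, DEFAULT_RESIDUAL_SD[lip])
        base = config.lipid_baselines.get(lip, DEFAULT_LIPID_BASELINES[lip])
        ln_lip = (math.log(base) + beta * g_centered + cov_lp + u
                  + rng.normal(0.0, sd, size=n))
        df[lip] = np.exp(ln_lip)

    mediator = df[config.mediator].to_numpy(float)
    lp = (config.theta_direct * g_centered
          + config.theta_mediator * mediator
          + _covariate_lp(df, config.covariate_effects_disease, centers))
    if config.baseline_logit is None:
        b0 = float(optimize.brentq(
            lambda b: expit(b + lp).mean() - config.target_prevalence, -50, 50))
    else:
        b0 = config.baseline_logit
    prob = expit(b0 + lp)
    df["T2DM"] = rng.binomial(1, prob)

    if config.missing_rate > 0:
        for col in (*LIPIDS, "genotype_code"):
            mask = rng.random(n) < config.missing_rate
            df.loc[mask, col] = np.nan
        df.loc[df["genotype_code"].isna(), "genotype"] = "./."

    df.attrs["baseline_logit"] = b0
    df.attrs["realized_prevalence"] = float(df["T2DM"].mean())
    return df


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """One call: families + phenotypes + truth, with column order fixed."""
    rng = np.random.default_rng(config.seed)
    fam = simulate_families(config, rng)
    df = simulate_phenotypes(fam, config, rng)
    df = df.loc[:, list(COHORT_COLUMNS)]
    return df, make_truth(config)


def generating_mediation_models(config: SimulationConfig, cohort: pd.DataFrame):
    """Re-express the generating model as (MediatorModel, OutcomeModel).

    The mediator regression is the linear projection the config implies
    (slope from :func:`implied_mediator_slope`, covariate slopes
    linearised at the centering point, residual variance from the
    log-normal spread); the outcome model is the generator's logistic
    model re-written without centering, using the tuned intercept stored
    in ``cohort.attrs["baseline_logit"]``.  Useful as a ground-truth
    input to the closed-form/oracle machinery without fitting anything.
    """
    from .mediation import MediatorModel, OutcomeModel  # local: avoid cycle

    lip = config.mediator
    centers = _covariate_centers(config)
    q = config.risk_allele_freq
    sd = config.residual_sd.get(lip, DEFAULT_RESIDUAL_SD[lip])
    mean_m = float(cohort[lip].mean())
    beta1 = implied_mediator_slope(config)
    beta_cov = {c: config.covariate_effects_lipid.get(c, 0.0) * mean_m
                for c in _COVARIATE_COLS}
    beta0 = (mean_m - beta1 * 2 * q
             - sum(beta_cov[c] * centers[c] for c in _COVARIATE_COLS))
    mm = MediatorModel(
        beta0=beta0, beta1=beta1, beta_cov=beta_cov,
        sigma2=(sd * mean_m) ** 2, covariates=tuple(_COVARIATE_COLS),
        covariate_means={c: float(cohort[c].mean()) for c in _COVARIATE_COLS},
        n_used=len(cohort),
    )
    b0 = cohort.attrs.get("baseline_logit")
    if b0 is None:
        raise ConfigurationError("cohort lacks the tuned baseline_logit attr")
    theta_cov = {c: config.covariate_effects_disease.get(c, 0.0)
                 for c in _COVARIATE_COLS}
    theta0 = (b0 - config.theta_direct * 2 * q
              - sum(theta_cov[c] * centers[c] for c in _COVARIATE_COLS))
    om = OutcomeModel(
        theta0=theta0, theta1=config.theta_direct,
        theta2=config.theta_mediator, theta_cov=theta_cov,
        theta3=None, n_used=len(cohort),
    )
    return mm, om


# ---------------------------------------------------------------------------
# scenarios

SCENARIOS = ("paper_like", "null", "strong_mediation")


def make_scenario(name: str, seed: int, **overrides) -> SimulationConfig:
    """Named study conditions.

    * ``paper_like`` — the defaults: 2885 families, risk-allele frequency
      0.34, published per-allele lipid effects, direct disease log-OR
      0.154, mediator effect ln(1.06) per mmol/L TC, prevalence 0.38.
    * ``null`` — no genotype effect anywhere (type-I-error runs).
    * ``strong_mediation`` — a large mediated path through TC with the
      direct effect solved in closed form so the implied proportion
      mediated is exactly 0.5; ~20k individuals for recovery tests.
    """
    if name == "paper_like":
        cfg = SimulationConfig(seed=seed, **overrides)
    elif name == "null":
        params = dict(
            lipid_effects={lip: 0.0 for lip in LIPIDS},
            theta_direct=0.0,
            theta_mediator=0.0,
        )
        params.update(overrides)
        cfg = SimulationConfig(seed=seed, **params)
    elif name == "strong_mediation":
        params = dict(
            n_families=9880,
            lipid_effects=dict(DEFAULT_LIPID_EFFECTS, TC=0.10),
            theta_mediator=0.45,
            theta_direct=0.0,  # placeholder, solved below
        )
        params.update(overrides)
        cfg = SimulationConfig(seed=seed, **params)
        # PM(ORd, ORi) = ORd(ORi-1)/(ORd·ORi-1) = 1/2  =>  ORd = 1/(2-ORi)
        ori = math.exp(cfg.theta_mediator * implied_mediator_slope(cfg))
        if ori >= 2.0:
            raise ConfigurationError("indirect OR too large for PM = 0.5")
        cfg.theta_direct = math.log(1.0 / (2.0 - ori))
    else:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return cfg


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
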