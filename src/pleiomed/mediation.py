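"""Counterfactual mediation of the genotype-disease effect through a lipid.

The decomposition follows the standard regression-based approach for a
binary outcome and a continuous (normal) mediator:

* mediator model  M = β0 + β1·A + β2'C + ε,  ε ~ N(0, σ²)   (least squares)
* outcome model   logit P(Y=1) = θ0 + θ1·A + θ2·M [+ θ3·A·M] + θc'C

Under the no-interaction model and the rare-outcome approximation the
natural direct and indirect effects per unit exposure contrast are

    OR^direct   = exp(θ1 (a − a*))
    OR^indirect = exp(θ2 β1 (a − a*))
    OR^total    = OR^direct · OR^indirect   (exactly, in this closed form)

With an exposure-mediator interaction the θ3 and σ² terms enter the
closed forms.  The proportion mediated uses the excess-odds form
PM = OR^d(OR^i − 1)/(OR^d·OR^i − 1).  A Monte-Carlo potential-outcome
oracle (:func:`mc_counterfactual_oracle`) integrates the same two models
over simulated counterfactual mediator values; it matches the closed
forms when the outcome is rare and quantifies the approximation error
when it is not (this cohort's 38% prevalence).

Confidence intervals come from a nonparametric bootstrap that resamples
whole families, respecting the within-family clustering of genotype and
lipid levels.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._glm import logit_fit, ols_beta
from .association import DEFAULT_ADJUST, _complete_cases, _fit_logit
from .errors import (ConfigurationError, DataError, DegenerateDesignError,
                     NullTotalEffectError)

logger = logging.getLogger("pleiomed")


@dataclass(frozen=True)
class MediatorModel:
    """Fitted linear model of the mediator on exposure and covariates."""

    beta0: float
    beta1: float
    beta_cov: dict
    sigma2: float
    covariates: tuple
    covariate_means: dict
    n_used: int

    def __post_init__(self):
        if not self.sigma2 > 0:
            raise DegenerateDesignError("mediator residual variance must be > 0")


@dataclass(frozen=True)
class OutcomeModel:
    """Fitted logistic model of disease on exposure, mediator, covariates."""

    theta0: float
    theta1: float
    theta2: float
    theta_cov: dict
    theta3: float | None = None
    n_used: int = 0


class NaturalEffects(NamedTuple):
    or_direct: float
    or_indirect: float
    or_total: float


@dataclass(frozen=True)
class MediationResult:
    """Direct/indirect/total odds ratios, PM, and bootstrap intervals."""

    mediator: str
    contrast: tuple
    or_direct: float
    or_indirect: float
    or_total: float
    pm: float
    ci_direct: tuple
    ci_indirect: tuple
    ci_total: tuple
    ci_pm: tuple
    n_boot: int
    n_used: int
    pm_defined: bool = True
    pm_formula: str = "corrected"

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for k in ("contrast", "ci_direct", "ci_indirect", "ci_total", "ci_pm"):
            d[k] = list(d[k])
        return d


# ---------------------------------------------------------------------------
# model fitting

def fit_mediation_models(
    data: pd.DataFrame,
    mediator: str,
    covariates=None,
    exposure: str = "genotype_code",
    outcome: str = "T2DM",
    interaction: bool = False,
) -> tuple[MediatorModel, OutcomeModel]:
    """Fit the two mediation regressions on one shared complete-case set.

    The mediator enters on its raw mmol/L scale.  Rows missing any column
    used by either model are dropped from both (the intersection), so the
    two fits describe the same individuals.
    """
    covs = list(covariates if covariates is not None else DEFAULT_ADJUST)
    cols = [outcome, exposure, mediator, *covs]
    cc = _complete_cases(data, cols)
    dropped = len(data) - len(cc)
    if dropped:
        logger.info("mediation %s: fitting both models on %d shared complete "
                    "cases (%d rows dropped)", mediator, len(cc), dropped)
    if len(cc) <= len(covs) + 3:
        raise DegenerateDesignError("too few complete cases for mediation models")
    a = cc[exposure].to_numpy(float)
    m = cc[mediator].to_numpy(float)
    if np.std(a) == 0:
        raise DegenerateDesignError(f"exposure {exposure!r} is constant")
    if np.std(m) == 0:
        raise DegenerateDesignError(f"mediator {mediator!r} is constant")
    y = cc[outcome].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise DegenerateDesignError(f"outcome {outcome!r} is single-class")

    Xm = sm.add_constant(cc[[exposure, *covs]].astype(float), has_constant="add")
    med_res = sm.OLS(m, Xm).fit()
    mm = MediatorModel(
        beta0=float(med_res.params["const"]),
        beta1=float(med_res.params[exposure]),
        beta_cov={c: float(med_res.params[c]) for c in covs},
        sigma2=float(med_res.mse_resid),
        covariates=tuple(covs),
        covariate_means={c: float(cc[c].mean()) for c in covs},
        n_used=len(cc),
    )

    cols_y = [exposure, mediator, *covs]
    Xy = cc[cols_y].astype(float).copy()
    if interaction:
        Xy["_ax_m"] = Xy[exposure] * Xy[mediator]
    Xy = sm.add_constant(Xy, has_constant="add")
    out_res = _fit_logit(Xy, y, {})
    om = OutcomeModel(
        theta0=float(out_res.params["const"]),
        theta1=float(out_res.params[exposure]),
        theta2=float(out_res.params[mediator]),
        theta_cov={c: float(out_res.params[c]) for c in covs},
        theta3=float(out_res.params["_ax_m"]) if interaction else None,
        n_used=len(cc),
    )
    return mm, om


# ---------------------------------------------------------------------------
# closed-form natural effects

def natural_effects(
    mm: MediatorModel,
    om: OutcomeModel,
    a: float = 1.0,
    a_star: float = 0.0,
    covariate_values: dict | None = None,
) -> NaturalEffects:
    """Natural direct/indirect odds ratios for the contrast (a, a*).

    No-interaction closed form (rare-outcome approximation):
    OR^d = exp(θ1 d), OR^i = exp(θ2 β1 d) with d = a − a*.  When the
    outcome model carries an exposure-mediator interaction θ3, the normal-
    mediator closed forms apply; the direct effect then depends on the
    covariate values (defaults: the fitted covariate means) and on σ².
    """
    if a == a_star:
        warnings.warn("contrast with a == a*: identity odds ratios returned",
                      stacklevel=2)
        return NaturalEffects(1.0, 1.0, 1.0)
    d = a - a_star
    if om.theta3 is None:
        log_ord = om.theta1 * d
        log_ori = om.theta2 * mm.beta1 * d
    else:
        cvals = covariate_values if covariate_values is not None else mm.covariate_means
        cov_mean = sum(mm.beta_cov[c] * cvals[c] for c in mm.covariates)
        mu_astar = mm.beta0 + mm.beta1 * a_star + cov_mean
        log_ord = ((om.theta1 + om.theta3 * (mu_astar + om.theta2 * mm.sigma2)) * d
                   + 0.5 * om.theta3 ** 2 * mm.sigma2 * (a * a - a_star * a_star))
        log_ori = (om.theta2 * mm.beta1 + om.theta3 * mm.beta1 * a) * d
    return NaturalEffects(math.exp(log_ord), math.exp(log_ori),
                          math.exp(log_ord + log_ori))


PM_FORMULAS = ("corrected", "as-printed")


def proportion_mediated(
    or_direct: float, or_indirect: float,
    formula: str = "corrected", tol: float = 1e-9,
) -> float:
    """Proportion of the total effect carried by the mediator pathway.

    The default ("corrected") excess-odds form is
    PM = OR^d(OR^i − 1)/(OR^d·OR^i − 1): zero when nothing is mediated
    (OR^i = 1) and one when everything is (OR^d = 1).  The "as-printed"
    variant OR^d(OR^d − 1)/(OR^d·OR^i − 1) replaces OR^i with OR^d in the
    numerator; it fails both boundary cases and is retained for audit
    only.  A null total effect leaves PM undefined and raises
    :class:`~pleiomed.errors.NullTotalEffectError` — never a silent 0.
    """
    if or_direct <= 0 or or_indirect <= 0:
        raise ValueError("odds ratios must be positive")
    if formula not in PM_FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; choose from {PM_FORMULAS}")
    total = or_direct * or_indirect
    if abs(math.log(total)) <= tol:
        raise NullTotalEffectError(
            "proportion mediated is undefined for a null total effect")
    if formula == "as-printed":
        return or_direct * (or_direct - 1.0) / (total - 1.0)
    return or_direct * (or_indirect - 1.0) / (total - 1.0)


# ---------------------------------------------------------------------------
# Monte-Carlo potential-outcome oracle

class OracleResult(NamedTuple):
    or_direct: float
    or_indirect: float
    se_log_direct: float
    se_log_indirect: float


def mc_counterfactual_oracle(
    mm: MediatorModel,
    om: OutcomeModel,
    covariates: pd.DataFrame,
    n_mc: int = 1_000_000,
    seed: int | None = None,
    a: float = 1.0,
    a_star: float = 0.0,
    n_batches: int = 50,
) -> OracleResult:
    """Potential-outcome Monte-Carlo estimate of the natural-effect ORs.

    For each draw, a covariate row is resampled and a counterfactual
    mediator value M(a') ~ N(μ(a', c), σ²) is simulated; the outcome model
    gives the risk P(Y(a, M(a'))=1 | c).  Averaging over draws yields the
    marginal counterfactual risks, whose odds form

        OR^d = odds(E[Y(a, M(a*))]) / odds(E[Y(a*, M(a*))])
        OR^i = odds(E[Y(a, M(a))])  / odds(E[Y(a, M(a*))])

    Each counterfactual risk uses an independent set of draws, so the
    batch-means Monte-Carlo SEs (``n_batches`` batches) honestly reflect
    the sampling noise of the reported log-ORs.  ``n_mc`` below ~1e5
    gives unstable estimates.
    """
    if n_mc < 1000:
        raise ConfigurationError("n_mc too small for a meaningful oracle run")
    rng = np.random.default_rng(seed)
    cols = list(mm.covariates)
    cov = covariates[cols].to_numpy(float) if cols else np.zeros((len(covariates), 0))
    if len(cov) == 0:
        raise DataError("empty covariate sample")
    bm = np.array([mm.beta_cov[c] for c in cols])
    tc = np.array([om.theta_cov[c] for c in cols])
    mu_cov = cov @ bm if cols else np.zeros(len(cov))
    lp_cov = cov @ tc if cols else np.zeros(len(cov))

    n_mc = int(n_mc // n_batches * n_batches)
    sigma = math.sqrt(mm.sigma2)

    def risks(a_y: float, a_m: float) -> np.ndarray:
        idx = rng.integers(0, len(cov), size=n_mc)
        z = rng.standard_normal(n_mc)
        m = mm.beta0 + mm.beta1 * a_m + mu_cov[idx] + sigma * z
        lp = om.theta0 + om.theta1 * a_y + om.theta2 * m + lp_cov[idx]
        if om.theta3 is not None:
            lp = lp + om.theta3 * a_y * m
        return expit(lp)

    r_aa = risks(a, a)          # E[Y(a, M(a))]
    r_as = risks(a, a_star)     # E[Y(a, M(a*))]
    r_ss = risks(a_star, a_star)

    def batch_logs(r_num: np.ndarray, r_den: np.ndarray):
        num = r_num.reshape(n_batches, -1).mean(axis=1)
        den = r_den.reshape(n_batches, -1).mean(axis=1)
        logs = np.log(num / (1 - num)) - np.log(den / (1 - den))
        overall = (math.log(r_num.mean() / (1 - r_num.mean()))
                   - math.log(r_den.mean() / (1 - r_den.mean())))
        return overall, float(np.std(logs, ddof=1) / math.sqrt(n_batches))

    log_ord, se_d = batch_logs(r_as, r_ss)
    log_ori, se_i = batch_logs(r_aa, r_as)
    return OracleResult(math.exp(log_ord), math.exp(log_ori), se_d, se_i)


# ---------------------------------------------------------------------------
# bootstrap estimator

class MediationAnalysis(BaseEstimator):
    """Full mediation decomposition with family-bootstrap intervals.

    Point estimates come from the two statsmodels fits on the complete
    data; percentile CIs from ``n_boot`` nonparametric resamples of whole
    families (individuals via ``resample="individual"``).  Degenerate
    replicates (constant exposure, single-class outcome, non-convergence)
    are redrawn up to ``retry_cap`` times each before erroring out.

    Fitted attributes: ``or_direct_``, ``or_indirect_``, ``or_total_``,
    ``pm_``, the ``ci_*_`` tuples, ``mediator_model_``,
    ``outcome_model_`` and ``result_``.
    """

    def __init__(self, mediator="TC", covariates=None, exposure="genotype_code",
                 outcome="T2DM", n_boot=1000, seed=None, resample="family",
                 pm_formula="corrected", contrast=(1.0, 0.0), family_col="FID",
                 interaction=False, retry_cap=10):
        self.mediator = mediator
        self.covariates = covariates
        self.exposure = exposure
        self.outcome = outcome
        self.n_boot = n_boot
        self.seed = seed
        self.resample = resample
        self.pm_formula = pm_formula
        self.contrast = contrast
        self.family_col = family_col
        self.interaction = interaction
        self.retry_cap = retry_cap

    # -- helpers -----------------------------------------------------------

    def _effects_from_coefs(self, beta1, theta1, theta2, theta3, sigma2,
                            mu_astar) -> tuple[float, float]:
        a, a_star = self.contrast
        d = a - a_star
        if theta3 is None:
            return theta1 * d, theta2 * beta1 * d
        log_ord = ((theta1 + theta3 * (mu_astar + theta2 * sigma2)) * d
                   + 0.5 * theta3 ** 2 * sigma2 * (a * a - a_star * a_star))
        log_ori = (theta2 * beta1 + theta3 * beta1 * a) * d
        return log_ord, log_ori

    def fit(self, X: pd.DataFrame, y=None) -> "MediationAnalysis":
        if self.n_boot < 200:
            raise ConfigurationError("n_boot must be at least 200")
        if self.seed is None:
            raise ConfigurationError("a bootstrap seed is mandatory")
        if self.resample not in ("family", "individual"):
            raise ValueError(f"unknown resample unit {self.resample!r}")
        covs = list(self.covariates if self.covariates is not None else DEFAULT_ADJUST)
        mm, om = fit_mediation_models(
            X, self.mediator, covs, self.exposure, self.outcome, self.interaction)
        self.mediator_model_, self.outcome_model_ = mm, om
        a, a_star = self.contrast
        ne = natural_effects(mm, om, a, a_star)
        self.or_direct_, self.or_indirect_, self.or_total_ = ne
        try:
            self.pm_ = proportion_mediated(ne.or_direct, ne.or_indirect,
                                           self.pm_formula)
            pm_defined = True
        except NullTotalEffectError:
            self.pm_, pm_defined = float("nan"), False

        boots = self._bootstrap(X, covs, mm, om)
        pct = lambda v: tuple(np.percentile(v, [2.5, 97.5]))
        self.ci_direct_ = pct(boots["ord"])
        self.ci_indirect_ = pct(boots["ori"])
        self.ci_total_ = pct(boots["ort"])
        pm_ok = boots["pm"][np.isfinite(boots["pm"])]
        self.ci_pm_ = pct(pm_ok) if len(pm_ok) >= 0.5 * self.n_boot else \
            (float("nan"), float("nan"))
        self.result_ = MediationResult(
            mediator=self.mediator, contrast=(a, a_star),
            or_direct=self.or_direct_, or_indirect=self.or_indirect_,
            or_total=self.or_total_, pm=self.pm_,
            ci_direct=self.ci_direct_, ci_indirect=self.ci_indirect_,
            ci_total=self.ci_total_, ci_pm=self.ci_pm_,
            n_boot=self.n_boot, n_used=mm.n_used,
            pm_defined=pm_defined, pm_formula=self.pm_formula,
        )
        return self

    def _bootstrap(self, X: pd.DataFrame, covs: list, mm: MediatorModel,
                   om: OutcomeModel) -> dict:
        cols = [self.outcome, self.exposure, self.mediator, *covs, self.family_col]
        cc = _complete_cases(X, cols).reset_index(drop=True)
        a_col = cc[self.exposure].to_numpy(float)
        m_col = cc[self.mediator].to_numpy(float)
        y_col = cc[self.outcome].to_numpy(float)
        covmat = cc[covs].to_numpy(float) if covs else np.zeros((len(cc), 0))
        n = len(cc)
        ones = np.ones(n)
        Xm_full = np.column_stack([ones, a_col, covmat])
        if self.interaction:
            Xy_full = np.column_stack([ones, a_col, m_col, covmat, a_col * m_col])
        else:
            Xy_full = np.column_stack([ones, a_col, m_col, covmat])

        # warm start for the bootstrap logit fits
        theta_full = np.concatenate([
            [om.theta0, om.theta1, om.theta2],
            [om.theta_cov[c] for c in covs],
            [om.theta3] if om.theta3 is not None else [],
        ])
        a_star = self.contrast[1]
        cov_means_vec = np.array([mm.covariate_means[c] for c in covs])

        if self.resample == "family":
            fam_codes = pd.factorize(cc[self.family_col])[0]
            order = np.argsort(fam_codes, kind="stable")
            bounds = np.flatnonzero(np.diff(fam_codes[order], prepend=-1))
            groups = np.split(order, bounds[1:])
            n_units = len(groups)
        else:
            groups = None
            n_units = n

        rng = np.random.default_rng(self.seed)
        out = {k: np.empty(self.n_boot) for k in ("ord", "ori", "ort", "pm")}
        for b in range(self.n_boot):
            for attempt in range(self.retry_cap + 1):
                if groups is not None:
                    pick = rng.integers(0, n_units, size=n_units)
                    ridx = np.concatenate([groups[i] for i in pick])
                else:
                    ridx = rng.integers(0, n_units, size=n_units)
                ab, yb = a_col[ridx], y_col[ridx]
                if np.std(ab) == 0 or yb.min() == yb.max():
                    continue
                Xm_b, Xy_b = Xm_full[ridx], Xy_full[ridx]
                beta_b = ols_beta(Xm_b, m_col[ridx])
                theta_b, conv = logit_fit(Xy_b, yb, beta0=theta_full)
                if not conv:
                    continue
                if self.interaction:
                    resid = m_col[ridx] - Xm_b @ beta_b
                    sigma2_b = float(resid @ resid / max(len(ridx) - Xm_b.shape[1], 1))
                    mu_astar_b = (beta_b[0] + beta_b[1] * a_star
                                  + (beta_b[2:] @ cov_means_vec if covs else 0.0))
                    theta3_b = theta_b[-1]
                else:
                    sigma2_b, mu_astar_b, theta3_b = mm.sigma2, 0.0, None
                log_ord, log_ori = self._effects_from_coefs(
                    beta_b[1], theta_b[1], theta_b[2], theta3_b, sigma2_b,
                    mu_astar_b)
                out["ord"][b] = math.exp(log_ord)
                out["ori"][b] = math.exp(log_ori)
                out["ort"][b] = math.exp(log_ord + log_ori)
                try:
                    out["pm"][b] = proportion_mediated(
                        out["ord"][b], out["ori"][b], self.pm_formula)
                except NullTotalEffectError:
                    out["pm"][b] = float("nan")
                break
            else:
                raise DegenerateDesignError(
                    f"bootstrap replicate {b} degenerate after "
                    f"{self.retry_cap} redraws")
        return out


def bootstrap_mediation(data, mediator, covariates=None, n_boot=1000,
                        seed=None, **kwargs) -> MediationResult:
    """Functional wrapper over :class:`MediationAnalysis`."""
    est = MediationAnalysis(mediator=mediator, covariates=covariates,
                            n_boot=n_boot, seed=seed, **kwargs).fit(data)
    return est.result_
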