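"""Additive-model association fits with percent-change reporting.

Three estimators, all scikit-learn ``BaseEstimator`` subclasses taking the
cohort DataFrame in ``fit``:

* :class:`LipidAssociation` — OLS of ln(lipid) on risk-allele dosage plus
  covariates; the dosage coefficient β is a log-scale slope, reported as
  the percent change 100·(exp(β) − 1) per allele.
* :class:`DiseaseAssociation` — logistic regression of disease on dosage
  plus covariates (Model 1) or additionally on TC, TG, LDL-C and HDL-C
  (Model 2); β is the per-allele log-OR.
* :class:`LipidToDisease` — logistic regression of disease on one lipid
  (raw mmol/L) plus covariates; percent change per 1 mmol/L.

Wald 95% CIs use the fixed 1.96 normal multiplier and are transformed
through the same exponential map as the point estimate.  Standard errors
are plain by default; ``robust="family"`` switches to cluster-robust SEs
grouped on the family ID, which is the appropriate choice for this
family-clustered design.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, clone

from .errors import DataError, DegenerateDesignError
from .io import LIPIDS

logger = logging.getLogger("pleiomed")

#: Adjustment set used by every published model.
DEFAULT_ADJUST = ("age", "sex", "smoker", "drinker", "hypertension", "CHD", "BMI")

#: Lipids added as covariates in the disease "Model 2".
MODEL2_LIPIDS = ("TC", "TG", "LDL_C", "HDL_C")

#: Fixed normal multiplier for 95% Wald intervals.
CI_Z = 1.96


class PercentChange(NamedTuple):
    pc: float
    ci_low: float
    ci_high: float


def percent_change(beta: float, se: float) -> PercentChange:
    """Percent change 100·(exp(β) − 1) with its Wald 95% CI.

    The interval is computed on the β scale (β ± 1.96·SE) and pushed
    through the same exponential map, so it is asymmetric around the
    point estimate whenever β is away from 0.
    """
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    return PercentChange(
        pc=100.0 * np.expm1(beta),
        ci_low=100.0 * np.expm1(beta - CI_Z * se),
        ci_high=100.0 * np.expm1(beta + CI_Z * se),
    )


@dataclass(frozen=True)
class AssociationResult:
    """One fitted regression contrast, ready for a results table."""

    outcome: str
    exposure: str
    beta: float
    se: float
    pc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    adjust_set: tuple = field(default_factory=tuple)
    model: str = "linear"

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["adjust_set"] = list(self.adjust_set)
        return d


def _complete_cases(data: pd.DataFrame, cols: list) -> pd.DataFrame:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"data lacks required columns {missing}")
    return data.dropna(subset=cols)


def _check_exposure(x: np.ndarray, name: str) -> None:
    if np.nanstd(x) == 0.0:
        raise DegenerateDesignError(f"exposure column {name!r} is constant")


def _design(cc: pd.DataFrame, exposure: str, covariates: list) -> pd.DataFrame:
    X = cc[[exposure, *covariates]].astype(float)
    return sm.add_constant(X, has_constant="add")


def _fit_kwargs(robust, cc: pd.DataFrame, family_col: str) -> dict:
    if robust is None or robust == "none":
        return {}
    if robust == "family":
        if family_col not in cc.columns:
            raise DataError(f"robust='family' needs a {family_col!r} column")
        groups = pd.factorize(cc[family_col])[0]
        return {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
    raise ValueError(f"unknown robust option {robust!r}")


class _AssociationMixin:
    """Shared extraction of (β, SE, PC, CI, P) for the exposure term."""

    def _finalize(self, res, exposure: str, outcome: str, covariates,
                  model: str, n_used: int) -> None:
        beta = float(res.params[exposure])
        se = float(res.bse[exposure])
        pc = percent_change(beta, se)
        self.beta_ = beta
        self.se_ = se
        self.pc_, self.ci_low_, self.ci_high_ = pc
        self.p_value_ = float(res.pvalues[exposure])
        self.n_used_ = n_used
        self.result_ = AssociationResult(
            outcome=outcome, exposure=exposure, beta=beta, se=se,
            pc=pc.pc, ci_low=pc.ci_low, ci_high=pc.ci_high,
            p_value=self.p_value_, n_used=n_used,
            adjust_set=tuple(covariates), model=model,
        )


class LipidAssociation(BaseEstimator, _AssociationMixin):
    """OLS of ln(lipid) on risk-allele dosage and covariates.

    Parameters
    ----------
    lipid : str
        Outcome lipid column (strictly positive mmol/L values).
    covariates : sequence of str, optional
        Adjustment set; defaults to the study's seven covariates.
    robust : {None, "none", "family"}
        Plain SEs (default) or family-cluster-robust SEs.
    log_transform : bool
        Model ln(lipid) (default).  ``False`` fits the raw scale; the
        percent-change transform is then not meaningful and is still
        reported only for API uniformity.
    """

    def __init__(self, lipid="TC", covariates=None, exposure="genotype_code",
                 robust=None, log_transform=True, family_col="FID"):
        self.lipid = lipid
        self.covariates = covariates
        self.exposure = exposure
        self.robust = robust
        self.log_transform = log_transform
        self.family_col = family_col

    def fit(self, X: pd.DataFrame, y=None) -> "LipidAssociation":
        covs = list(self.covariates if self.covariates is not None else DEFAULT_ADJUST)
        cols = [self.lipid, self.exposure, *covs]
        if self.robust == "family":
            cols.append(self.family_col)
        cc = _complete_cases(X, cols)
        if len(cc) <= len(covs) + 2:
            raise DegenerateDesignError(
                f"n={len(cc)} complete cases for {len(covs) + 2} parameters")
        xvec = cc[self.exposure].to_numpy(float)
        _check_exposure(xvec, self.exposure)
        outcome = cc[self.lipid].to_numpy(float)
        if self.log_transform:
            if (outcome <= 0).any():
                raise DataError(f"{self.lipid} has non-positive values; "
                                "cannot log-transform")
            outcome = np.log(outcome)
        design = _design(cc, self.exposure, covs)
        res = sm.OLS(outcome, design).fit(**_fit_kwargs(self.robust, cc, self.family_col))
        self._finalize(res, self.exposure, self.lipid, covs, "linear", len(cc))
        return self


def _fit_logit(design: pd.DataFrame, y: np.ndarray, fit_kwargs: dict):
    """Logit fit that converts separation/singularity into package errors."""
    with warnings.catch_warnings():
        warnings.filterwarnings("error", message=".*[Ss]eparation.*")
        try:
            model = sm.Logit(y, design)
            res = model.fit(disp=0, maxiter=100, **fit_kwargs)
        except (np.linalg.LinAlgError, Warning) as exc:
            raise DegenerateDesignError(
                f"logistic fit failed (possible perfect separation): {exc}"
            ) from exc
    if not res.mle_retvals.get("converged", True):
        raise DegenerateDesignError("logistic fit did not converge")
    return res


class DiseaseAssociation(BaseEstimator, _AssociationMixin):
    """Logistic regression of disease on risk-allele dosage.

    ``include_lipids=True`` reproduces "Model 2": TC, TG, LDL-C and HDL-C
    join the adjustment set.
    """

    def __init__(self, outcome="T2DM", covariates=None, include_lipids=False,
                 exposure="genotype_code", robust=None, family_col="FID"):
        self.outcome = outcome
        self.covariates = covariates
        self.include_lipids = include_lipids
        self.exposure = exposure
        self.robust = robust
        self.family_col = family_col

    def fit(self, X: pd.DataFrame, y=None) -> "DiseaseAssociation":
        covs = list(self.covariates if self.covariates is not None else DEFAULT_ADJUST)
        if self.include_lipids:
            covs += [l for l in MODEL2_LIPIDS if l not in covs]
        cols = [self.outcome, self.exposure, *covs]
        if self.robust == "family":
            cols.append(self.family_col)
        cc = _complete_cases(X, cols)
        yvec = cc[self.outcome].to_numpy(float)
        if len(np.unique(yvec)) < 2:
            raise DegenerateDesignError(f"outcome {self.outcome!r} is single-class")
        _check_exposure(cc[self.exposure].to_numpy(float), self.exposure)
        design = _design(cc, self.exposure, covs)
        res = _fit_logit(design, yvec, _fit_kwargs(self.robust, cc, self.family_col))
        model = "logistic-model2" if self.include_lipids else "logistic"
        self._finalize(res, self.exposure, self.outcome, covs, model, len(cc))
        return self


class LipidToDisease(BaseEstimator, _AssociationMixin):
    """Logistic regression of disease on one lipid (per 1 mmol/L)."""

    def __init__(self, lipid="TC", outcome="T2DM", covariates=None,
                 robust=None, family_col="FID"):
        self.lipid = lipid
        self.outcome = outcome
        self.covariates = covariates
        self.robust = robust
        self.family_col = family_col

    def fit(self, X: pd.DataFrame, y=None) -> "LipidToDisease":
        covs = list(self.covariates if self.covariates is not None else DEFAULT_ADJUST)
        cols = [self.outcome, self.lipid, *covs]
        if self.robust == "family":
            cols.append(self.family_col)
        cc = _complete_cases(X, cols)
        yvec = cc[self.outcome].to_numpy(float)
        if len(np.unique(yvec)) < 2:
            raise DegenerateDesignError(f"outcome {self.outcome!r} is single-class")
        _check_exposure(cc[self.lipid].to_numpy(float), self.lipid)
        design = _design(cc, self.lipid, covs)
        res = _fit_logit(design, yvec, _fit_kwargs(self.robust, cc, self.family_col))
        self._finalize(res, self.lipid, self.outcome, covs, "logistic", len(cc))
        return self


# ---------------------------------------------------------------------------
# functional wrappers

def fit_lipid_association(data, lipid, covariates=None, robust=None,
                          log_transform=True) -> AssociationResult:
    est = LipidAssociation(lipid=lipid, covariates=covariates, robust=robust,
                           log_transform=log_transform).fit(data)
    return est.result_


def fit_disease_association(data, adjust_set=None, include_lipids=False,
                            robust=None) -> AssociationResult:
    est = DiseaseAssociation(covariates=adjust_set,
                             include_lipids=include_lipids, robust=robust).fit(data)
    return est.result_


def fit_lipid_to_disease(data, lipid, covariates=None, robust=None) -> AssociationResult:
    est = LipidToDisease(lipid=lipid, covariates=covariates, robust=robust).fit(data)
    return est.result_


# ---------------------------------------------------------------------------
# subgroup analysis

#: stratifier name -> (column, covariate to drop, labelling function)
_STRATIFIERS = {
    "bmi": ("BMI", "BMI", lambda s, cut: np.where(s >= cut, f"BMI>={cut:g}",
                                                  f"BMI<{cut:g}")),
    "smoker": ("smoker", "smoker", lambda s, cut: np.where(s == 1, "smoker",
                                                           "nonsmoker")),
    "drinker": ("drinker", "drinker", lambda s, cut: np.where(s == 1, "drinker",
                                                              "nondrinker")),
}


@dataclass(frozen=True)
class SubgroupResults:
    """Association results keyed by stratum, with stratum sizes."""

    stratifier: str
    results: dict
    sizes: dict


def subgroup_analysis(data: pd.DataFrame, stratifier: str, analysis,
                      bmi_cutoff: float = 24.0) -> SubgroupResults:
    """Run an association separately in the two strata of a binary split.

    ``analysis`` is either an unfitted estimator (cloned per stratum, with
    the stratifying variable removed from its adjustment set) or a plain
    callable ``data -> AssociationResult``.  Empty strata are skipped with
    a logged warning.
    """
    if stratifier not in _STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}; "
                         f"choose from {sorted(_STRATIFIERS)}")
    col, drop_cov, labeller = _STRATIFIERS[stratifier]
    if col not in data.columns:
        raise DataError(f"stratifier column {col!r} not in data")
    labels = labeller(data[col].to_numpy(float), bmi_cutoff)
    results, sizes = {}, {}
    for label in pd.unique(labels):
        sub = data.loc[labels == label]
        sizes[str(label)] = int(len(sub))
        if len(sub) == 0:
            logger.warning("subgroup %s: stratum %s is empty, skipped",
                           stratifier, label)
            warnings.warn(f"stratum {label} is empty; skipped", stacklevel=2)
            continue
        if hasattr(analysis, "fit") and hasattr(analysis, "get_params"):
            est = clone(analysis)
            covs = est.get_params().get("covariates")
            covs = list(covs if covs is not None else DEFAULT_ADJUST)
            est.set_params(covariates=[c for c in covs if c != drop_cov])
            results[str(label)] = est.fit(sub).result_
        else:
            results[str(label)] = analysis(sub)
    return SubgroupResults(stratifier=stratifier, results=results, sizes=sizes)
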