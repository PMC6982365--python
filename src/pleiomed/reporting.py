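"""Descriptive tables and end-to-end pipeline orchestration.

``descriptive_table`` mirrors the baseline-characteristics table: mean
and SD for continuous variables, percentages for categorical ones, split
by disease status with a comparison P value.  The default comparisons are
unpaired (Welch t / Pearson chi-square); when an explicit case-control
pairing within families is supplied, the paired t-test and McNemar's
chi-square are used instead.  Spreads are standard deviations and are
labelled as such.

``run_pipeline`` chains QC -> descriptives -> genotype-lipid and
genotype-disease associations -> lipid-disease models -> subgroup
analyses -> mediation for all six lipids, writing TSV tables at the
published precision plus a full-precision JSON sidecar and a run log.
The JSON output is byte-identical across reruns of the same config/seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from . import __version__
from .association import (DEFAULT_ADJUST, DiseaseAssociation, LipidAssociation,
                          fit_lipid_association, fit_lipid_to_disease,
                          subgroup_analysis)
from .errors import ConfigurationError, DataError, PipelineError
from .genetics import GenotypeCounts, allele_freq, call_rate, hwe_test
from .io import LIPIDS, read_cohort, write_cohort, write_truth
from .mediation import bootstrap_mediation
from .simulate import SCENARIOS, make_scenario, simulate_cohort

logger = logging.getLogger("pleiomed")

CONTINUOUS_VARS = ("age", "BMI", *LIPIDS)
CATEGORICAL_VARS = ("sex", "smoker", "drinker", "hypertension", "CHD")


def mcnemar_test(b: int, c: int) -> tuple[float, float]:
    """McNemar chi-square (b − c)²/(b + c) on discordant-pair counts,
    without continuity correction, with its 1-df tail probability."""
    if b + c == 0:
        raise DataError("McNemar test undefined with no discordant pairs")
    res = _sm_mcnemar([[0, b], [c, 0]], exact=False, correction=False)
    return float(res.statistic), float(res.pvalue)


def _pair_arrays(data: pd.DataFrame, pairing, var: str):
    idx = data.set_index("IID")[var]
    pairs = [(ca, co) for ca, co in pairing
             if ca in idx.index and co in idx.index]
    if not pairs:
        return None, None
    case_v = np.array([idx[ca] for ca, _ in pairs], float)
    ctrl_v = np.array([idx[co] for _, co in pairs], float)
    keep = ~(np.isnan(case_v) | np.isnan(ctrl_v))
    return case_v[keep], ctrl_v[keep]


def descriptive_table(
    data: pd.DataFrame,
    pairing=None,
    continuous=CONTINUOUS_VARS,
    categorical=CATEGORICAL_VARS,
    group: str = "T2DM",
) -> pd.DataFrame:
    """Case/control descriptive summary with comparison tests.

    Parameters
    ----------
    pairing : sequence of (case IID, control IID), optional
        Within-family one-to-one matches.  When given, continuous
        variables use the paired t-test and categoricals McNemar's
        chi-square; otherwise Welch's two-sample t and Pearson's
        chi-square.  If a pairing is requested but yields no usable pairs
        for a variable, the unpaired test is used and a warning logged.
    """
    if group not in data.columns:
        raise DataError(f"grouping column {group!r} not in data")
    cases = data[data[group] == 1]
    ctrls = data[data[group] == 0]
    if len(cases) == 0 or len(ctrls) == 0:
        raise DataError("descriptive table needs both cases and controls")

    rows = []
    for var in continuous:
        a = cases[var].dropna().to_numpy(float)
        b = ctrls[var].dropna().to_numpy(float)
        test, p = "Welch t", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if pairing is not None:
            pa, pb = _pair_arrays(data, pairing, var)
            if pa is not None and len(pa) > 1:
                test, p = "paired t", float(stats.ttest_rel(pa, pb).pvalue)
            else:
                logger.warning("no usable pairs for %s; unpaired t used", var)
        rows.append({
            "variable": var, "type": "continuous",
            "case_n": len(a), "control_n": len(b),
            "case_mean": a.mean(), "case_sd": a.std(ddof=1),
            "control_mean": b.mean(), "control_sd": b.std(ddof=1),
            "case_pct": np.nan, "control_pct": np.nan,
            "p_value": p, "test": test,
        })
    for var in categorical:
        a = cases[var].dropna().astype(int)
        b = ctrls[var].dropna().astype(int)
        table = np.array([[int((a == 1).sum()), int((a == 0).sum())],
                          [int((b == 1).sum()), int((b == 0).sum())]])
        test = "chi-square"
        if table.min() == 0:
            p = float("nan")
        else:
            p = float(stats.chi2_contingency(table, correction=False)[1])
        if pairing is not None:
            pa, pb = _pair_arrays(data, pairing, var)
            if pa is not None and len(pa) > 0:
                disc_b = int(np.sum((pa == 1) & (pb == 0)))
                disc_c = int(np.sum((pa == 0) & (pb == 1)))
                if disc_b + disc_c > 0:
                    test = "McNemar"
                    _, p = mcnemar_test(disc_b, disc_c)
            else:
                logger.warning("no usable pairs for %s; chi-square used", var)
        rows.append({
            "variable": var, "type": "categorical",
            "case_n": len(a), "control_n": len(b),
            "case_mean": np.nan, "case_sd": np.nan,
            "control_mean": np.nan, "control_sd": np.nan,
            "case_pct": 100.0 * (a == 1).mean(),
            "control_pct": 100.0 * (b == 1).mean(),
            "p_value": p, "test": test,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (YAML-loadable)."""

    seed: int
    scenario: str | None = "paper_like"
    n_families: int | None = None
    data_path: str | None = None
    risk_allele: str = "C"
    adjust_set: tuple = DEFAULT_ADJUST
    mediators: tuple = LIPIDS
    subgroups: tuple = ("bmi", "smoker", "drinker")
    bmi_cutoff: float = 24.0
    n_boot: int = 200
    robust: str | None = None
    outdir: str = "results"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("pipeline seed is mandatory")
        if self.scenario is None and self.data_path is None:
            raise ConfigurationError("either a scenario or a data_path is needed")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        for m in self.mediators:
            if m not in LIPIDS:
                raise ConfigurationError(f"unknown mediator {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("adjust_set", "mediators", "subgroups"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _assoc_row(res) -> dict:
    return {
        "outcome": res.outcome,
        "exposure": res.exposure,
        "model": res.model,
        "beta_se": f"{res.beta:.3f} ({res.se:.3f})",
        "pc_ci": f"{res.pc:.2f} ({res.ci_low:.2f}, {res.ci_high:.2f})",
        "P": _fmt_p(res.p_value),
        "n": res.n_used,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every analysis stage; returns the report dict.

    Writes ``cohort.tsv``/``truth.json`` (simulated runs),
    ``descriptives.tsv``, ``associations.tsv``, ``lipid_to_disease.tsv``,
    ``subgroups.tsv``, ``mediation.tsv``, ``report.json`` and ``run.log``
    under ``config.outdir``.  Any stage failure raises
    :class:`~pleiomed.errors.PipelineError` naming the stage; outputs of
    completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        # outdir is environment-specific and kept out of the reproducible
        # report payload
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()
                   if k != "outdir"},
    }

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s: start", name)
                fn()
                logger.info("stage %s: done", name)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                logger.error("stage %s failed: %s", name, exc)
                logger.removeHandler(handler)
                raise PipelineError(name, str(exc)) from exc
        return deco

    state: dict = {}

    @stage("data")
    def _data():
        if config.data_path is not None:
            state["df"] = read_cohort(config.data_path)
            report["data"] = {"source": str(config.data_path)}
        else:
            overrides = ({"n_families": config.n_families}
                         if config.n_families else {})
            cfg = make_scenario(config.scenario, seed=config.seed, **overrides)
            df, truth = simulate_cohort(cfg)
            write_cohort(df, outdir / "cohort.tsv")
            write_truth(truth, outdir / "truth.json")
            state["df"] = df
            report["data"] = {
                "source": f"simulated:{config.scenario}",
                "n_families": cfg.n_families,
                "realized_prevalence": df.attrs.get("realized_prevalence"),
            }
        report["data"]["n_individuals"] = int(len(state["df"]))

    @stage("qc")
    def _qc():
        df = state["df"]
        counts = GenotypeCounts.from_codes(df["genotype_code"])
        res = hwe_test(counts)
        founders = df[(df["PID"] == "0") & (df["MID"] == "0")]
        ctrl = df[df["T2DM"] == 0]
        report["qc"] = {
            "call_rate": call_rate(df["genotype_code"]),
            "genotype_counts": [counts.n_0, counts.n_1, counts.n_2],
            "risk_allele_freq": allele_freq(counts),
            "hwe_chi2": res.chi2,
            "hwe_p": res.p_value,
            "hwe_p_founders": hwe_test(
                GenotypeCounts.from_codes(founders["genotype_code"])).p_value,
            "hwe_p_controls": hwe_test(
                GenotypeCounts.from_codes(ctrl["genotype_code"])).p_value,
        }

    @stage("descriptives")
    def _descriptives():
        table = descriptive_table(state["df"])
        table.to_csv(outdir / "descriptives.tsv", sep="\t", index=False,
                     float_format="%.4g", lineterminator="\n")
        report["descriptives"] = json.loads(table.to_json(orient="records"))

    @stage("associations")
    def _associations():
        df = state["df"]
        adjust = list(config.adjust_set)
        results = []
        for lip in LIPIDS:
            results.append(fit_lipid_association(df, lip, adjust,
                                                 robust=config.robust))
        m1 = DiseaseAssociation(covariates=adjust, robust=config.robust).fit(df)
        m2 = DiseaseAssociation(covariates=adjust, include_lipids=True,
                                robust=config.robust).fit(df)
        results += [m1.result_, m2.result_]
        pd.DataFrame([_assoc_row(r) for r in results]).to_csv(
            outdir / "associations.tsv", sep="\t", index=False,
            lineterminator="\n")
        report["associations"] = [r.to_dict() for r in results]
        state["m1"] = m1.result_

    @stage("lipid_to_disease")
    def _lipid_to_disease():
        df = state["df"]
        results = [fit_lipid_to_disease(df, lip, list(config.adjust_set),
                                        robust=config.robust)
                   for lip in LIPIDS]
        pd.DataFrame([_assoc_row(r) for r in results]).to_csv(
            outdir / "lipid_to_disease.tsv", sep="\t", index=False,
            lineterminator="\n")
        report["lipid_to_disease"] = [r.to_dict() for r in results]

    @stage("subgroups")
    def _subgroups():
        df = state["df"]
        rows, payload = [], {}
        for strat in config.subgroups:
            for target in (*LIPIDS, "T2DM"):
                if target == "T2DM":
                    est = DiseaseAssociation(covariates=list(config.adjust_set),
                                             robust=config.robust)
                else:
                    est = LipidAssociation(lipid=target,
                                           covariates=list(config.adjust_set),
                                           robust=config.robust)
                sub = subgroup_analysis(df, strat, est,
                                        bmi_cutoff=config.bmi_cutoff)
                for label, res in sub.results.items():
                    rows.append({"stratifier": strat, "stratum": label,
                                 "stratum_n": sub.sizes[label],
                                 **_assoc_row(res)})
                    payload[f"{strat}|{label}|{target}"] = res.to_dict()
        pd.DataFrame(rows).to_csv(outdir / "subgroups.tsv", sep="\t",
                                  index=False, lineterminator="\n")
        report["subgroups"] = payload

    @stage("mediation")
    def _mediation():
        df = state["df"]
        rows, payload = [], []
        for i, med in enumerate(config.mediators):
            res = bootstrap_mediation(
                df, med, list(config.adjust_set), n_boot=config.n_boot,
                seed=config.seed + 1000 + i)
            rows.append({
                "mediator": med,
                "direct_or": f"{res.or_direct:.2f} "
                             f"({res.ci_direct[0]:.2f}, {res.ci_direct[1]:.2f})",
                "indirect_or": f"{res.or_indirect:.2f} "
                               f"({res.ci_indirect[0]:.2f}, {res.ci_indirect[1]:.2f})",
                "total_or": f"{res.or_total:.2f} "
                            f"({res.ci_total[0]:.2f}, {res.ci_total[1]:.2f})",
                "pm_pct": f"{100.0 * res.pm:.1f}" if res.pm_defined else "undef",
                "n": res.n_used,
            })
            payload.append(res.to_dict())
        pd.DataFrame(rows).to_csv(outdir / "mediation.tsv", sep="\t",
                                  index=False, lineterminator="\n")
        report["mediation"] = payload

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n")
    logger.removeHandler(handler)
    handler.close()
    return report
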