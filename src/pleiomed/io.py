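"""Cohort TSV and truth-JSON input/output.

The cohort file is a flat tab-separated table, one row per individual,
with PLINK-style family columns (PID/MID equal to "0" for founders).  All
stages of the pipeline consume this single format.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .errors import DataError

#: Lipid trait columns, in the order the tables print them (mmol/L).
LIPIDS = ("TC", "TG", "LDL_C", "HDL_C", "APO_A", "APO_B")

#: Cohort column order for the emitted TSV.
COHORT_COLUMNS = (
    "FID", "IID", "PID", "MID", "sex", "age", "genotype_code", "genotype",
    *LIPIDS, "T2DM", "BMI", "smoker", "drinker", "hypertension", "CHD",
)

_STR_COLS = ("FID", "IID", "PID", "MID", "genotype")


def write_cohort(data: pd.DataFrame, path) -> None:
    """Write a cohort TSV with a stable column order and float format."""
    missing = [c for c in COHORT_COLUMNS if c not in data.columns]
    if missing:
        raise DataError(f"cohort is missing columns {missing}")
    data.loc[:, list(COHORT_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format="%.6g", lineterminator="\n"
    )


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV, validating that the expected columns exist."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _STR_COLS})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    return df


def write_truth(truth, path) -> None:
    """Serialise a SimulationTruth (dataclass) to pretty, sorted JSON."""
    payload = dataclasses.asdict(truth)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
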