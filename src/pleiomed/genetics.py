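"""Genotype coding, allele frequencies, and Hardy-Weinberg testing.

The study SNP is biallelic; genotypes arrive either as unordered allele
pairs ("A/C") or as risk-allele dosages 0/1/2 under the additive model.
Hardy-Weinberg equilibrium is assessed with the classic 1-df Pearson
chi-square comparing observed genotype counts with the q^2 N, 2pq N, p^2 N
expectation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, MonomorphicError

#: Missing-genotype tokens accepted in allele-pair columns.
MISSING_TOKENS = {"", ".", "./.", "0/0", "NA", "nan"}


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of individuals carrying 0, 1 or 2 copies of the risk allele."""

    n_0: int
    n_1: int
    n_2: int

    def __post_init__(self) -> None:
        if min(self.n_0, self.n_1, self.n_2) < 0:
            raise DataError("genotype counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_0 + self.n_1 + self.n_2

    @classmethod
    def from_codes(cls, codes) -> "GenotypeCounts":
        """Tally a sequence of additive codes, ignoring missing values."""
        arr = pd.Series(codes).dropna().astype(int)
        if not arr.isin([0, 1, 2]).all():
            raise DataError("additive genotype codes must be 0, 1 or 2")
        vc = arr.value_counts()
        return cls(int(vc.get(0, 0)), int(vc.get(1, 0)), int(vc.get(2, 0)))


@dataclass(frozen=True)
class HweResult:
    """Outcome of the 1-df chi-square Hardy-Weinberg test."""

    chi2: float
    df: int
    p_value: float
    allele_freq: float
    n: int


def code_additive(genotype, risk_allele: str, other_allele: str | None = None):
    """Additive (dosage) coding: count of the risk allele in a genotype pair.

    Parameters
    ----------
    genotype : str or None
        Unordered allele pair such as ``"A/C"`` (``"|"`` also accepted as
        separator).  Missing tokens (``None``, ``""``, ``"./."``, ``"0/0"``)
        return ``None`` so the record drops out of complete-case fits.
    risk_allele : str
        The counted allele (allele C for the study SNP).
    other_allele : str, optional
        If given, any allele outside ``{risk_allele, other_allele}`` raises
        :class:`~pleiomed.errors.DataError`.

    Returns
    -------
    int or None
        0, 1 or 2 copies of the risk allele; ``None`` when missing.
    """
    if genotype is None or (isinstance(genotype, float) and np.isnan(genotype)):
        return None
    g = str(genotype).strip()
    if g in MISSING_TOKENS:
        return None
    sep = "/" if "/" in g else "|"
    parts = g.split(sep)
    if len(parts) != 2 or not all(parts):
        raise DataError(f"malformed genotype {genotype!r}: expected an allele pair")
    allowed = {risk_allele} | ({other_allele} if other_allele else set(parts))
    for a in parts:
        if a not in allowed:
            raise DataError(
                f"allele {a!r} not in the SNP alphabet {sorted(allowed)}"
            )
    return sum(a == risk_allele for a in parts)


def code_additive_series(
    genotypes: pd.Series, risk_allele: str, other_allele: str | None = None
) -> pd.Series:
    """Vectorised :func:`code_additive` returning a nullable-int Series."""
    coded = genotypes.map(lambda g: code_additive(g, risk_allele, other_allele))
    return pd.Series(coded, index=genotypes.index, dtype="Int64")


def allele_freq(counts: GenotypeCounts) -> float:
    """Risk-allele frequency from genotype counts: (n1 + 2 n2) / 2N."""
    n = counts.total
    if n == 0:
        raise DataError("cannot compute allele frequency from all-zero counts")
    return (counts.n_1 + 2 * counts.n_2) / (2 * n)


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df).

    Expected counts under HWE with risk-allele frequency ``q`` are
    ``(1-q)^2 N, 2q(1-q) N, q^2 N``.  A monomorphic SNP has no test
    (the statistic would be identically zero by construction) and raises
    :class:`~pleiomed.errors.MonomorphicError`.
    """
    n = counts.total
    if n == 0:
        raise DataError("cannot test HWE on empty counts")
    q = allele_freq(counts)
    if q <= 0.0 or q >= 1.0:
        raise MonomorphicError(
            f"HWE test undefined for a monomorphic SNP (allele freq {q:g})"
        )
    p = 1.0 - q
    expected = np.array([p * p * n, 2.0 * p * q * n, q * q * n])
    observed = np.array([counts.n_0, counts.n_1, counts.n_2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, df=1, p_value=p_value, allele_freq=q, n=n)


def call_rate(codes: pd.Series) -> float:
    """Fraction of non-missing genotype calls."""
    s = pd.Series(codes)
    if len(s) == 0:
        raise DataError("empty genotype column")
    return float(s.notna().mean())


def check_call_rate(codes: pd.Series, threshold: float = 0.95) -> bool:
    """QC gate: True when the call rate meets the threshold (default 95%)."""
    return call_rate(codes) >= threshold
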