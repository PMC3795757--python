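"""Association tests on 2x3 case-control genotype count tables.

Implements the statistics a basic GWAS scan uses on a single marker: the
Cochran-Armitage trend test (1 df score test for dose-response in minor
allele dosage), the Pearson genotype chi-square, the allelic chi-square on
the collapsed 2x2 allele table, and the allelic odds ratio with a Wald
confidence interval.  No continuity corrections are applied anywhere; a
zero cell in the odds-ratio table is handled by the Haldane-Anscombe 0.5
correction with an explicit flag.

Degenerate tables (all observations in one dosage column, zero trend
variance, monomorphic markers) report ``statistic = 0, p = 1`` and a
``degenerate`` flag rather than raising: inside Monte-Carlo loops a
degenerate draw is a valid non-rejection, not a crash.

Vectorised kernels (``catt_statistic``, ``allelic_chisq_statistic``,
``genotype_chisq_statistic``, ``allelic_or_vec``) operate on arrays of
tables with shape ``(..., 3)`` and are what the power engine calls in bulk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeCountTable",
    "TestResult",
    "ORResult",
    "catt",
    "chisq_genotype",
    "chisq_allelic",
    "allele_table",
    "allelic_or",
    "catt_statistic",
    "genotype_chisq_statistic",
    "allelic_chisq_statistic",
    "allelic_or_vec",
]


@dataclass(frozen=True)
class GenotypeCountTable:
    """Observed dosage counts for cases (n0,n1,n2) and controls (m0,m1,m2)."""

    case_counts: Tuple[int, int, int]
    control_counts: Tuple[int, int, int]

    def __post_init__(self) -> None:
        n = np.asarray(self.case_counts)
        m = np.asarray(self.control_counts)
        if n.shape != (3,) or m.shape != (3,):
            raise ValueError("counts must be length-3 vectors")
        if np.any(n < 0) or np.any(m < 0):
            raise ValueError("counts must be non-negative")
        if n.sum() < 1 or m.sum() < 1:
            raise ValueError("each group needs at least one observation")

    @property
    def cases(self) -> np.ndarray:
        return np.asarray(self.case_counts, dtype=float)

    @property
    def controls(self) -> np.ndarray:
        return np.asarray(self.control_counts, dtype=float)

    def swapped(self) -> "GenotypeCountTable":
        return GenotypeCountTable(self.control_counts, self.case_counts)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    log_se: float
    ci_low: float
    ci_high: float
    corrected: bool


# ---------------------------------------------------------------------------
# vectorised kernels: inputs (..., 3) case / control count arrays
# ---------------------------------------------------------------------------

def catt_statistic(cases, controls, weights: Sequence[float] = (0.0, 1.0, 2.0)):
    """Cochran-Armitage trend statistic for arrays of 2x3 tables.

    T = N * (N * sum(w n) - R * sum(w t))^2
        / (R * S * (N * sum(w^2 t) - sum(w t)^2))

    with t = n + m the dosage margins, R/S the group totals, N = R + S.
    Zero trend variance yields statistic 0.
    """
    n = np.asarray(cases, dtype=float)
    m = np.asarray(controls, dtype=float)
    w = np.asarray(weights, dtype=float)
    t = n + m
    R = n.sum(axis=-1)
    S = m.sum(axis=-1)
    N = R + S
    swn = (w * n).sum(axis=-1)
    swt = (w * t).sum(axis=-1)
    sw2t = (w**2 * t).sum(axis=-1)
    num = N * swn - R * swt
    var = R * S * (N * sw2t - swt**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, N * num**2 / np.where(var > 0, var, 1.0), 0.0)
    return stat


def allelic_chisq_statistic(cases, controls):
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 allele table."""
    n = np.asarray(cases, dtype=float)
    m = np.asarray(controls, dtype=float)
    a = n[..., 1] + 2.0 * n[..., 2]  # minor alleles, cases
    c = m[..., 1] + 2.0 * m[..., 2]
    b = 2.0 * n.sum(axis=-1) - a
    d = 2.0 * m.sum(axis=-1) - c
    N = a + b + c + d
    det = a * d - b * c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, N * det**2 / np.where(denom > 0, denom, 1.0), 0.0)
    return stat


def genotype_chisq_statistic(cases, controls):
    """Pearson chi-square over the 2x3 table; returns (statistic, df).

    Dosage columns empty in both groups are dropped (df adjusts); a table
    with fewer than two occupied columns is degenerate (statistic 0, df 0).
    """
    n = np.asarray(cases, dtype=float)
    m = np.asarray(controls, dtype=float)
    t = n + m
    R = n.sum(axis=-1, keepdims=True)
    S = m.sum(axis=-1, keepdims=True)
    N = (R + S)[..., 0]
    occupied = t > 0
    k = occupied.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        en = R * t / N[..., None]
        em = S * t / N[..., None]
        contrib = np.where(occupied & (en > 0), (n - en) ** 2 / np.where(en > 0, en, 1.0), 0.0)
        contrib = contrib + np.where(
            occupied & (em > 0), (m - em) ** 2 / np.where(em > 0, em, 1.0), 0.0
        )
    stat = contrib.sum(axis=-1)
    df = np.maximum(k - 1, 0)
    stat = np.where(df > 0, stat, 0.0)
    return stat, df


def allelic_or_vec(cases, controls):
    """Allelic odds ratio for arrays of tables; returns (or, corrected mask).

    Any zero cell in a 2x2 allele table triggers the Haldane-Anscombe 0.5
    correction for that table only.
    """
    n = np.asarray(cases, dtype=float)
    m = np.asarray(controls, dtype=float)
    a = n[..., 1] + 2.0 * n[..., 2]
    c = m[..., 1] + 2.0 * m[..., 2]
    b = 2.0 * n.sum(axis=-1) - a
    d = 2.0 * m.sum(axis=-1) - c
    corrected = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    shift = np.where(corrected, 0.5, 0.0)
    a, b, c, d = a + shift, b + shift, c + shift, d + shift
    return (a * d) / (b * c), corrected


# ---------------------------------------------------------------------------
# scalar API on GenotypeCountTable
# ---------------------------------------------------------------------------

def _result_1df(stat: float) -> TestResult:
    if stat <= 0.0:
        return TestResult(0.0, 1, 1.0, degenerate=True)
    return TestResult(float(stat), 1, float(stats.chi2.sf(stat, 1)))


def catt(
    table: GenotypeCountTable, weights: Sequence[float] = (0.0, 1.0, 2.0)
) -> TestResult:
    """Cochran-Armitage trend test with dosage weights (default 0,1,2)."""
    n, m = table.cases, table.controls
    t = n + m
    w = np.asarray(weights, dtype=float)
    N = t.sum()
    var = n.sum() * m.sum() * (N * (w**2 * t).sum() - ((w * t).sum()) ** 2)
    if var <= 0:
        return TestResult(0.0, 1, 1.0, degenerate=True)
    stat = float(catt_statistic(n, m, weights=w))
    return TestResult(stat, 1, float(stats.chi2.sf(stat, 1)))


def chisq_genotype(table: GenotypeCountTable) -> TestResult:
    """Pearson chi-square on the 2xk genotype table (all-zero columns dropped)."""
    stat, df = genotype_chisq_statistic(table.cases, table.controls)
    stat, df = float(stat), int(df)
    if df == 0:
        return TestResult(0.0, 1, 1.0, degenerate=True)
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)))


def allele_table(table: GenotypeCountTable) -> np.ndarray:
    """Collapse to the 2x2 allele table [[minor, major] cases; controls]."""
    n, m = table.cases, table.controls
    a = n[1] + 2 * n[2]
    c = m[1] + 2 * m[2]
    return np.array(
        [[a, 2 * n.sum() - a], [c, 2 * m.sum() - c]], dtype=float
    )


def chisq_allelic(table: GenotypeCountTable) -> TestResult:
    """1-df Pearson chi-square on the allele table (the basic GWAS scan test)."""
    tab = allele_table(table)
    if np.any(tab.sum(axis=0) == 0):  # monomorphic marker
        return TestResult(0.0, 1, 1.0, degenerate=True)
    return _result_1df(float(allelic_chisq_statistic(table.cases, table.controls)))


def allelic_or(table: GenotypeCountTable) -> ORResult:
    """Allelic odds ratio with 95% Wald CI on the log scale."""
    tab = allele_table(table)
    corrected = bool(np.any(tab == 0))
    if corrected:
        tab = tab + 0.5
    (a, b), (c, d) = tab
    or_ = (a * d) / (b * c)
    log_se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = stats.norm.ppf(0.975)
    return ORResult(
        odds_ratio=float(or_),
        log_se=log_se,
        ci_low=float(np.exp(np.log(or_) - z * log_se)),
        ci_high=float(np.exp(np.log(or_) + z * log_se)),
        corrected=corrected,
    )
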