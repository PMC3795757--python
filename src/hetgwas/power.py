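"""Monte-Carlo power, analytic non-central chi-square power, and minimum
sample size under case-group contamination.

Two complementary routes to the same quantity:

* ``mc_power`` draws replicate case-control genotype count tables
  (count-level multinomial sampling, identical in law to per-individual
  assignment) and reports the fraction rejecting at the chosen alpha.
* ``analytic_power`` evaluates the chosen 1-df test statistic on expected
  counts; because the statistic is a score statistic, its value on expected
  counts is the non-centrality parameter, and power is the upper tail of
  the non-central chi-square(1) at the central critical value.

``min_sample_size`` reproduces the binary-search design: the smallest equal
per-group n whose Monte-Carlo power reaches the target (default 90%) at
genome-wide alpha (default 5e-8), capped at 1,000,000 total.  The search is
pre-bracketed by inverting the analytic power (non-centrality is linear in
n), then refined with Monte-Carlo evaluations on a deterministic
per-candidate seed schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .association import (
    GenotypeCountTable,
    allelic_chisq_statistic,
    allelic_or_vec,
    catt_statistic,
    genotype_chisq_statistic,
)
from .models import (
    GenotypeDist,
    ModelSpec,
    PenetranceOverflowError,
    admixed_case_dist,
    case_dist,
    control_dist,
    expected_allelic_or,
)

__all__ = [
    "SimConfig",
    "PowerEstimate",
    "SampleSizeResult",
    "simulate_table",
    "mc_power",
    "analytic_power",
    "analytic_min_n",
    "min_sample_size",
    "or_curve",
    "run_grid",
]

GENOME_WIDE_ALPHA = 5e-8
SAMPLE_SIZE_CAP = 1_000_000  # total (cases + controls)


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo configuration shared by the power and sample-size runs."""

    alpha: float = GENOME_WIDE_ALPHA
    target_power: float = 0.9
    reps: int = 1000
    seed: int = 0
    test: str = "catt"
    n_cap: int = SAMPLE_SIZE_CAP

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError(f"target_power must be in (0,1), got {self.target_power}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.test not in ("catt", "chisq_genotype", "chisq_allelic"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.n_cap < 2:
            raise ValueError("n_cap must be >= 2")


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    reps: int

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.power * (1.0 - self.power) / self.reps)


@dataclass(frozen=True)
class SampleSizeResult:
    n_total: int
    n_per_group: int
    achieved_power: float
    converged: bool
    capped: bool


def simulate_table(
    case: GenotypeDist,
    control: GenotypeDist,
    n_case: int,
    n_control: int,
    rng: np.random.Generator,
) -> GenotypeCountTable:
    """One multinomial case-control genotype count table."""
    n = rng.multinomial(n_case, case.as_array())
    m = rng.multinomial(n_control, control.as_array())
    return GenotypeCountTable(tuple(int(x) for x in n), tuple(int(x) for x in m))


def _simulate_counts(
    case: GenotypeDist,
    control: GenotypeDist,
    n_case: int,
    n_control: int,
    reps: int,
    rng: np.random.Generator,
):
    n = rng.multinomial(n_case, case.as_array(), size=reps)
    m = rng.multinomial(n_control, control.as_array(), size=reps)
    return n, m


def _pvalues(test: str, n, m) -> np.ndarray:
    if test == "catt":
        return stats.chi2.sf(catt_statistic(n, m), 1)
    if test == "chisq_allelic":
        return stats.chi2.sf(allelic_chisq_statistic(n, m), 1)
    if test == "chisq_genotype":
        stat, df = genotype_chisq_statistic(n, m)
        p = np.ones_like(stat, dtype=float)
        ok = df > 0
        p[ok] = stats.chi2.sf(stat[ok], df[ok])
        return p
    raise ValueError(f"unknown test {test!r}")


def _dists(spec: ModelSpec, beta: float):
    cd = case_dist(spec)
    td = control_dist(spec)
    return admixed_case_dist(cd, td, beta), td


def mc_power(
    spec: ModelSpec,
    beta: float,
    n_case: int,
    n_control: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> PowerEstimate:
    """Monte-Carlo rejection rate at ``cfg.alpha`` with contaminated cases."""
    admixed, td = _dists(spec, beta)
    if rng is None:
        rng = substream(cfg.seed, "power", n_case, n_control)
    n, m = _simulate_counts(admixed, td, n_case, n_control, cfg.reps, rng)
    p = _pvalues(cfg.test, n, m)
    return PowerEstimate(power=float(np.mean(p < cfg.alpha)), reps=cfg.reps)


def _ncp_per_pair(spec: ModelSpec, beta: float, test: str) -> float:
    """Non-centrality of the 1-df test per (case, control) pair."""
    admixed, td = _dists(spec, beta)
    n = admixed.as_array()
    m = td.as_array()
    if test == "catt":
        return float(catt_statistic(n, m))
    if test == "chisq_allelic":
        return float(allelic_chisq_statistic(n, m))
    raise ValueError(f"analytic power unsupported for test {test!r}")


def analytic_power(
    spec: ModelSpec,
    beta: float,
    n_case: int,
    n_control: int,
    alpha: float = GENOME_WIDE_ALPHA,
    test: str = "catt",
) -> float:
    """Deterministic non-central chi-square(1) power for the 1-df tests.

    The non-centrality is the test-statistic formula evaluated on expected
    counts ``n_i = n_case * admixed_i``, ``m_i = n_control * control_i``;
    for equal statistic weights it scales linearly in the per-group n.
    """
    admixed, td = _dists(spec, beta)
    n = n_case * admixed.as_array()
    m = n_control * td.as_array()
    if test == "catt":
        ncp = float(catt_statistic(n, m))
    elif test == "chisq_allelic":
        ncp = float(allelic_chisq_statistic(n, m))
    else:
        raise ValueError(f"analytic power unsupported for test {test!r}")
    crit = stats.chi2.isf(alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(alpha)


def _required_ncp(alpha: float, target_power: float) -> float:
    """Non-centrality at which ncx2(1) power equals the target."""
    crit = stats.chi2.isf(alpha, 1)
    from scipy.optimize import brentq

    f = lambda ncp: stats.ncx2.sf(crit, 1, ncp) - target_power
    return float(brentq(f, 1e-9, 1e6))


def analytic_min_n(
    spec: ModelSpec,
    beta: float,
    alpha: float = GENOME_WIDE_ALPHA,
    target_power: float = 0.9,
    test: str = "catt",
) -> float:
    """Closed-form per-group sample size from inverting the analytic power."""
    ncp1 = _ncp_per_pair(spec, beta, test)
    if ncp1 <= 0:
        return math.inf
    return _required_ncp(alpha, target_power) / ncp1


def min_sample_size(
    spec: ModelSpec, beta: float, cfg: SimConfig
) -> SampleSizeResult:
    """Smallest equal per-group n whose Monte-Carlo power reaches the target.

    Analytic pre-bracketing (non-centrality inversion) seeds the bracket;
    the bracket is validated and refined by Monte-Carlo binary search with
    a per-candidate seed derived from ``(cfg.seed, n)``, terminating at
    bracket width <= max(1, 1% of n).  If the cap is reached before the
    target power, ``capped`` is set.
    """
    test = cfg.test if cfg.test != "chisq_genotype" else "catt"
    cap_per_group = cfg.n_cap // 2

    def power_at(n: int) -> float:
        rng = substream(cfg.seed, "samplesize", n)
        return mc_power(spec, beta, n, n, cfg, rng=rng).power

    n_star = analytic_min_n(spec, beta, cfg.alpha, cfg.target_power, test)
    if not math.isfinite(n_star) or n_star > cap_per_group:
        p_cap = power_at(cap_per_group)
        if p_cap < cfg.target_power:
            return SampleSizeResult(
                2 * cap_per_group, cap_per_group, p_cap, converged=False, capped=True
            )
        n_star = float(cap_per_group) / 2  # analytic was pessimistic; search below cap

    lo = max(1, int(0.5 * n_star))
    hi = min(cap_per_group, max(lo + 1, int(math.ceil(2.0 * n_star))))

    # grow hi until power clears the target (or the cap binds)
    p_hi = power_at(hi)
    while p_hi < cfg.target_power:
        if hi >= cap_per_group:
            return SampleSizeResult(2 * hi, hi, p_hi, converged=False, capped=True)
        lo = hi
        hi = min(cap_per_group, hi * 2)
        p_hi = power_at(hi)

    # shrink lo until power is below target (keeps the invariant lo < answer <= hi)
    while lo > 1 and power_at(lo) >= cfg.target_power:
        hi, p_hi = lo, power_at(lo)
        lo = max(1, lo // 2)

    while hi - lo > max(1, int(0.01 * hi)):
        mid = (lo + hi) // 2
        if power_at(mid) >= cfg.target_power:
            hi, p_hi = mid, power_at(mid)
        else:
            lo = mid

    return SampleSizeResult(2 * hi, hi, p_hi, converged=True, capped=False)


def or_curve(
    spec: ModelSpec,
    betas: Sequence[float],
    n_case: int,
    n_control: int,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Mean simulated allelic OR and its closed-form expectation per beta.

    Columns: beta, expected_or, mean_or, se_or, n_reps.
    """
    cd = case_dist(spec)
    td = control_dist(spec)
    rows = []
    for i, beta in enumerate(betas):
        admixed = admixed_case_dist(cd, td, beta)
        rng = substream(cfg.seed, "orcurve", i)
        n, m = _simulate_counts(admixed, td, n_case, n_control, cfg.reps, rng)
        ors, _ = allelic_or_vec(n, m)
        rows.append(
            {
                "beta": beta,
                "expected_or": expected_allelic_or(admixed, td),
                "mean_or": float(np.mean(ors)),
                "se_or": float(np.std(ors, ddof=1) / math.sqrt(cfg.reps)),
                "n_reps": cfg.reps,
            }
        )
    return pd.DataFrame(rows)


def run_grid(
    models: Iterable[str],
    prevalences: Iterable[float],
    mafs: Iterable[float],
    rrs: Iterable[float],
    betas: Iterable[float],
    cfg: SimConfig,
    n_case: int | None = None,
    n_control: int | None = None,
    compute_min_n: bool = False,
) -> pd.DataFrame:
    """Long-format sweep over the full parameter grid.

    One row per (model, prevalence, maf, rr, beta).  Infeasible
    combinations (penetrance overflow) are flagged, never dropped.  With
    ``n_case``/``n_control`` given, Monte-Carlo power at that fixed n is
    reported; with ``compute_min_n``, the binary-search minimum sample size.
    """
    rows = []
    for model, K, q, rr, beta in product(models, prevalences, mafs, rrs, betas):
        row = {
            "model": model,
            "prevalence": K,
            "maf": q,
            "rr": rr,
            "beta": beta,
            "feasible": True,
            "power": np.nan,
            "mc_se": np.nan,
            "n_total": np.nan,
            "converged": np.nan,
            "capped": np.nan,
        }
        try:
            spec = ModelSpec(model, K, q, rr)
            case_dist(spec)  # feasibility probe
        except (PenetranceOverflowError, ValueError):
            row["feasible"] = False
            rows.append(row)
            continue
        if n_case is not None and n_control is not None:
            est = mc_power(spec, beta, n_case, n_control, cfg)
            row["power"] = est.power
            row["mc_se"] = est.mc_se
        if compute_min_n:
            res = min_sample_size(spec, beta, cfg)
            row["n_total"] = res.n_total
            row["converged"] = res.converged
            row["capped"] = res.capped
        rows.append(row)
    return pd.DataFrame(rows)
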