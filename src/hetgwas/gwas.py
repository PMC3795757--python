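"""Synthetic two-disease cohort generation and the case-swap (mix-scan)
resampling experiment.

Emulates the design of a two-disease case-control study sharing one control
pool: cohort A (default 1,963 cases), cohort B (default 1,924 cases) and
2,938 shared controls, genotyped on a panel of independent SNPs.  Each SNP
carries a disease-specific relative risk for A and for B (both 1 for null
markers; both > 1 for a shared-effect marker, the analog of a locus like
*HLA-DRB1* that is associated with both phenotypes).

The mix-scan replaces a proportion ``beta`` of one disease's cases with
cases of the other disease (sampling without replacement, fresh per
resample), re-runs the single-marker association scan against the shared
controls, and averages -log10(p) per SNP over resamples at each beta —
quantifying how diagnostic contamination erodes association signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .association import (
    allelic_chisq_statistic,
    catt_statistic,
    genotype_chisq_statistic,
)
from .models import (
    GenotypeDist,
    ModelSpec,
    PenetranceOverflowError,
    case_dist,
    hwe_dist,
    penetrances,
)

__all__ = [
    "SNPSpec",
    "CohortSpec",
    "GenotypeMatrix",
    "default_snp_panel",
    "shared_control_dist",
    "generate_cohorts",
    "mix_cases",
    "scan",
    "mixscan",
    "write_ped_map",
]

DEFAULT_BETAS = tuple(round(0.1 * i, 1) for i in range(10))  # 0.0 .. 0.9


@dataclass(frozen=True)
class SNPSpec:
    """One marker: MAF plus a relative risk under each disease.

    ``rr_a = rr_b = 1`` is a null SNP; ``rr_a > 1 = rr_b`` an A-specific
    SNP; both > 1 a shared-effect SNP.
    """

    id: str
    maf: float
    rr_a: float = 1.0
    rr_b: float = 1.0
    model: str = "multiplicative"

    def spec_for(self, disease: str, prevalence: float) -> ModelSpec:
        rr = self.rr_a if disease == "A" else self.rr_b
        return ModelSpec(self.model, prevalence, self.maf, rr)


@dataclass(frozen=True)
class CohortSpec:
    """Design of the synthetic two-disease study."""

    n_case_a: int = 1963
    n_case_b: int = 1924
    n_controls: int = 2938
    prevalence_a: float = 0.005
    prevalence_b: float = 0.05
    snps: Sequence[SNPSpec] = field(default_factory=lambda: default_snp_panel())
    seed: int = 0


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix for one group."""

    dosages: np.ndarray  # (n, n_snps) int8 in {0,1,2}
    group: str  # "case_A" | "case_B" | "control"
    snp_ids: tuple

    def __post_init__(self) -> None:
        d = self.dosages
        if d.ndim != 2 or d.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match SNP ids")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    def dosage_counts(self) -> np.ndarray:
        """Per-SNP counts of dosages 0/1/2, shape (n_snps, 3)."""
        d = self.dosages
        c1 = (d == 1).sum(axis=0)
        c2 = (d == 2).sum(axis=0)
        c0 = d.shape[0] - c1 - c2
        return np.stack([c0, c1, c2], axis=1).astype(float)


def default_snp_panel(
    n_specific: int = 20,
    rr_range: tuple = (1.3, 2.0),
    shared_rr: float = 3.0,
    n_null: int = 459,
    panel_seed: int = 2013,
) -> List[SNPSpec]:
    """The shipped marker panel: 20 A-specific and 20 B-specific SNPs with
    relative risks spaced over 1.3-2.0, one shared-effect SNP (rr 3 under
    both diseases), and 459 null SNPs — 500 markers total.  MAFs are drawn
    from {0.05, 0.10, ..., 0.50} with a fixed panel seed so the default
    experiment is a constant.
    """
    rng = substream(panel_seed, "panel")
    maf_choices = np.round(np.arange(0.05, 0.501, 0.05), 2)
    rrs = np.round(np.linspace(rr_range[0], rr_range[1], n_specific), 3)
    snps: List[SNPSpec] = []
    for i in range(n_specific):
        snps.append(
            SNPSpec(f"snpA{i + 1:03d}", float(rng.choice(maf_choices)), rr_a=float(rrs[i]))
        )
    for i in range(n_specific):
        snps.append(
            SNPSpec(f"snpB{i + 1:03d}", float(rng.choice(maf_choices)), rr_b=float(rrs[i]))
        )
    snps.append(SNPSpec("snpShared001", 0.25, rr_a=shared_rr, rr_b=shared_rr))
    for i in range(n_null):
        snps.append(SNPSpec(f"snpNull{i + 1:03d}", float(rng.choice(maf_choices))))
    return snps


def shared_control_dist(snp: SNPSpec, spec: CohortSpec) -> GenotypeDist:
    """Genotype distribution of controls unaffected by either disease.

    ``p_i ∝ g_i (1 - f_i^A)(1 - f_i^B)``; collapses to the single-disease
    unaffected distribution when the other relative risk is 1, and to the
    population HWE distribution for null SNPs.
    """
    g = hwe_dist(snp.maf).as_array()
    fa = penetrances(snp.spec_for("A", spec.prevalence_a)).as_array()
    fb = penetrances(snp.spec_for("B", spec.prevalence_b)).as_array()
    p = g * (1.0 - fa) * (1.0 - fb)
    return GenotypeDist.from_array(p / p.sum())


def _case_dists(spec: CohortSpec, disease: str) -> np.ndarray:
    prevalence = spec.prevalence_a if disease == "A" else spec.prevalence_b
    dists = []
    for snp in spec.snps:
        try:
            dists.append(case_dist(snp.spec_for(disease, prevalence)).as_array())
        except PenetranceOverflowError as err:
            raise PenetranceOverflowError(
                f"SNP {snp.id}: {err} (disease {disease})"
            ) from err
    return np.asarray(dists)


def _draw_matrix(
    dists: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an (n, n_snps) dosage matrix; SNPs independent, one dist each."""
    u = rng.random((n, dists.shape[0]))
    thr1 = dists[:, 0]
    thr2 = dists[:, 0] + dists[:, 1]
    return ((u >= thr1).astype(np.int8) + (u >= thr2).astype(np.int8))


def generate_cohorts(spec: CohortSpec):
    """Draw the three cohorts; returns (case_A, case_B, controls)."""
    da = _case_dists(spec, "A")
    db = _case_dists(spec, "B")
    dc = np.asarray([shared_control_dist(s, spec).as_array() for s in spec.snps])
    ids = tuple(s.id for s in spec.snps)
    case_a = GenotypeMatrix(
        _draw_matrix(da, spec.n_case_a, substream(spec.seed, "cohort", "A")),
        "case_A",
        ids,
    )
    case_b = GenotypeMatrix(
        _draw_matrix(db, spec.n_case_b, substream(spec.seed, "cohort", "B")),
        "case_B",
        ids,
    )
    controls = GenotypeMatrix(
        _draw_matrix(dc, spec.n_controls, substream(spec.seed, "cohort", "C")),
        "control",
        ids,
    )
    return case_a, case_b, controls


def mix_cases(
    cases_primary: GenotypeMatrix,
    cases_other: GenotypeMatrix,
    beta: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Replace round(N*beta) randomly chosen primary cases with donors.

    Sampling is without replacement on both sides; the output always has
    exactly N = rows(cases_primary) rows.  Rounding is half away from zero.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0,1], got {beta}")
    n = cases_primary.n
    k = int(np.floor(n * beta + 0.5))
    if k > cases_other.n:
        raise ValueError(
            f"donor pool has {cases_other.n} rows, need {k} for beta={beta}"
        )
    if k == 0:
        return cases_primary
    keep = rng.choice(n, size=n - k, replace=False)
    donors = rng.choice(cases_other.n, size=k, replace=False)
    dosages = np.concatenate(
        [cases_primary.dosages[keep], cases_other.dosages[donors]], axis=0
    )
    return GenotypeMatrix(dosages, cases_primary.group, cases_primary.snp_ids)


def _scan_pvalues(
    case_counts: np.ndarray, control_counts: np.ndarray, test: str
) -> np.ndarray:
    if test == "chisq_allelic":
        return stats.chi2.sf(allelic_chisq_statistic(case_counts, control_counts), 1)
    if test == "catt":
        return stats.chi2.sf(catt_statistic(case_counts, control_counts), 1)
    if test == "chisq_genotype":
        stat, df = genotype_chisq_statistic(case_counts, control_counts)
        p = np.ones_like(stat)
        ok = df > 0
        p[ok] = stats.chi2.sf(stat[ok], df[ok])
        return p
    raise ValueError(f"unknown test {test!r}")


def scan(
    cases: GenotypeMatrix, controls: GenotypeMatrix, test: str = "chisq_allelic"
) -> pd.DataFrame:
    """Single-marker association scan; one row per SNP.

    Columns: snp, statistic, p_value, degenerate.  Monomorphic markers are
    degenerate (statistic 0, p 1).
    """
    if cases.snp_ids != controls.snp_ids:
        raise ValueError("case and control SNP panels differ")
    n = cases.dosage_counts()
    m = controls.dosage_counts()
    p = _scan_pvalues(n, m, test)
    if test == "chisq_allelic":
        stat = allelic_chisq_statistic(n, m)
    elif test == "catt":
        stat = catt_statistic(n, m)
    else:
        stat, _ = genotype_chisq_statistic(n, m)
    minor = n[:, 1] + 2 * n[:, 2] + m[:, 1] + 2 * m[:, 2]
    total = 2 * (n.sum(axis=1) + m.sum(axis=1))
    degenerate = (minor == 0) | (minor == total) | (stat <= 0)
    return pd.DataFrame(
        {
            "snp": list(cases.snp_ids),
            "statistic": stat,
            "p_value": p,
            "degenerate": degenerate,
        }
    )


def mixscan(
    spec: CohortSpec,
    betas: Sequence[float] = DEFAULT_BETAS,
    n_resamples: int = 100,
    test: str = "chisq_allelic",
    primary: str = "A",
    keep_pvalues: bool = False,
):
    """The case-swap experiment: mean -log10(p) per SNP at each beta.

    For each beta and resample, ``round(N*beta)`` primary cases are swapped
    for other-disease cases and the scan is re-run against the shared
    controls.  Returns a DataFrame (snp, beta, mean_neglog10p, n_resamples)
    and, with ``keep_pvalues``, the raw (beta, resample, snp) p-value array.
    """
    case_a, case_b, controls = generate_cohorts(spec)
    cases_primary, cases_other = (
        (case_a, case_b) if primary == "A" else (case_b, case_a)
    )
    control_counts = controls.dosage_counts()
    n_snps = len(spec.snps)
    pvals = np.empty((len(betas), n_resamples, n_snps))
    for bi, beta in enumerate(betas):
        rng = substream(spec.seed, "mixscan", primary, bi)
        for r in range(n_resamples):
            mixed = mix_cases(cases_primary, cases_other, beta, rng)
            pvals[bi, r] = _scan_pvalues(
                mixed.dosage_counts(), control_counts, test
            )
    neglog = -np.log10(np.clip(pvals, 1e-300, None))
    rows = []
    for bi, beta in enumerate(betas):
        for si, snp in enumerate(spec.snps):
            rows.append(
                {
                    "snp": snp.id,
                    "beta": beta,
                    "mean_neglog10p": float(neglog[bi, :, si].mean()),
                    "n_resamples": n_resamples,
                }
            )
    result = pd.DataFrame(rows)
    if keep_pvalues:
        return result, pvals
    return result


def write_ped_map(
    matrices: Sequence[GenotypeMatrix], spec: CohortSpec, prefix: str
) -> None:
    """Write cohorts as PLINK text PED/MAP (minor allele 'A', major 'G').

    Phenotype column: 2 for case rows, 1 for controls.  The MAP file places
    every SNP on chromosome 1 at consecutive positions.
    """
    alleles = {0: "G G", 1: "A G", 2: "A A"}
    with open(f"{prefix}.ped", "w") as ped:
        iid = 0
        for mat in matrices:
            pheno = 1 if mat.group == "control" else 2
            for row in mat.dosages:
                iid += 1
                geno = " ".join(alleles[int(d)] for d in row)
                ped.write(f"F{iid} I{iid} 0 0 0 {pheno} {geno}\n")
    with open(f"{prefix}.map", "w") as mp:
        for i, snp in enumerate(spec.snps, start=1):
            mp.write(f"1\t{snp.id}\t0\t{i}\n")
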