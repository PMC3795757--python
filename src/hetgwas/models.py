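"""Single-locus disease models and genotype distributions.

A disease model is parameterised by its mode of inheritance (dominant or
multiplicative), the population prevalence ``K``, the minor allele frequency
``q`` and the relative risk ``gamma`` carried by the minor allele.  Genotype
frequencies in the population follow Hardy-Weinberg equilibrium,
``g = ((1-q)^2, 2q(1-q), q^2)`` by minor-allele dosage.  The baseline
penetrance ``f0`` is solved so that the genotype-averaged penetrance equals
the prevalence, ``sum_i f_i * g_i = K``; Bayes' rule then yields the genotype
distributions of affected (cases) and unaffected (controls) individuals.

Phenotypic heterogeneity is modelled as admixture: a proportion ``beta`` of
the case group is drawn from the non-case distribution, diluting the
case/control genotype contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PenetranceOverflowError",
    "ModelSpec",
    "PenetranceVector",
    "GenotypeDist",
    "hwe_dist",
    "penetrances",
    "case_dist",
    "control_dist",
    "admixed_case_dist",
    "allele_freq",
    "expected_allelic_or",
]

_NORM_TOL = 1e-12


class PenetranceOverflowError(ValueError):
    """Raised when a model implies a genotype penetrance above 1."""


@dataclass(frozen=True)
class ModelSpec:
    """A single-locus disease model.

    Parameters
    ----------
    model :
        ``"dominant"`` (carriers of >=1 minor allele have relative risk
        ``rr``) or ``"multiplicative"`` (genotype relative risks
        ``1, rr, rr**2`` by dosage; log-additive).
    prevalence :
        Population disease prevalence ``K``, in (0, 1).
    maf :
        Minor allele frequency ``q``, in (0, 0.5].
    rr :
        Relative risk of disease for the minor allele, > 0.  The minor
        allele is treated as the risk allele; ``rr < 1`` is permitted and
        handled symmetrically.
    """

    model: str
    prevalence: float
    maf: float
    rr: float

    def __post_init__(self) -> None:
        if self.model not in ("dominant", "multiplicative"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0,0.5], got {self.maf}")
        if not self.rr > 0.0:
            raise ValueError(f"rr must be positive, got {self.rr}")

    @property
    def genotype_relative_risks(self) -> np.ndarray:
        if self.model == "dominant":
            return np.array([1.0, self.rr, self.rr])
        return np.array([1.0, self.rr, self.rr**2])


@dataclass(frozen=True)
class PenetranceVector:
    """Probability of disease given minor-allele dosage 0, 1, 2."""

    f0: float
    f1: float
    f2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.f1, self.f2])


@dataclass(frozen=True)
class GenotypeDist:
    """Distribution over minor-allele dosage {0, 1, 2} in one group."""

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        p = self.as_array()
        if np.any(p < -_NORM_TOL):
            raise ValueError(f"negative genotype probability: {p}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"genotype probabilities sum to {p.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2])

    @classmethod
    def from_array(cls, p) -> "GenotypeDist":
        p = np.asarray(p, dtype=float)
        return cls(float(p[0]), float(p[1]), float(p[2]))


def hwe_dist(maf: float) -> GenotypeDist:
    """Hardy-Weinberg genotype distribution at minor allele frequency ``maf``."""
    q = float(maf)
    return GenotypeDist((1 - q) ** 2, 2 * q * (1 - q), q**2)


def penetrances(spec: ModelSpec) -> PenetranceVector:
    """Solve the baseline penetrance so the model reproduces the prevalence.

    With HWE genotype frequencies ``g`` and genotype relative risks ``w``
    (``(1, rr, rr)`` dominant, ``(1, rr, rr^2)`` multiplicative), the
    penetrances are ``f_i = f0 * w_i`` with ``f0 = K / sum(w * g)``.

    Raises
    ------
    PenetranceOverflowError
        If any implied penetrance exceeds 1 (the model cannot attain the
        requested prevalence); such specs are rejected, never truncated.
    """
    g = hwe_dist(spec.maf).as_array()
    w = spec.genotype_relative_risks
    f0 = spec.prevalence / float(np.dot(w, g))
    f = f0 * w
    if np.any(f > 1.0):
        raise PenetranceOverflowError(
            f"penetrance overflow: model {spec} implies penetrances {f}"
        )
    return PenetranceVector(float(f[0]), float(f[1]), float(f[2]))


def case_dist(spec: ModelSpec) -> GenotypeDist:
    """Genotype distribution among affected individuals, ``f_i g_i / K``."""
    g = hwe_dist(spec.maf).as_array()
    f = penetrances(spec).as_array()
    p = f * g / spec.prevalence
    return GenotypeDist.from_array(p / p.sum())


def control_dist(spec: ModelSpec) -> GenotypeDist:
    """Genotype distribution among unaffected individuals, ``(1-f_i) g_i / (1-K)``."""
    g = hwe_dist(spec.maf).as_array()
    f = penetrances(spec).as_array()
    p = (1.0 - f) * g / (1.0 - spec.prevalence)
    return GenotypeDist.from_array(p / p.sum())


def admixed_case_dist(
    case: GenotypeDist, control: GenotypeDist, beta: float
) -> GenotypeDist:
    """Case distribution contaminated with a proportion ``beta`` of non-cases.

    ``p_i = (1-beta) * case_i + beta * control_i``.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0,1], got {beta}")
    p = (1.0 - beta) * case.as_array() + beta * control.as_array()
    return GenotypeDist.from_array(p)


def allele_freq(dist: GenotypeDist) -> float:
    """Minor allele frequency implied by a genotype distribution."""
    return (dist.p1 + 2.0 * dist.p2) / 2.0


def expected_allelic_or(case: GenotypeDist, control: GenotypeDist) -> float:
    """Population-level allelic odds ratio between two genotype distributions.

    ``odds(p_case) / odds(p_control)`` where ``p`` is the group allele
    frequency.  Raises on monomorphic input.
    """
    pc = allele_freq(case)
    pt = allele_freq(control)
    if not (0.0 < pc < 1.0 and 0.0 < pt < 1.0):
        raise ValueError("allelic odds ratio undefined for monomorphic groups")
    return (pc / (1.0 - pc)) / (pt / (1.0 - pt))
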