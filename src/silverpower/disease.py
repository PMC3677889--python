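"""Genotypic disease risk model.

A bi-allelic locus in a diploid organism with genotypes ordered (aa, Aa, AA)
throughout the package: aa carries no copy of the risk allele, AA two copies.
Genotype frequencies follow Hardy-Weinberg equilibrium at risk-allele
frequency ``m``.  Disease risk is parameterised by the population prevalence
``k`` and the homozygous relative risk ``rr_AA``; the heterozygous relative
risk is fixed by the inheritance mode:

=============== ==========
mode            rr_Aa
=============== ==========
dominant        rr_AA
recessive       1
multiplicative  sqrt(rr_AA)
=============== ==========

Penetrances follow from the law of total probability,

    P(Aff | aa) = k / (f_aa + f_Aa * rr_Aa + f_AA * rr_AA),

with P(Aff|Aa) and P(Aff|AA) by relative-risk scaling.  The model is
over-specified: some parameter combinations force a penetrance above 1 and
are flagged "unphysical" (strictly greater than 1; exactly 1 is physical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GENOTYPES = ("aa", "Aa", "AA")
MODES = ("dominant", "recessive", "multiplicative")


class UnphysicalModelError(ValueError):
    """Raised when an operation requires penetrances but one exceeds 1."""


@dataclass(frozen=True)
class DiseaseModel:
    """Risk-allele frequency, prevalence, homozygous relative risk, mode."""

    m: float
    k: float
    rr_AA: float
    mode: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"risk allele frequency m={self.m} outside [0, 1]")
        if not 0.0 < self.k < 1.0:
            raise ValueError(f"prevalence k={self.k} outside (0, 1)")
        if self.rr_AA < 1.0:
            raise ValueError(
                f"rr_AA={self.rr_AA} < 1: recode the risk allele instead of "
                "using a protective relative risk"
            )
        if self.mode not in MODES:
            raise ValueError(f"mode={self.mode!r} not one of {MODES}")

    @property
    def rr_Aa(self) -> float:
        """Heterozygous relative risk implied by the inheritance mode."""
        if self.mode == "dominant":
            return self.rr_AA
        if self.mode == "recessive":
            return 1.0
        return float(np.sqrt(self.rr_AA))

    @property
    def is_null(self) -> bool:
        """True when rr_AA = 1 (no genotype-phenotype association)."""
        return self.rr_AA == 1.0


@dataclass(frozen=True)
class GenotypeDistribution:
    """Marginal HWE genotype probabilities, ordered (aa, Aa, AA)."""

    f_aa: float
    f_Aa: float
    f_AA: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_aa, self.f_Aa, self.f_AA])


@dataclass(frozen=True)
class PenetranceVector:
    """P(Aff | genotype), ordered (aa, Aa, AA), plus the unphysical flag.

    Values are returned un-clipped even when a penetrance exceeds 1, so a
    caller can report *which* parameter combination is infeasible.
    """

    p_aff_aa: float
    p_aff_Aa: float
    p_aff_AA: float
    unphysical: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.p_aff_aa, self.p_aff_Aa, self.p_aff_AA])


@dataclass(eq=False)
class ConditionalGenotypeFreqs:
    """Rows of the matrix P: P(genotype | affected) and P(genotype | unaffected)."""

    p_case: np.ndarray
    p_control: np.ndarray

    def __post_init__(self) -> None:
        self.p_case = np.asarray(self.p_case, dtype=float)
        self.p_control = np.asarray(self.p_control, dtype=float)
        for name, row in (("p_case", self.p_case), ("p_control", self.p_control)):
            if row.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector, got {row.shape}")
            if not np.isclose(row.sum(), 1.0, atol=1e-8):
                raise ValueError(f"{name} does not sum to 1: {row}")


def genotype_frequencies(m: float) -> GenotypeDistribution:
    """HWE genotype frequencies ((1-m)^2, 2m(1-m), m^2) at allele frequency m."""
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"allele frequency m={m} outside [0, 1]")
    return GenotypeDistribution((1.0 - m) ** 2, 2.0 * m * (1.0 - m), m**2)


def penetrance(model: DiseaseModel) -> PenetranceVector:
    """Genotype-specific penetrances via the law of total probability."""
    f = genotype_frequencies(model.m).as_array()
    rr = np.array([1.0, model.rr_Aa, model.rr_AA])
    p_aa = model.k / float(f @ rr)
    p = p_aa * rr
    return PenetranceVector(p[0], p[1], p[2], unphysical=bool(p[1] > 1.0 or p[2] > 1.0))


def conditional_genotype_freqs(model: DiseaseModel) -> ConditionalGenotypeFreqs:
    """Bayes inversion of penetrances: the matrix P of the misclassification model.

    p_case_g = P(Aff|g) f_g / k and p_control_g = (1 - P(Aff|g)) f_g / (1 - k).

    Raises
    ------
    UnphysicalModelError
        If any penetrance exceeds 1, naming the offending genotype.
    """
    pen = penetrance(model)
    if pen.unphysical:
        bad = [
            g
            for g, v in zip(GENOTYPES, pen.as_array())
            if v > 1.0
        ]
        raise UnphysicalModelError(
            f"unphysical model {model}: P(Aff|{'), P(Aff|'.join(bad)}) > 1"
        )
    f = genotype_frequencies(model.m).as_array()
    p = pen.as_array()
    return ConditionalGenotypeFreqs(
        p_case=p * f / model.k,
        p_control=(1.0 - p) * f / (1.0 - model.k),
    )


def is_physical(m: float, k: float, rr_AA: float, mode: str) -> bool:
    """True when no penetrance exceeds 1 for these risk parameters."""
    return not penetrance(DiseaseModel(m=m, k=k, rr_AA=rr_AA, mode=mode)).unphysical


def count_unphysical(grid) -> int:
    """Number of grid scenarios whose risk parameters force a penetrance > 1.

    Accepts a :class:`~silverpower.grids.ScenarioGrid`.
    """
    return int((~grid.physical_mask()).sum())
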