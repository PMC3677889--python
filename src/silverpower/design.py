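"""Study-design bookkeeping for a blended gold/silver case-control study.

The design is anchored on the number of gold-standard controls ``n_co`` with
three ratios: ``r`` gold controls per gold case, ``gamma_ca`` silver cases per
gold case and ``gamma_co`` silver controls per gold control.  Gold-standard
labels are treated as error-free; silver-standard labels carry a 2x2 confusion
matrix

    T = [[phi, 1 - phi], [1 - theta, theta]]

whose rows are the observed label X in {case, control} and columns the latent
affection status Z in {affected, unaffected}: phi is the positive predictive
value of a silver case label, theta the negative predictive value of a silver
control label.  A modelling assumption (not a runtime check) is that X and
genotype are conditionally independent given Z — genotype influences the
observed label only through true affection status.

Genotype frequencies in the silver-standard population are Q = T' P
(rows of P from :mod:`silverpower.disease`), and the case/control genotype
frequencies of the blended study are count-weighted averages of P and Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .disease import ConditionalGenotypeFreqs, DiseaseModel, conditional_genotype_freqs


@dataclass(frozen=True)
class ConfusionMatrix:
    """Predictive values of the silver-standard labels.

    phi = P(Z=affected | X=case), theta = P(Z=unaffected | X=control) among
    silver-standard subjects.  phi = theta = 1 recovers error-free labels.
    """

    phi: float
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi={self.phi} outside [0, 1]")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta={self.theta} outside [0, 1]")

    def as_matrix(self) -> np.ndarray:
        """2x2 row-stochastic matrix T, rows X=(case, control), cols Z=(aff, unaff)."""
        return np.array([[self.phi, 1.0 - self.phi], [1.0 - self.theta, self.theta]])


#: Error-free labels, the convention for gold-standard subjects.
PERFECT_LABELS = ConfusionMatrix(phi=1.0, theta=1.0)


@dataclass(frozen=True)
class StudyDesign:
    """Sample-size structure: gold controls plus three ratios."""

    n_co: float
    r: float
    gamma_ca: float
    gamma_co: float

    def __post_init__(self) -> None:
        if self.n_co <= 0:
            raise ValueError(f"n_co={self.n_co} must be positive")
        if self.r <= 0:
            raise ValueError(f"r={self.r} must be positive")
        if self.gamma_ca < 0 or self.gamma_co < 0:
            raise ValueError("gamma_ca and gamma_co must be non-negative")


@dataclass(frozen=True)
class GroupCounts:
    """Derived per-group sample counts and row totals M1 (cases), M2 (controls)."""

    n_gold_case: float
    n_silver_case: float
    n_gold_control: float
    n_silver_control: float
    m1: float
    m2: float


@dataclass(eq=False)
class MixedFrequencies:
    """Genotype frequencies m1 (case-labelled row) and m2 (control-labelled row)."""

    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        for name, row in (("m1", self.m1), ("m2", self.m2)):
            if not np.isclose(row.sum(), 1.0, atol=1e-8):
                raise ValueError(f"{name} does not sum to 1: {row}")


def group_counts(design: StudyDesign) -> GroupCounts:
    """Expand a design into per-group counts.

    Counts are carried as real numbers for the analytic path; a warning is
    emitted when the gold-case count n_co / r is not an integer.
    """
    n_gold_case = design.n_co / design.r
    if abs(n_gold_case - round(n_gold_case)) > 1e-9:
        warnings.warn(
            f"gold case count n_co/r = {n_gold_case} is not an integer; "
            "kept as a real number for analytic use",
            stacklevel=2,
        )
    n_silver_case = design.gamma_ca * n_gold_case
    n_silver_control = design.gamma_co * design.n_co
    return GroupCounts(
        n_gold_case=n_gold_case,
        n_silver_case=n_silver_case,
        n_gold_control=design.n_co,
        n_silver_control=n_silver_control,
        m1=n_gold_case * (1.0 + design.gamma_ca),
        m2=design.n_co * (1.0 + design.gamma_co),
    )


def silver_frequencies(
    confusion: ConfusionMatrix, p: ConditionalGenotypeFreqs
) -> ConditionalGenotypeFreqs:
    """Genotype frequencies among silver-standard subjects: Q = T' P.

    Q_case = phi * p_case + (1 - phi) * p_control;
    Q_control = (1 - theta) * p_case + theta * p_control.
    Each row of Q is a convex combination of P's rows, so row-stochasticity
    is preserved exactly.
    """
    return ConditionalGenotypeFreqs(
        p_case=confusion.phi * p.p_case + (1.0 - confusion.phi) * p.p_control,
        p_control=(1.0 - confusion.theta) * p.p_case + confusion.theta * p.p_control,
    )


def mixed_frequencies(
    p: ConditionalGenotypeFreqs,
    q: ConditionalGenotypeFreqs,
    counts: GroupCounts,
) -> MixedFrequencies:
    """Count-weighted average of gold (P) and silver (Q) genotype frequencies."""
    if counts.m1 <= 0:
        raise ValueError("no case-labelled subjects (m1 = 0)")
    if counts.m2 <= 0:
        raise ValueError("no control-labelled subjects (m2 = 0)")
    m1 = (counts.n_gold_case * p.p_case + counts.n_silver_case * q.p_case) / counts.m1
    m2 = (
        counts.n_gold_control * p.p_control
        + counts.n_silver_control * q.p_control
    ) / counts.m2
    return MixedFrequencies(m1=m1, m2=m2)


@dataclass(frozen=True)
class Scenario:
    """One point omega of the parameter space: design, labels, disease, alpha."""

    design: StudyDesign
    confusion: ConfusionMatrix
    disease: DiseaseModel
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")

    def group_counts(self) -> GroupCounts:
        return group_counts(self.design)

    def gold_silver_freqs(
        self,
    ) -> tuple[ConditionalGenotypeFreqs, ConditionalGenotypeFreqs]:
        """(P, Q): gold-standard and silver-standard conditional genotype freqs."""
        p = conditional_genotype_freqs(self.disease)
        return p, silver_frequencies(self.confusion, p)

    def mixed_frequencies(self) -> MixedFrequencies:
        """Blended case/control genotype frequencies (m1, m2) of this scenario."""
        p, q = self.gold_silver_freqs()
        return mixed_frequencies(p, q, self.group_counts())

    def with_gamma_ca(self, gamma_ca: float) -> "Scenario":
        """Copy of this scenario with the silver-case ratio replaced."""
        return replace(self, design=replace(self.design, gamma_ca=gamma_ca))
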