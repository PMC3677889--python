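"""Asymptotic non-centrality and power of the 2-df chi-square test.

Under an alternative in which M1 case-labelled and M2 control-labelled
subjects have genotype frequencies m1 and m2, the Pearson X^2 statistic on
the 2x3 table is asymptotically non-central chi-square with 2 degrees of
freedom and non-centrality

    lambda = sum_k M1 * M2 * (m1_k - m2_k)^2 / C_k,

where C_k = M1*m1_k + M2*m2_k is the k-th column total of the expected-count
table.  This closed form is algebraically identical to the X^2 statistic
evaluated on the expected-count table itself (rows M1*m1 and M2*m2), an
identity the test suite exercises as the implementation oracle.

Power at significance level alpha is

    1 - F_{ncx2(2, lambda)}( q_{chi2(2)}(1 - alpha) ),

where with 2 central degrees of freedom q_{chi2(2)}(1 - alpha) = -2 ln(alpha).
Power is strictly increasing in lambda, so the sign of d(lambda)/d(gamma_ca)
— the marginal effect of adding silver-standard cases — is the sign of the
change in power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import GroupCounts, MixedFrequencies, Scenario, mixed_frequencies


@dataclass(frozen=True)
class PowerResult:
    """Non-centrality and power of one scenario at one significance level."""

    lam: float
    power: float
    alpha: float
    df: int = 2


@dataclass(eq=False)
class RegionMap:
    """Sign of d(lambda)/d(gamma_ca) over a (phi, R) grid.

    ``sign[i, j]`` is the sign at phi_grid[i], r_grid[j]: +1 where adding
    silver cases increases power, -1 where it reduces power, 0 at the null.
    """

    phi_grid: np.ndarray
    r_grid: np.ndarray
    sign: np.ndarray


def noncentrality(freqs: MixedFrequencies, counts: GroupCounts) -> float:
    """Non-centrality lambda of the 2-df test for the given blended study.

    Genotype columns with zero total frequency (e.g. a monomorphic locus)
    are dropped with a warning; the remaining columns define a reduced-df
    statistic.
    """
    m1, m2 = counts.m1, counts.m2
    if m1 + m2 <= 0:
        raise ValueError("empty study: m1 + m2 = 0")
    col = m1 * freqs.m1 + m2 * freqs.m2
    keep = col > 0
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} genotype column(s) structurally empty; "
            f"df reduced to {int(keep.sum()) - 1}",
            stacklevel=2,
        )
    delta = freqs.m1[keep] - freqs.m2[keep]
    return float(m1 * m2 * np.sum(delta**2 / col[keep]))


def scenario_noncentrality(scenario: Scenario) -> float:
    """lambda for one scenario, composing P -> Q -> mixed frequencies."""
    return noncentrality(scenario.mixed_frequencies(), scenario.group_counts())


def power(lam: float, alpha: float, df: int = 2) -> float:
    """Power of the chi-square test at non-centrality lam and level alpha."""
    if lam < 0:
        raise ValueError(f"non-centrality lam={lam} must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    crit = stats.chi2.isf(alpha, df)
    if lam == 0.0:
        return float(stats.chi2.sf(crit, df))
    return float(stats.ncx2.sf(crit, df, lam))


def scenario_power(scenario: Scenario, alpha: float | None = None) -> PowerResult:
    """Non-centrality and power for one scenario."""
    a = scenario.alpha if alpha is None else alpha
    lam = scenario_noncentrality(scenario)
    return PowerResult(lam=lam, power=power(lam, a), alpha=a)


def dlambda_dgamma_ca(scenario: Scenario) -> float:
    """Exact derivative of lambda in the silver-case ratio gamma_ca.

    gamma_ca is treated as continuous; a positive value means power increases
    with the inclusion of silver-standard cases.  The derivative is obtained
    by differentiating the closed form term by term: with n_gc gold cases,

        M1 = n_gc (1 + gamma),  dM1 = n_gc,
        M1 m1_k = n_gc (p_k + gamma q_k),  d(M1 m1_k) = n_gc q_k,
        C_k = M1 m1_k + M2 m2_k,  dC_k = n_gc q_k,

    where p, q are the gold and silver case-row genotype frequencies.
    """
    p, q = scenario.gold_silver_freqs()
    counts = scenario.group_counts()
    n_gc = counts.n_gold_case
    mixed = mixed_frequencies(p, q, counts)
    m1_row, m2_row = mixed.m1, mixed.m2
    m1_tot, m2_tot = counts.m1, counts.m2
    gamma = scenario.design.gamma_ca

    col = m1_tot * m1_row + m2_tot * m2_row
    keep = col > 0
    delta = m1_row - m2_row
    # d m1_k / d gamma = (q_k - m1_k) / (1 + gamma)
    ddelta = (q.p_case - m1_row) / (1.0 + gamma)
    dcol = n_gc * q.p_case

    term = (
        m2_tot * n_gc * delta**2 / col
        + 2.0 * m1_tot * m2_tot * delta * ddelta / col
        - m1_tot * m2_tot * delta**2 * dcol / col**2
    )
    return float(term[keep].sum())


def dlambda_dgamma_ca_fd(scenario: Scenario, rel_step: float = 1e-6) -> float:
    """Central finite-difference check of :func:`dlambda_dgamma_ca`."""
    g = scenario.design.gamma_ca
    h = rel_step * max(1.0, abs(g))
    lo = max(g - h, 0.0)
    hi = g + h
    lam_hi = scenario_noncentrality(scenario.with_gamma_ca(hi))
    lam_lo = scenario_noncentrality(scenario.with_gamma_ca(lo))
    return float((lam_hi - lam_lo) / (hi - lo))


def power_region_map(
    base: Scenario, phi_grid: np.ndarray, r_grid: np.ndarray
) -> RegionMap:
    """Sign of d(lambda)/d(gamma_ca) over a (phi, R) grid, other parameters fixed.

    Raises
    ------
    silverpower.disease.UnphysicalModelError
        The disease model is shared across the grid, so an unphysical base
        model is rejected rather than silently dropped.
    """
    from dataclasses import replace

    phi_grid = np.asarray(phi_grid, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    sign = np.zeros((phi_grid.size, r_grid.size), dtype=int)
    for i, phi in enumerate(phi_grid):
        for j, r in enumerate(r_grid):
            sc = replace(
                base,
                design=replace(base.design, r=float(r)),
                confusion=replace(base.confusion, phi=float(phi)),
            )
            d = dlambda_dgamma_ca(sc)
            sign[i, j] = 0 if d == 0.0 else (1 if d > 0 else -1)
    return RegionMap(phi_grid=phi_grid, r_grid=r_grid, sign=sign)
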