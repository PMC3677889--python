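"""Monte-Carlo validation of the asymptotic power approximation.

Each replicate draws the case row of a 2x3 phenotype-by-genotype table from
a 3-category multinomial(M1, m1) and the control row, independently, from
multinomial(M2, m2) — case-control sampling conditional on fixed group
totals, matching the conditional-frequency formulation of the asymptotics.

The point of comparison between the simulated and asymptotic sampling
distributions is the 20th percentile of X^2: since 80% of realizations
exceed it, it is the critical value that would give exactly 80% power, so
comparing the empirical and non-central chi-square 20th percentiles probes
the approximation where a study designer would use it.  The percentage
error of a scenario omega is

    E(omega) = 100 * (q20_sim - q20_asym) / q20_asym.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import Scenario
from .grids import ScenarioGrid
from .power import scenario_noncentrality

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class SweepResult:
    """Asymptotic-vs-simulated comparison for one scenario."""

    scenario_id: int
    lam_analytic: float
    q20_sim: float
    q20_asym: float
    e_omega: float
    n_reps: int
    seed: int


@dataclass(eq=False)
class ORBiasSummary:
    """Allelic odds-ratio estimates under misclassification vs the truth."""

    or_true: float
    or_mean: float
    or_median: float
    n_reps: int
    n_corrected: int  # replicates needing the Haldane-Anscombe 0.5 correction


def chisq_stat(table: np.ndarray) -> float:
    """Pearson X^2 for a 2x3 table: sum (O - E)^2 / E with E from margins.

    Genotype columns with zero total are dropped (reducing the degrees of
    freedom of the reference distribution) with a warning.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 3):
        raise ValueError(f"expected a 2x3 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("table has negative counts")
    col = table.sum(axis=0)
    keep = col > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} empty genotype column(s) dropped; "
            f"df reduced to {int(keep.sum()) - 1}",
            stacklevel=2,
        )
        table = table[:, keep]
        col = col[keep]
    row = table.sum(axis=1)
    if (row <= 0).any():
        raise ValueError("each row must have at least one positive entry")
    n = table.sum()
    expected = np.outer(row, col) / n
    return float(((table - expected) ** 2 / expected).sum())


def _chisq_batch(tables: np.ndarray) -> np.ndarray:
    """X^2 for a stack of 2x3 tables, shape (n, 2, 3).

    Empty columns contribute nothing to the statistic (observed = expected
    = 0), so they are handled by masking rather than per-table reshaping.
    """
    row = tables.sum(axis=2, keepdims=True)  # (n, 2, 1)
    col = tables.sum(axis=1, keepdims=True)  # (n, 1, 3)
    n = tables.sum(axis=(1, 2), keepdims=True)
    expected = row * col / n
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (tables - expected) ** 2 / expected
    return np.where(expected > 0, cells, 0.0).sum(axis=(1, 2))


def _rounded_counts(scenario: Scenario) -> tuple[int, int]:
    """Integer (M1, M2) for simulation, logging when rounding occurs."""
    counts = scenario.group_counts()
    m1, m2 = int(round(counts.m1)), int(round(counts.m2))
    if abs(m1 - counts.m1) > 1e-9 or abs(m2 - counts.m2) > 1e-9:
        logger.info(
            "rounded group totals (M1, M2) = (%s, %s) -> (%d, %d)",
            counts.m1,
            counts.m2,
            m1,
            m2,
        )
    return m1, m2


def simulate_tables(scenario: Scenario, n_reps: int, seed: int) -> np.ndarray:
    """X^2 statistics from ``n_reps`` multinomial replicates of a scenario.

    Fully reproducible from ``seed``.  Unphysical scenarios are refused.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    freqs = scenario.mixed_frequencies()  # raises for unphysical models
    m1, m2 = _rounded_counts(scenario)
    rng = np.random.default_rng(seed)
    cases = rng.multinomial(m1, freqs.m1, size=n_reps)
    controls = rng.multinomial(m2, freqs.m2, size=n_reps)
    return _chisq_batch(np.stack([cases, controls], axis=1).astype(float))


def empirical_error(
    scenario: Scenario,
    n_reps: int = 500,
    seed: int = 0,
    scenario_id: int = 0,
) -> SweepResult:
    """Percentage error E(omega) of the asymptotic 20th percentile.

    q20_sim is the empirical 20th percentile of simulated X^2 (linear
    interpolation between order statistics); q20_asym the 20th percentile of
    the non-central chi-square(2, lambda(omega)).  For a null scenario
    q20_asym = -2 ln(0.8) ~= 0.4463 in closed form.
    """
    lam = scenario_noncentrality(scenario)
    stats_sim = simulate_tables(scenario, n_reps, seed)
    q20_sim = float(np.quantile(stats_sim, 0.2))
    if lam == 0.0:
        q20_asym = float(stats.chi2.ppf(0.2, 2))
    else:
        q20_asym = float(stats.ncx2.ppf(0.2, 2, lam))
    e_omega = 100.0 * (q20_sim - q20_asym) / q20_asym if q20_asym > 0 else np.nan
    if not np.isfinite(e_omega):
        logger.warning("q20_asym = 0 for scenario %d; E(omega) undefined", scenario_id)
    return SweepResult(
        scenario_id=scenario_id,
        lam_analytic=lam,
        q20_sim=q20_sim,
        q20_asym=q20_asym,
        e_omega=float(e_omega),
        n_reps=n_reps,
        seed=seed,
    )


def scenario_seed(master_seed: int, index: int) -> int:
    """Stable per-scenario seed, independent of sweep order or parallelism."""
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31)
    )


def sweep_grid(
    grid: ScenarioGrid, n_reps: int = 500, master_seed: int = 0
) -> pd.DataFrame:
    """One :class:`SweepResult` row per physical scenario of ``grid``.

    Unphysical scenarios are excluded (their count appears in the
    ``n_unphysical`` DataFrame attribute).  Each scenario gets its own seed
    derived from ``master_seed`` and its grid index, so any subset can be
    re-run independently and bit-identically.
    """
    mask = grid.physical_mask()
    rows = []
    for i in np.flatnonzero(mask):
        res = empirical_error(
            grid.scenario(int(i)),
            n_reps=n_reps,
            seed=scenario_seed(master_seed, int(i)),
            scenario_id=int(i),
        )
        rows.append(res.__dict__)
        if len(rows) % 1000 == 0:
            logger.info("swept %d scenarios", len(rows))
    out = pd.DataFrame(rows)
    out.attrs["n_unphysical"] = int((~mask).sum())
    out.attrs["master_seed"] = master_seed
    return out


def _allelic_or(table: np.ndarray) -> tuple[float, bool]:
    """Allelic odds ratio from a 2x3 genotype table (aa, Aa, AA columns).

    Returns (estimate, corrected) where corrected marks use of the
    Haldane-Anscombe 0.5 continuity correction for zero allele counts.
    """
    risk = table[:, 1] + 2.0 * table[:, 2]  # risk-allele count per row
    nonrisk = 2.0 * table[:, 0] + table[:, 1]
    cells = np.array([risk[0], nonrisk[0], risk[1], nonrisk[1]], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a_ca, b_ca, a_co, b_co = cells
    return float((a_ca * b_co) / (b_ca * a_co)), corrected


def or_bias(scenario: Scenario, n_reps: int = 500, seed: int = 0) -> ORBiasSummary:
    """Attenuation of the allelic odds ratio under label misclassification.

    The "true" OR is computed from the gold-standard conditional genotype
    frequencies (p_case, p_control); the estimates come from the blended
    study's simulated tables, whose case row is diluted by silver-standard
    misclassification, biasing estimates towards 1.
    """
    if scenario.disease.rr_AA <= 1.0:
        raise ValueError("or_bias requires an effect (rr_AA > 1)")
    p, _ = scenario.gold_silver_freqs()
    m1, m2 = _rounded_counts(scenario)
    freqs = scenario.mixed_frequencies()

    def allele_freq(row: np.ndarray) -> float:
        return float(row[1] / 2.0 + row[2])

    fa_case, fa_ctrl = allele_freq(p.p_case), allele_freq(p.p_control)
    or_true = (fa_case / (1 - fa_case)) / (fa_ctrl / (1 - fa_ctrl))

    rng = np.random.default_rng(seed)
    cases = rng.multinomial(m1, freqs.m1, size=n_reps)
    controls = rng.multinomial(m2, freqs.m2, size=n_reps)
    ests = np.empty(n_reps)
    n_corrected = 0
    for i in range(n_reps):
        ests[i], corr = _allelic_or(
            np.stack([cases[i], controls[i]]).astype(float)
        )
        n_corrected += corr
    if n_corrected:
        logger.info("Haldane-Anscombe correction applied in %d replicates", n_corrected)
    return ORBiasSummary(
        or_true=or_true,
        or_mean=float(ests.mean()),
        or_median=float(np.median(ests)),
        n_reps=n_reps,
        n_corrected=n_corrected,
    )
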