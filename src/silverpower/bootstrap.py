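"""Empirical power by bootstrap resampling of per-locus genotype pools.

Given observed genotype counts for a locus in three pools — gold-standard
cases, silver-standard cases and gold-standard controls — a hypothetical
study at ratios (R, gamma_ca) is emulated by resampling genotypes with
replacement from each pool at the implied sizes, forming the 2x3 table
(cases = gold + silver), and computing X^2.  The empirical 20th percentile
of X^2 over many replicates is the power summary, directly comparable with
the 20th percentile of the non-central chi-square(2, lambda) implied by an
assumed disease model (:func:`asymptotic_counterpart`).

Resample sizes follow a fixed gold-case budget convention: gold cases =
budget (default: the gold-case pool size), gold controls = R x budget,
silver cases = gamma_ca x budget, each rounded to the nearest integer.

Real genotype pools are read/written as a delimited table (columns locus,
pool, n_aa, n_Aa, n_AA); :func:`make_locus_fixture` generates synthetic
pools from a known disease model for validation studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    ConfusionMatrix,
    GroupCounts,
    MixedFrequencies,
    StudyDesign,
    group_counts,
    mixed_frequencies,
    silver_frequencies,
)
from .disease import DiseaseModel, conditional_genotype_freqs
from .power import noncentrality
from .simulate import _chisq_batch

logger = logging.getLogger(__name__)

POOL_NAMES = ("gold_case", "silver_case", "gold_control")


@dataclass(eq=False)
class LocusPools:
    """Genotype counts (aa, Aa, AA) for the three pools at one locus."""

    locus: str
    gold_case: np.ndarray
    silver_case: np.ndarray
    gold_control: np.ndarray

    def __post_init__(self) -> None:
        for name in POOL_NAMES:
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (3,) or (arr < 0).any():
                raise ValueError(f"{name} must be a non-negative 3-vector of counts")
            setattr(self, name, arr)

    def pool(self, name: str) -> np.ndarray:
        if name not in POOL_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(eq=False)
class BootstrapPowerCurve:
    """q20 of bootstrap X^2 (and asymptotic counterpart) per (gamma_ca, R)."""

    table: pd.DataFrame  # columns: locus, r, gamma_ca, q20_boot, n_reps, seed


def make_locus_fixture(
    model: DiseaseModel,
    confusion: ConfusionMatrix,
    pool_sizes: tuple[int, int, int],
    seed: int,
    locus: str = "synthetic",
) -> LocusPools:
    """Synthetic genotype pools drawn from a known scenario.

    Pool sizes are ordered (gold cases, silver cases, gold controls).  Gold
    pools are drawn from the gold-standard conditional genotype frequencies
    and the silver-case pool from the misclassification-permuted frequencies
    Q, so the pools are exactly self-consistent with the analytic model —
    the basis of the bootstrap-vs-asymptotic validation tests.
    """
    p = conditional_genotype_freqs(model)  # refuses unphysical models
    q = silver_frequencies(confusion, p)
    n_gca, n_sca, n_gco = pool_sizes
    rng = np.random.default_rng(seed)
    return LocusPools(
        locus=locus,
        gold_case=rng.multinomial(n_gca, p.p_case),
        silver_case=rng.multinomial(n_sca, q.p_case),
        gold_control=rng.multinomial(n_gco, p.p_control),
    )


def bootstrap_power(
    pools: LocusPools,
    r: float,
    gamma_ca: float,
    n_reps: int = 1000,
    seed: int = 0,
    gold_case_budget: int | None = None,
    quantile: float = 0.2,
) -> float:
    """Empirical ``quantile`` of bootstrap X^2 at ratios (R, gamma_ca).

    Resampling genotypes with replacement from a pool of counts c is a
    multinomial draw with probabilities c / sum(c).
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    budget = int(pools.gold_case.sum()) if gold_case_budget is None else int(gold_case_budget)
    if budget <= 0:
        raise ValueError("gold-case budget must be positive")
    n_silver = int(round(gamma_ca * budget))
    n_control = int(round(r * budget))
    if n_silver != gamma_ca * budget or n_control != r * budget:
        logger.info(
            "rounded resample sizes: silver cases %s -> %d, controls %s -> %d",
            gamma_ca * budget,
            n_silver,
            r * budget,
            n_control,
        )
    for name, size in (("gold_case", budget), ("silver_case", n_silver), ("gold_control", n_control)):
        pool = pools.pool(name)
        if size > 0 and pool.sum() == 0:
            raise ValueError(f"cannot resample {size} subjects from empty pool {name!r}")

    rng = np.random.default_rng(seed)
    gold = rng.multinomial(budget, pools.gold_case / pools.gold_case.sum(), size=n_reps)
    if n_silver > 0:
        silver = rng.multinomial(
            n_silver, pools.silver_case / pools.silver_case.sum(), size=n_reps
        )
    else:
        silver = np.zeros_like(gold)
    controls = rng.multinomial(
        n_control, pools.gold_control / pools.gold_control.sum(), size=n_reps
    )
    tables = np.stack([gold + silver, controls], axis=1).astype(float)
    return float(np.quantile(_chisq_batch(tables), quantile))


def bootstrap_power_curve(
    pools: LocusPools,
    r_values,
    gamma_ca_values,
    n_reps: int = 1000,
    seed: int = 0,
    gold_case_budget: int | None = None,
) -> BootstrapPowerCurve:
    """q20 of bootstrap X^2 over the (gamma_ca, R) product grid."""
    rows = []
    for i, r in enumerate(r_values):
        for j, g in enumerate(gamma_ca_values):
            sub_seed = int(
                np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % (2**31)
            )
            q20 = bootstrap_power(
                pools,
                r=float(r),
                gamma_ca=float(g),
                n_reps=n_reps,
                seed=sub_seed,
                gold_case_budget=gold_case_budget,
            )
            rows.append(
                {
                    "locus": pools.locus,
                    "r": float(r),
                    "gamma_ca": float(g),
                    "q20_boot": q20,
                    "n_reps": n_reps,
                    "seed": sub_seed,
                }
            )
    return BootstrapPowerCurve(table=pd.DataFrame(rows))


def asymptotic_counterpart(
    model: DiseaseModel,
    confusion: ConfusionMatrix,
    design: StudyDesign,
    quantile: float = 0.2,
) -> float:
    """``quantile`` of the non-central chi-square(2, lambda) for one design.

    The asymptotic twin of :func:`bootstrap_power`: lambda is composed from
    the disease model, the silver-label confusion matrix and the design.
    For lambda = 0 this is the central chi-square quantile
    (-2 ln(1 - quantile) in closed form; ~0.4463 at the 20th percentile).
    """
    p = conditional_genotype_freqs(model)
    q = silver_frequencies(confusion, p)
    counts = group_counts(design)
    lam = noncentrality(mixed_frequencies(p, q, counts), counts)
    if lam == 0.0:
        return float(stats.chi2.ppf(quantile, 2))
    return float(stats.ncx2.ppf(quantile, 2, lam))


def pool_asymptotic_q20(
    pools: LocusPools,
    r: float,
    gamma_ca: float,
    gold_case_budget: int | None = None,
    quantile: float = 0.2,
) -> float:
    """``quantile`` of the non-central chi-square implied by the pools themselves.

    Conditional on the observed pools, the bootstrap resamples from their
    empirical genotype frequencies, so its large-sample reference is the
    non-centrality computed from those frequencies — not from any assumed
    disease model.  Comparing :func:`bootstrap_power` against this quantity
    isolates finite-study-size effects from pool sampling noise.
    """
    budget = int(pools.gold_case.sum()) if gold_case_budget is None else int(gold_case_budget)
    n_silver = int(round(gamma_ca * budget))
    n_control = int(round(r * budget))
    gold_f = pools.gold_case / pools.gold_case.sum()
    control_f = pools.gold_control / pools.gold_control.sum()
    m1_total = budget + n_silver
    if n_silver > 0:
        silver_f = pools.silver_case / pools.silver_case.sum()
        m1 = (budget * gold_f + n_silver * silver_f) / m1_total
    else:
        m1 = gold_f
    counts = GroupCounts(
        n_gold_case=budget,
        n_silver_case=n_silver,
        n_gold_control=n_control,
        n_silver_control=0,
        m1=m1_total,
        m2=n_control,
    )
    lam = noncentrality(MixedFrequencies(m1=m1, m2=control_f), counts)
    if lam == 0.0:
        return float(stats.chi2.ppf(quantile, 2))
    return float(stats.ncx2.ppf(quantile, 2, lam))


def read_pools(path) -> list[LocusPools]:
    """Read per-locus pools from a delimited table.

    Expected columns: locus, pool (gold_case | silver_case | gold_control),
    n_aa, n_Aa, n_AA.  Comment lines starting with '#' are skipped.
    """
    df = pd.read_csv(path, comment="#")
    required = {"locus", "pool", "n_aa", "n_Aa", "n_AA"}
    if not required.issubset(df.columns):
        raise ValueError(f"pools table must have columns {sorted(required)}")
    out = []
    for locus, sub in df.groupby("locus", sort=False):
        counts = {}
        for row in sub.itertuples(index=False):
            if row.pool not in POOL_NAMES:
                raise ValueError(f"unknown pool name {row.pool!r} for locus {locus!r}")
            counts[row.pool] = np.array([row.n_aa, row.n_Aa, row.n_AA], dtype=int)
        missing = [p for p in POOL_NAMES if p not in counts]
        if missing:
            raise ValueError(f"locus {locus!r} missing pools: {missing}")
        out.append(LocusPools(locus=str(locus), **counts))
    return out


def write_pools(pools_list: list[LocusPools], path) -> None:
    """Write pools in the same delimited layout :func:`read_pools` expects."""
    rows = []
    for pools in pools_list:
        for name in POOL_NAMES:
            c = pools.pool(name)
            rows.append(
                {
                    "locus": pools.locus,
                    "pool": name,
                    "n_aa": int(c[0]),
                    "n_Aa": int(c[1]),
                    "n_AA": int(c[2]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
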