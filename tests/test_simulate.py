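"""Monte-Carlo engine: Pearson statistic, sampling, calibration, OR bias."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from silverpower import (
    ConfusionMatrix,
    DiseaseModel,
    Scenario,
    StudyDesign,
    chisq_stat,
    empirical_error,
    or_bias,
    simulate_tables,
    sweep_grid,
)
from silverpower.grids import ScenarioGrid
from silverpower.simulate import scenario_seed


def null_scenario(n_co=1000, r=2, gamma_ca=1, gamma_co=1, phi=0.6, theta=0.8):
    return Scenario(
        design=StudyDesign(n_co, r, gamma_ca, gamma_co),
        confusion=ConfusionMatrix(phi, theta),
        disease=DiseaseModel(m=0.2, k=0.05, rr_AA=1.0, mode="multiplicative"),
    )


def test_chisq_identical_rows_is_zero():
    assert chisq_stat([[10, 20, 10], [10, 20, 10]]) == pytest.approx(0.0)


def test_chisq_hand_computed_example():
    # margins (40, 60) x (30, 40, 30), E = [[12,16,12],[18,24,18]]
    assert chisq_stat([[10, 20, 10], [20, 20, 20]]) == pytest.approx(2.7778, abs=1e-4)


def test_chisq_scales_with_counts():
    table = np.array([[12, 35, 9], [20, 18, 30]], dtype=float)
    assert chisq_stat(7 * table) == pytest.approx(7 * chisq_stat(table), rel=1e-12)


def test_chisq_drops_empty_genotype_column():
    with pytest.warns(UserWarning, match="df reduced"):
        x2 = chisq_stat([[10, 20, 0], [20, 20, 0]])
    ref, *_ = stats.chi2_contingency([[10, 20], [20, 20]], correction=False)
    assert x2 == pytest.approx(ref, rel=1e-12)


def test_simulation_reproducible_from_seed(reference_scenario):
    a = simulate_tables(reference_scenario, n_reps=50, seed=123)
    b = simulate_tables(reference_scenario, n_reps=50, seed=123)
    assert np.array_equal(a, b)
    c = simulate_tables(reference_scenario, n_reps=50, seed=124)
    assert not np.array_equal(a, c)


def test_monomorphic_locus_yields_zero_statistics():
    sc = Scenario(
        design=StudyDesign(1000, 2, 0, 0),
        confusion=ConfusionMatrix(1.0, 1.0),
        disease=DiseaseModel(m=0.0, k=0.05, rr_AA=1.0, mode="dominant"),
    )
    assert np.allclose(simulate_tables(sc, n_reps=20, seed=0), 0.0)


def test_null_rejection_rate_at_nominal_level():
    """Misclassification leaves the type-I error of the test untouched."""
    x2 = simulate_tables(null_scenario(), n_reps=2000, seed=99)
    crit = stats.chi2.isf(0.05, 2)
    rate = (x2 > crit).mean()
    # binomial 99% CI around 0.05 at n=2000
    half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
    assert abs(rate - 0.05) < half


def test_unphysical_scenario_refused():
    sc = Scenario(
        design=StudyDesign(1000, 2, 1, 0),
        confusion=ConfusionMatrix(0.8, 1.0),
        disease=DiseaseModel(m=0.05, k=0.3, rr_AA=9, mode="multiplicative"),
    )
    with pytest.raises(Exception, match="unphysical"):
        simulate_tables(sc, n_reps=10, seed=0)


def test_null_q20_asym_closed_form():
    """Central chi-square(2df) 20th percentile is -2 ln(0.8)."""
    res = empirical_error(null_scenario(n_co=5000), n_reps=4000, seed=5)
    assert res.q20_asym == pytest.approx(-2 * np.log(0.8), abs=1e-10)
    assert res.q20_asym == pytest.approx(0.4463, abs=1e-4)
    # empirical error near zero at large N and many reps
    assert abs(res.e_omega) < 10


def test_empirical_error_small_at_large_noncentrality(reference_scenario):
    res = empirical_error(reference_scenario, n_reps=500, seed=11)
    assert res.lam_analytic > 20
    assert abs(res.e_omega) < 10


def test_empirical_error_converges_with_replicates():
    sc = null_scenario(n_co=4000, r=1, gamma_ca=0, gamma_co=0)
    res = empirical_error(sc, n_reps=100_000, seed=17)
    # MC SE of the 20th percentile via the asymptotic quantile formula
    q = res.q20_asym
    dens = stats.chi2.pdf(q, 2)
    se_pct = 100 * np.sqrt(0.2 * 0.8 / 100_000) / dens / q
    assert abs(res.e_omega) < 3 * se_pct


def test_sweep_excludes_unphysical_and_seeds_per_scenario():
    grid = ScenarioGrid.from_product(
        {
            "r": (2,),
            "gamma_ca": (1,),
            "gamma_co": (0,),
            "phi": (0.8,),
            "theta": (1.0,),
            "rr_AA": (1.0, 9.0),
            "n_co": (1000,),
            "m": (0.05,),
            "k": (0.01, 0.3),
            "mode": ("multiplicative",),
        }
    )
    out = sweep_grid(grid, n_reps=100, master_seed=3)
    assert out.attrs["n_unphysical"] == 1  # k=0.3, rr=9 multiplicative
    assert len(out) == 3
    # re-running one scenario with its own seed reproduces the row
    row = out.iloc[-1]
    res = empirical_error(
        grid.scenario(int(row.scenario_id)),
        n_reps=100,
        seed=scenario_seed(3, int(row.scenario_id)),
        scenario_id=int(row.scenario_id),
    )
    assert res.q20_sim == row.q20_sim
    assert res.e_omega == row.e_omega


@pytest.fixture(scope="module")
def attenuation_scenario():
    # strong effect read through heavily contaminated silver cases
    return Scenario(
        design=StudyDesign(n_co=1000, r=4, gamma_ca=4, gamma_co=0),
        confusion=ConfusionMatrix(phi=0.6, theta=1.0),
        disease=DiseaseModel(m=0.3, k=0.01, rr_AA=3, mode="multiplicative"),
    )


def test_or_unbiased_with_perfect_labels(attenuation_scenario):
    sc = replace(attenuation_scenario, confusion=ConfusionMatrix(1.0, 1.0))
    res = or_bias(sc, n_reps=500, seed=21)
    assert res.or_median == pytest.approx(res.or_true, rel=0.05)


def test_or_attenuated_towards_one_by_misclassification(attenuation_scenario):
    biased = or_bias(attenuation_scenario, n_reps=500, seed=21)
    clean = or_bias(
        replace(attenuation_scenario, confusion=ConfusionMatrix(1.0, 1.0)),
        n_reps=500,
        seed=21,
    )
    assert 1.0 < biased.or_median < clean.or_median


def test_or_attenuation_grows_with_silver_fraction(attenuation_scenario):
    little = or_bias(
        replace(
            attenuation_scenario,
            design=replace(attenuation_scenario.design, gamma_ca=1),
        ),
        n_reps=500,
        seed=22,
    )
    lots = or_bias(attenuation_scenario, n_reps=500, seed=22)
    assert lots.or_median < little.or_median
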