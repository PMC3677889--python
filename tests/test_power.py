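"""Non-centrality, power, the silver-case derivative and region maps."""

import numpy as np
import pytest
from scipy import stats

from silverpower import (
    ConfusionMatrix,
    DiseaseModel,
    Scenario,
    StudyDesign,
    chisq_stat,
    dlambda_dgamma_ca,
    power,
    power_region_map,
    scenario_noncentrality,
)
from silverpower.power import dlambda_dgamma_ca_fd

from conftest import random_valid_scenarios


def expected_table(scenario):
    counts = scenario.group_counts()
    freqs = scenario.mixed_frequencies()
    return np.stack([counts.m1 * freqs.m1, counts.m2 * freqs.m2])


@pytest.mark.parametrize("mode", ["dominant", "recessive", "multiplicative"])
def test_null_model_noncentrality_is_zero(mode):
    sc = Scenario(
        design=StudyDesign(1000, 2, 4, 4),
        confusion=ConfusionMatrix(0.6, 0.6),
        disease=DiseaseModel(m=0.1, k=0.01, rr_AA=1.0, mode=mode),
    )
    assert scenario_noncentrality(sc) == pytest.approx(0.0, abs=1e-12)


def test_noncentrality_equals_chisq_of_expected_table(reference_scenario):
    lam = scenario_noncentrality(reference_scenario)
    assert lam == pytest.approx(chisq_stat(expected_table(reference_scenario)), rel=1e-8)


def test_noncentrality_oracle_identity_on_random_scenarios():
    """lambda must equal the Pearson statistic on the expected-count table."""
    rng = np.random.default_rng(20240901)
    for sc in random_valid_scenarios(rng, 200):
        lam = scenario_noncentrality(sc)
        assert lam == pytest.approx(chisq_stat(expected_table(sc)), rel=1e-8, abs=1e-12)


def test_noncentrality_scales_linearly_with_sample_size(reference_scenario):
    from dataclasses import replace

    lam = scenario_noncentrality(reference_scenario)
    doubled = replace(
        reference_scenario,
        design=replace(reference_scenario.design, n_co=2 * reference_scenario.design.n_co),
    )
    assert scenario_noncentrality(doubled) == pytest.approx(2 * lam, rel=1e-10)


def test_power_central_case_equals_size():
    assert power(0.0, 0.05) == pytest.approx(0.05, rel=1e-10)


def test_power_saturates_at_large_noncentrality():
    assert power(1e6, 0.05) == pytest.approx(1.0, abs=1e-12)


def test_power_matches_monte_carlo_noncentral_chisq():
    """Simulation oracle: draws of ncx2(2, lam) versus the closed-form tail."""
    lam, alpha, n = 10.0, 0.05, 10**6
    rng = np.random.default_rng(7)
    draws = stats.ncx2.rvs(2, lam, size=n, random_state=rng)
    crit = -2.0 * np.log(alpha)  # central chi2(2) quantile in closed form
    mc = (draws > crit).mean()
    se = np.sqrt(mc * (1 - mc) / n)
    assert power(lam, alpha) == pytest.approx(mc, abs=3 * se)


def test_power_monotone_in_noncentrality():
    lams = np.linspace(0, 40, 30)
    pows = [power(l, 0.05) for l in lams]
    assert np.all(np.diff(pows) > 0)


def test_derivative_zero_under_null():
    sc = Scenario(
        design=StudyDesign(1000, 2, 1, 0),
        confusion=ConfusionMatrix(0.7, 0.9),
        disease=DiseaseModel(m=0.2, k=0.05, rr_AA=1.0, mode="dominant"),
    )
    assert dlambda_dgamma_ca(sc) == pytest.approx(0.0, abs=1e-12)


def test_perfect_silver_cases_increase_power(reference_scenario):
    from dataclasses import replace

    sc = replace(reference_scenario, confusion=ConfusionMatrix(1.0, 1.0))
    assert dlambda_dgamma_ca(sc) > 0


def test_derivative_matches_finite_difference_on_random_scenarios():
    rng = np.random.default_rng(20240902)
    for sc in random_valid_scenarios(rng, 100):
        exact = dlambda_dgamma_ca(sc)
        fd = dlambda_dgamma_ca_fd(sc)
        assert exact == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_noncentrality_nondecreasing_in_ppv(reference_scenario):
    """Purer silver cases never hurt when they carry a real effect."""
    from dataclasses import replace

    lams = [
        scenario_noncentrality(
            replace(reference_scenario, confusion=ConfusionMatrix(phi, 1.0))
        )
        for phi in np.linspace(0.4, 1.0, 13)
    ]
    assert np.all(np.diff(lams) >= -1e-12)


@pytest.fixture(scope="module")
def region_base():
    return Scenario(
        design=StudyDesign(n_co=1000, r=1, gamma_ca=1, gamma_co=0),
        confusion=ConfusionMatrix(phi=0.7, theta=1.0),
        disease=DiseaseModel(m=0.3, k=0.05, rr_AA=2, mode="multiplicative"),
    )


def test_region_map_benefit_at_high_r_and_ppv(region_base):
    rmap = power_region_map(region_base, np.array([0.4, 1.0]), np.array([1.0, 4.0]))
    assert rmap.sign[1, 1] == 1  # phi=1, R=4: silver cases help
    assert rmap.sign[0, 0] == -1  # phi=0.4, R=1: silver cases hurt


def test_region_map_monotone_along_ppv(region_base):
    """No harmful region above a beneficial one at fixed R."""
    rmap = power_region_map(
        region_base, np.linspace(0.4, 1.0, 13), np.array([1.0, 2.0, 4.0])
    )
    for j in range(rmap.r_grid.size):
        col = rmap.sign[:, j]
        first_pos = np.argmax(col == 1) if (col == 1).any() else col.size
        assert (col[first_pos:] == 1).all()


def test_region_map_agrees_with_finite_difference(region_base):
    phis, rs = np.array([0.4, 0.6, 0.8, 1.0]), np.array([1.0, 2.0, 4.0])
    rmap = power_region_map(region_base, phis, rs)
    from dataclasses import replace

    for i, phi in enumerate(phis):
        for j, r in enumerate(rs):
            sc = replace(
                region_base,
                design=replace(region_base.design, r=float(r)),
                confusion=replace(region_base.confusion, phi=float(phi)),
            )
            assert rmap.sign[i, j] == np.sign(dlambda_dgamma_ca_fd(sc))
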