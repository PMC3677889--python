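import numpy as np
import pytest

from silverpower import (
    ConfusionMatrix,
    DiseaseModel,
    Scenario,
    StudyDesign,
    conditional_genotype_freqs,
    penetrance,
)
from silverpower.disease import MODES


def random_valid_scenarios(rng: np.random.Generator, n: int) -> list[Scenario]:
    """Physical scenarios drawn uniformly from realistic parameter ranges."""
    out = []
    while len(out) < n:
        model = DiseaseModel(
            m=rng.uniform(0.02, 0.5),
            k=rng.uniform(0.001, 0.3),
            rr_AA=rng.uniform(1.0, 9.0),
            mode=MODES[rng.integers(3)],
        )
        if penetrance(model).unphysical:
            continue
        out.append(
            Scenario(
                design=StudyDesign(
                    n_co=float(rng.integers(100, 5000)),
                    r=rng.uniform(0.5, 4.0),
                    gamma_ca=rng.uniform(0.0, 4.0),
                    gamma_co=rng.uniform(0.0, 4.0),
                ),
                confusion=ConfusionMatrix(
                    phi=rng.uniform(0.4, 1.0), theta=rng.uniform(0.4, 1.0)
                ),
                disease=model,
            )
        )
    return out


@pytest.fixture(scope="session")
def reference_scenario() -> Scenario:
    """A moderately powered blended design used across tests."""
    return Scenario(
        design=StudyDesign(n_co=1000, r=2, gamma_ca=1, gamma_co=0),
        confusion=ConfusionMatrix(phi=0.8, theta=1.0),
        disease=DiseaseModel(m=0.3, k=0.01, rr_AA=3, mode="multiplicative"),
    )


@pytest.fixture(scope="session")
def reference_freqs(reference_scenario):
    return conditional_genotype_freqs(reference_scenario.disease)
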