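import numpy as np
import pytest

from warfarin_pkpd import (
    GeneratorConfig,
    PKParameters,
    Patient,
    PopulationPrior,
    VisitRecord,
)


@pytest.fixture
def mean_params() -> PKParameters:
    """PK parameters at the study population means."""
    return PKParameters(c_max=5.8, k=1.0, cl=2.1, v_d=7.6, m=1.0)


@pytest.fixture
def default_prior() -> PopulationPrior:
    return PopulationPrior()


@pytest.fixture
def param_rng():
    """Draws random valid PK parameter sets around the population values."""
    rng = np.random.default_rng(20260923)

    def draw() -> PKParameters:
        return PKParameters(
            c_max=rng.uniform(4.5, 7.0),
            k=rng.uniform(0.7, 1.3),
            cl=rng.uniform(1.5, 2.7),
            v_d=rng.uniform(6.9, 8.3),
            m=1.0,
        )

    return draw


def make_visits(pid, times, inrs, doses, tau=24.0):
    return [
        VisitRecord(pid, t, i, d, tau) for t, i, d in zip(times, inrs, doses)
    ]


@pytest.fixture
def simple_patient():
    """Patient with a hand-checkable visit history."""
    visits = make_visits("A", [0.0, 10.0, 30.0], [1.5, 2.5, 2.5], [5.0, 5.0, 5.0])
    return Patient("A", age=70.0, sex="M", body_weight=70.0, visits=visits)


@pytest.fixture
def tiny_generator_config() -> GeneratorConfig:
    return GeneratorConfig(n_patients=10, seed=7)
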