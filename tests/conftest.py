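import numpy as np
import pytest

from pipkin import find_steady_state, load_network
from pipkin.experiments import ExperimentRunner
from pipkin.synthetic import reference_fixture


@pytest.fixture(scope="session")
def model():
    return load_network()


@pytest.fixture(scope="session")
def reference(model):
    return reference_fixture()


@pytest.fixture(scope="session")
def basal(model, reference):
    return find_steady_state(model, reference)


@pytest.fixture(scope="session")
def runner(model, reference):
    """Shared experiment runner (one basal solve for the whole session)."""
    return ExperimentRunner(params=reference, model=model)


@pytest.fixture()
def toy_cycle():
    """Two-species closed cycle A <-> B, first order, gamma*E forward = 2,
    backward = 1.  With A + B = 30 the analytic steady state is A = 10,
    B = 20 (balance: 2A = B)."""
    from pipkin.network import EnzymeGroup, FluxDef, PathwayModel, Species
    from pipkin.params import ParameterSet

    model = PathwayModel(
        species=[Species("A", "A", 30.0), Species("B", "B", 0.0)],
        fluxes=[
            FluxDef("vA->B", "phosphorylation", "A", "B", enzyme="EF"),
            FluxDef("vB->A", "hydrolysis", "B", "A", enzyme="EB"),
        ],
        enzymes=[EnzymeGroup("EF"), EnzymeGroup("EB")],
    )
    params = ParameterSet(
        gamma={"vA->B": 2.0, "vB->A": 1.0},
        f={"vA->B": 1.0, "vB->A": 1.0},
        enzyme_activity={"EF": 1.0, "EB": 1.0},
        influx_rate={}, efflux_rate_constant=0.0,
    )
    return model, params


def percent(ss, basal_ss, species):
    return 100.0 * ss[species] / basal_ss[species]


@pytest.fixture(scope="session")
def random_states():
    rng = np.random.default_rng(42)
    return [rng.uniform(0.5, 2.0, size=8) for _ in range(5)]
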