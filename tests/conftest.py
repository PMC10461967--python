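import numpy as np
import pytest

from ricp.artifact import ArtifactParameters
from ricp.models import ModelParameters
from ricp.protocol import ricp_protocol, ricp_timepoints
from ricp.trace import Trace


@pytest.fixture(scope="session")
def protocol():
    return ricp_protocol()


@pytest.fixture(scope="session")
def timepoints():
    return ricp_timepoints()


@pytest.fixture
def kernik():
    return ModelParameters(model_id="kernik")


@pytest.fixture
def paci():
    return ModelParameters(model_id="paci")


@pytest.fixture
def baseline_artifact():
    return ArtifactParameters()


def make_trace(t, v, units="mV"):
    return Trace(np.asarray(t, dtype=float), np.asarray(v, dtype=float),
                 units)


# ---- expensive shared simulations (built once per session) --------------

@pytest.fixture(scope="session")
def kernik_population_table():
    """n=150 Kernik population run through the full pipeline."""
    from ricp.population import (PopulationSpec, run_population,
                                 sample_population)
    spec = PopulationSpec(n=150, model_id="kernik", seed=11)
    return run_population(sample_population(spec))


@pytest.fixture(scope="session")
def paci_population_table():
    """n=150 Paci population run through the full pipeline."""
    from ricp.population import (PopulationSpec, run_population,
                                 sample_population)
    spec = PopulationSpec(n=150, model_id="paci", seed=11)
    return run_population(sample_population(spec))


@pytest.fixture(scope="session")
def default_cohort():
    """Default 39-cell synthetic cohort."""
    from ricp.cohort import CohortSpec, generate_cohort
    return generate_cohort(CohortSpec(n_cells=39, seed=3))
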