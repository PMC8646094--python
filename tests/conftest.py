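import numpy as np
import pytest

from icgsim.model import DoseProtocol, Individual, INFUSION_PROTOCOL, simulate
from icgsim.pk import compute_pk


@pytest.fixture(scope="session")
def reference_individual():
    return Individual()


@pytest.fixture(scope="session")
def reference_bolus_tc(reference_individual):
    """Reference healthy individual, 0.5 mg/kg bolus."""
    return simulate(reference_individual, DoseProtocol(mode="bolus", bolus_dose=0.5))


@pytest.fixture(scope="session")
def reference_bolus_pk(reference_bolus_tc):
    return compute_pk(reference_bolus_tc)


@pytest.fixture(scope="session")
def reference_infusion_tc(reference_individual):
    """Reference individual under the default constant-infusion protocol."""
    return simulate(reference_individual, INFUSION_PROTOCOL)
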