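import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._expected as _expected

from rheumcca import (
    CostConsequenceModel,
    Subgroup,
    default_safety_fixture,
    generate_resource_use,
    table1_fixture,
    table2_fixture,
)
from rheumcca.synthetic_inputs import SyntheticScenario


@pytest.fixture(scope="session")
def clinical():
    return table1_fixture()


@pytest.fixture(scope="session")
def safety():
    return default_safety_fixture()


@pytest.fixture(scope="session")
def de_costs():
    return table2_fixture("DE")


@pytest.fixture(scope="session")
def de_resource_use():
    return generate_resource_use(SyntheticScenario(seed=0), country="DE")


@pytest.fixture
def model_factory():
    def make(country="DE", subgroup=Subgroup.Q4, **config):
        return CostConsequenceModel.from_fixtures(country, subgroup, **config)

    return make
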