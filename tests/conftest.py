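import logging

import pytest

from cbakit.core_model import MediumCondition, apply_medium, build_catalog, load_pathway_catalog
from cbakit.fixtures import generate_toy_fixture
from cbakit.solvers import optimize_pfba

# the waste rules intentionally reference ids absent from the core model
logging.getLogger("cbakit.cba").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def pathways():
    return load_pathway_catalog()


@pytest.fixture(scope="session")
def wt_aerobic(catalog):
    return apply_medium(catalog["WT"], MediumCondition.aerobic())


@pytest.fixture(scope="session")
def wt_aerobic_solution(wt_aerobic):
    return optimize_pfba(wt_aerobic)


@pytest.fixture(scope="session")
def aerobic_models(catalog, pathways):
    medium = MediumCondition.aerobic()
    return {name: apply_medium(catalog[name], medium) for name in pathways}


@pytest.fixture(scope="session")
def aerobic_solutions(aerobic_models):
    return {name: optimize_pfba(model) for name, model in aerobic_models.items()}


@pytest.fixture(scope="session")
def toy():
    return generate_toy_fixture(seed=0)
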