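import pytest

from emforce.ensemble import EnsembleModel
from emforce.must import find_must_single
from emforce.synth import (
    ground_truth,
    toy_branch,
    toy_branch_condition,
    toy_branch_mechanisms,
)


@pytest.fixture(scope="session")
def toy():
    """(network, partition, reference) of the canonical branched fixture."""
    return toy_branch()


@pytest.fixture(scope="session")
def toy_condition():
    return toy_branch_condition()


@pytest.fixture(scope="session")
def toy_mechanisms():
    return toy_branch_mechanisms()


@pytest.fixture(scope="session")
def toy_model(toy, toy_mechanisms):
    network, part, reference = toy
    return EnsembleModel(network, part, toy_mechanisms, reference)


@pytest.fixture(scope="session")
def toy_truth(toy, toy_mechanisms):
    network, part, reference = toy
    return ground_truth(network, part, toy_mechanisms, reference, seed=0)


@pytest.fixture(scope="session")
def toy_must(toy, toy_condition):
    network, part, reference = toy
    return find_must_single(network, part, reference, toy_condition)
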