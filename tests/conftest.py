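import numpy as np
import pytest

from seqdta import protein_dictionary, smiles_dictionary


@pytest.fixture(scope="session")
def protein_dict():
    return protein_dictionary()


@pytest.fixture(scope="session")
def smiles_dict():
    return smiles_dictionary()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# Expensive trained-model studies are shared session-wide so the learning
# property tests and the acceptance tests run them once.

@pytest.fixture(scope="session")
def overfit_result():
    from seqdta.experiments import overfit_study
    return overfit_study(seed=0)


@pytest.fixture(scope="session")
def generalization_result():
    from seqdta.experiments import generalization_study
    return generalization_study(seed=0)


@pytest.fixture(scope="session")
def pocket_advantage_result():
    from seqdta.experiments import pocket_advantage_study
    return pocket_advantage_study(seed=0)
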