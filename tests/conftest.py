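import pytest

import thioscreen as ts


@pytest.fixture(scope="session")
def bondlengths():
    return ts.bundled_fixture("bondlengths_tu")


@pytest.fixture(scope="session")
def reactivity_inputs():
    return ts.bundled_fixture("reactivity_inputs")


@pytest.fixture(scope="session")
def energies_dipoles():
    return ts.bundled_fixture("energies_dipoles")


@pytest.fixture(scope="session")
def physchem():
    return ts.bundled_fixture("physchem")


@pytest.fixture(scope="session")
def activities():
    return ts.bundled_fixture("activities")


@pytest.fixture(scope="session")
def docking_alpha():
    return ts.bundled_fixture("docking_alpha")


@pytest.fixture(scope="session")
def docking_beta():
    return ts.bundled_fixture("docking_beta")


@pytest.fixture(scope="session")
def descriptors_aqueous(reactivity_inputs):
    return ts.descriptor_table(reactivity_inputs, phase="aqueous")


@pytest.fixture(scope="session")
def descriptors_gas(reactivity_inputs):
    return ts.descriptor_table(reactivity_inputs, phase="gas")
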