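import pytest

from sharenet import ModelParams, fixture_fig1, fixture_star_d1


@pytest.fixture(scope="session")
def fig1():
    return fixture_fig1()


@pytest.fixture(scope="session")
def star_d1():
    return fixture_star_d1()


@pytest.fixture(scope="session")
def fig1_params():
    return ModelParams(ph=0.2, F=4)


# All Table-style expected eating probabilities for the 7-node worked example
# at ph=0.2, keyed by F.  Node order 0..6.
FIG1_EXPECTED = {
    2: (0.2, 0.1, 0.0, 0.1, 0.2, 0.2, 0.0),
    3: (0.2, 0.2, 0.1, 0.1, 0.2, 0.2, 0.2),
    4: (0.2, 0.36, 0.2, 0.2, 0.2, 0.2, 0.2),
    5: (0.2, 0.36, 0.36, 0.2, 0.2, 0.2, 0.2),
}


@pytest.fixture(scope="session")
def fig1_expected():
    return FIG1_EXPECTED
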