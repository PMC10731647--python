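import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from chelatherm.speciation import ComplexSpecies, ProtolysisScheme

#: four-step ladder used throughout: carboxyl pair then amine pair
LADDER = (2.40, 3.13, 6.80, 7.73)


@pytest.fixture(scope="session")
def scheme():
    return ProtolysisScheme(LADDER)


@pytest.fixture(scope="session")
def aprotic():
    return ProtolysisScheme([])


@pytest.fixture(scope="session")
def ml_species():
    return ComplexSpecies(m=1, l=1, log_beta=13.0, label="ML")
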