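import numpy as np
import pytest

from peptigrid.fixtures import FixtureSpec, generate_mini_groove
from peptigrid.forcefield import default_params
from peptigrid.pipeline import prepare_receptor
from peptigrid.structure_io import peptide_conformation, receptor_atom_set


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def groove():
    """The packaged default mini-groove complex and its ground truth."""
    return generate_mini_groove(FixtureSpec())


@pytest.fixture(scope="session")
def groove_complex(groove):
    return groove[0]


@pytest.fixture(scope="session")
def native(groove_complex):
    """The native bound peptide conformation of the default fixture."""
    return peptide_conformation(groove_complex)


@pytest.fixture(scope="session")
def receptor(groove_complex):
    return receptor_atom_set(groove_complex)


@pytest.fixture(scope="session")
def workspace(groove_complex):
    """Docking workspace (box, binding site, grid maps) for the fixture."""
    return prepare_receptor(groove_complex)


@pytest.fixture()
def rng():
    return np.random.default_rng(20100301)
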