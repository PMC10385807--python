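import numpy as np
import pytest

from opmsss import build_basis, make_helmet_array


@pytest.fixture(scope="session")
def helmet():
    """The default 64-sensor (192-channel) synthetic triaxial helmet."""
    return make_helmet_array()


@pytest.fixture(scope="session")
def full_basis(helmet):
    """Basis at the highest truncation orders used anywhere (L_in=11, L_out=5);
    lower-order bases are column slices of this one."""
    return build_basis(helmet, 11, 5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
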