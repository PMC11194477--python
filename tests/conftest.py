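import numpy as np
import pytest

from mcassembly.fixtures import ComplexSpec, make_complex
from mcassembly.structures import ChainModel


def make_chain(ca, entity="A", chain_id="A", plddt=0.9, cb=None, seq=None):
    """Small helper: a ChainModel from bare CA coordinates."""
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    if cb is None:
        cb = ca
    if seq is None:
        seq = "A" * n
    if np.isscalar(plddt):
        plddt = np.full(n, float(plddt))
    return ChainModel(chain_id, entity, seq, ca, np.asarray(cb, float), plddt)


@pytest.fixture(scope="session")
def c6_reference():
    return make_complex(ComplexSpec(symmetry="cyclic", n_units=6))


@pytest.fixture(scope="session")
def c3_reference():
    return make_complex(ComplexSpec(symmetry="cyclic", n_units=3))


@pytest.fixture(scope="session")
def d3_hetero_reference():
    # dihedral with a two-entity asymmetric unit: 12 chains, A6B6
    return make_complex(
        ComplexSpec(symmetry="dihedral", n_units=3, entities=("A", "B"))
    )
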