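import numpy as np
import pytest

from memsalt.core_model import Frame, Topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simple_topology(tags_per_atom, charges=None, mol_ids=None, leaflet=None):
    """Build a minimal Topology from a list of tag-sets."""
    n = len(tags_per_atom)
    return Topology(
        atom_name=np.array(["X"] * n, dtype=object),
        atom_type=np.array(["X"] * n, dtype=object),
        charge=np.zeros(n) if charges is None else np.asarray(charges, float),
        mol_id=np.arange(n) if mol_ids is None else np.asarray(mol_ids, int),
        tags=[set(t) for t in tags_per_atom],
        leaflet=leaflet,
    )


@pytest.fixture
def make_topology():
    return simple_topology


@pytest.fixture
def make_frame():
    def _make(coords, box=(10.0, 10.0, 10.0), time=0.0):
        return Frame(time=time, coords=np.asarray(coords, float),
                     box=np.asarray(box, float))

    return _make
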