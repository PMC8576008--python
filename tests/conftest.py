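import numpy as np
import pytest
import biotite.structure as struc

from cellufacet.crystal import GlucoseTemplate, UnitCell, assemble_nanocrystal


@pytest.fixture(scope="session")
def cell():
    return UnitCell()


@pytest.fixture(scope="session")
def template():
    return GlucoseTemplate.ideal()


@pytest.fixture(scope="session")
def model_3o4():
    return assemble_nanocrystal(3, 4, "O")


@pytest.fixture(scope="session")
def model_3a4():
    return assemble_nanocrystal(3, 4, "A")


@pytest.fixture(scope="session")
def model_6o12():
    return assemble_nanocrystal(6, 12, "O")


@pytest.fixture(scope="session")
def model_6a12():
    return assemble_nanocrystal(6, 12, "A")


@pytest.fixture(scope="session")
def model_6b12():
    return assemble_nanocrystal(6, 12, "B")


def make_frame(atoms_spec):
    """AtomArray from [(chain_index, res_id, atom_name, (x, y, z)), ...]."""
    n = len(atoms_spec)
    arr = struc.AtomArray(n)
    arr.coord = np.array([s[3] for s in atoms_spec], dtype=float)
    arr.chain_id = np.array([chr(ord("A") + s[0]) for s in atoms_spec])
    arr.res_id = np.array([s[1] for s in atoms_spec])
    arr.atom_name = np.array([s[2] for s in atoms_spec])
    arr.res_name = np.full(n, "BGC")
    arr.element = np.array([s[2].strip("0123456789")[0] for s in atoms_spec])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("chain_index", np.array([s[0] for s in atoms_spec], dtype=int))
    return arr


@pytest.fixture
def frame_factory():
    return make_frame
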