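import numpy as np
import pytest

from cryoligid import AtomRecord, DensityMap, MolecularModel

PDB_FIXTURE = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.759   7.092  -4.960  1.00 10.00           C
"""


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cube_map(rng):
    """8^3 map, 1 A voxels, origin at the world origin."""
    return DensityMap(rng.normal(size=(8, 8, 8)), voxel_size=1.0, origin=(0, 0, 0))


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(PDB_FIXTURE)
    return path


def chain(coords, chain_id="A", start_res=1, atom_name="CA", element="C",
          res_step=1):
    """Helper: one pseudo-residue per coordinate with sequential numbering."""
    return [
        AtomRecord(element=element, position=tuple(pos), chain_id=chain_id,
                   residue_index=start_res + i * res_step, residue_name="ALA",
                   atom_name=atom_name)
        for i, pos in enumerate(coords)
    ]


@pytest.fixture
def straight_chain_model():
    coords = [(3.8 * i, 0.0, 0.0) for i in range(10)]
    return MolecularModel(chain(coords))
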