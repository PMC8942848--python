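import numpy as np
import pytest

from dimerstate.model import StructureModel


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.750   7.092  -4.937  1.00 10.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


def build_model(atoms, protomer_map=None, source_id="fixture"):
    """Build a StructureModel from (chain, res_id, res_name, atom_name, element, xyz[, hetero])."""
    rows = [list(a) + [False] * (7 - len(a)) for a in atoms]
    return StructureModel(
        chain_ids=[r[0] for r in rows],
        res_ids=[r[1] for r in rows],
        ins_codes=[""] * len(rows),
        res_names=[r[2] for r in rows],
        atom_names=[r[3] for r in rows],
        elements=[r[4] for r in rows],
        coords=np.array([r[5] for r in rows], float),
        hetero=[r[6] for r in rows],
        protomer_map=protomer_map,
        source_id=source_id,
    )


@pytest.fixture
def build():
    return build_model


@pytest.fixture
def toy_dimer():
    from dimerstate.synthetic import PlantedTransform, SyntheticSpec, make_toy_dimer_states

    spec = SyntheticSpec(
        n_residues=30,
        transforms=[PlantedTransform("S", 10, 20, translation=(6.0, 0.0, 0.0))],
    )
    return make_toy_dimer_states(spec)


def random_rigid_transform(rng):
    from dimerstate.geometry import rotation_about_axis

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return rotation_about_axis(axis, rng.uniform(0, 360)), rng.uniform(-20, 20, 3)


@pytest.fixture
def rigid_transform():
    return random_rigid_transform
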