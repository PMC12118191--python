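import numpy as np
import pytest

from koffkit.complex_io import AtomRecord, ParameterizedComplex, ResidueGroup
from koffkit.energetics import EnergeticsConfig, build_matrix
from koffkit.synthetic import SyntheticSpec, make_toy_complexes


def make_atom(
    name="C1",
    element="C",
    position=(0.0, 0.0, 0.0),
    charge=0.0,
    rmin_half=1.9,
    epsilon=0.1,
    residue_index=0,
    role="protein",
):
    return AtomRecord(
        atom_name=name,
        element=element,
        position=np.asarray(position, dtype=float),
        charge=charge,
        lj_rmin_half=rmin_half,
        lj_epsilon=epsilon,
        residue_index=residue_index,
        molecule_role=role,
    )


@pytest.fixture
def two_residue_complex():
    """1 ligand atom facing 2 single-atom residues; simplest decomposition case."""
    res0 = ResidueGroup("ALA1", [make_atom("CA", position=(0, 0, 0), charge=0.3)])
    res1 = ResidueGroup(
        "GLY2", [make_atom("CB", position=(4, 0, 0), charge=-0.2, residue_index=1)]
    )
    lig = [make_atom("L1", position=(2, 3, 0), charge=-0.5, role="ligand")]
    return ParameterizedComplex("toy", [res0, res1], lig)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_ligands=12, n_residues=3, atoms_per_residue=2, atoms_per_ligand=3, seed=11)


@pytest.fixture(scope="session")
def small_complexes(small_spec):
    return make_toy_complexes(small_spec)


@pytest.fixture(scope="session")
def small_matrix(small_complexes):
    return build_matrix(small_complexes, EnergeticsConfig())
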