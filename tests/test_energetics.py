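import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_atom
from koffkit.energetics import (
    COULOMB_CONSTANT,
    EnergeticsConfig,
    EnergeticsError,
    build_matrix,
    pair_energy_elec,
    pair_energy_vdw,
    residue_energies,
)
from koffkit.synthetic import SyntheticSpec, make_toy_complexes


def brute_force_total(complex_, cfg):
    """Independent all-pairs double loop over intermolecular pairs."""
    total = 0.0
    for lig in complex_.ligand_atoms:
        for prot in complex_.protein_atoms():
            r = float(np.linalg.norm(lig.position - prot.position))
            if cfg.cutoff is not None and r > cfg.cutoff:
                continue
            eps = (lig.lj_epsilon * prot.lj_epsilon) ** 0.5
            rmin = lig.lj_rmin_half + prot.lj_rmin_half
            total += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            total += cfg.coulomb_constant * lig.charge * prot.charge / (cfg.dielectric * r)
    return total


class TestPairVdw:
    def test_well_depth_at_rmin(self):
        a = make_atom(epsilon=0.1, rmin_half=1.9)
        b = make_atom(epsilon=0.1, rmin_half=1.9)
        assert pair_energy_vdw(a, b, 3.8) == pytest.approx(-0.1, abs=1e-12)

    def test_decay_at_long_range(self):
        a = make_atom(epsilon=0.1, rmin_half=1.9)
        assert abs(pair_energy_vdw(a, a, 38.0)) < 1e-5

    def test_zero_epsilon(self):
        a = make_atom(epsilon=0.0)
        b = make_atom(epsilon=0.25)
        for r in (0.5, 2.0, 10.0):
            assert pair_energy_vdw(a, b, r) == 0.0

    def test_invalid_distance(self):
        a = make_atom()
        with pytest.raises(EnergeticsError):
            pair_energy_vdw(a, a, 0.0)
        with pytest.raises(EnergeticsError):
            pair_energy_vdw(a, a, -1.0)


class TestPairElec:
    def test_closed_form_example(self):
        # k_e * (0.5 * -0.5) / (4 * 4) = -5.1883 kcal/mol
        a = make_atom(charge=0.5)
        b = make_atom(charge=-0.5)
        cfg = EnergeticsConfig(dielectric=4.0)
        assert pair_energy_elec(a, b, 4.0, cfg) == pytest.approx(-5.1883, abs=1e-4)
        assert pair_energy_elec(a, b, 4.0, cfg) == pytest.approx(
            COULOMB_CONSTANT * -0.25 / 16.0, rel=1e-12
        )

    def test_zero_charge(self):
        assert pair_energy_elec(make_atom(charge=0.0), make_atom(charge=0.7), 3.0) == 0.0

    def test_like_charges_positive(self):
        assert pair_energy_elec(make_atom(charge=0.4), make_atom(charge=0.4), 3.0) > 0
        assert pair_energy_elec(make_atom(charge=-0.4), make_atom(charge=-0.4), 3.0) > 0

    @given(
        q1=st.floats(-1, 1), q2=st.floats(-1, 1),
        r=st.floats(0.5, 20), scale=st.floats(1.5, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_dielectric_scaling(self, q1, q2, r, scale):
        a, b = make_atom(charge=q1), make_atom(charge=q2)
        base = pair_energy_elec(a, b, r, EnergeticsConfig(dielectric=4.0))
        scaled = pair_energy_elec(a, b, r, EnergeticsConfig(dielectric=4.0 * scale))
        assert scaled * scale == pytest.approx(base, rel=1e-12, abs=1e-12)

    @given(
        q1=st.floats(-1, 1), q2=st.floats(-1, 1),
        e1=st.floats(0.01, 0.3), e2=st.floats(0.01, 0.3),
        r=st.floats(0.8, 15),
    )
    @settings(max_examples=50, deadline=None)
    def test_pair_symmetry(self, q1, q2, e1, e2, r):
        a = make_atom(charge=q1, epsilon=e1, rmin_half=1.7)
        b = make_atom(charge=q2, epsilon=e2, rmin_half=2.0)
        assert pair_energy_vdw(a, b, r) == pair_energy_vdw(b, a, r)
        assert pair_energy_elec(a, b, r) == pair_energy_elec(b, a, r)


class TestResidueEnergies:
    def test_two_pair_decomposition(self, two_residue_complex):
        cfg = EnergeticsConfig()
        res = residue_energies(two_residue_complex, cfg)
        assert res.n_residues == 2
        lig = two_residue_complex.ligand_atoms[0]
        for k, group in enumerate(two_residue_complex.protein_residues):
            prot = group.atoms[0]
            r = float(np.linalg.norm(lig.position - prot.position))
            assert res.e_vdw[k] == pytest.approx(pair_energy_vdw(lig, prot, r), rel=1e-12)
            assert res.e_elec[k] == pytest.approx(pair_energy_elec(lig, prot, r, cfg), rel=1e-12)

    def test_charge_linearity(self, two_residue_complex):
        cfg = EnergeticsConfig()
        base = residue_energies(two_residue_complex, cfg)
        for atom in two_residue_complex.ligand_atoms:
            atom.charge *= 2.0
        doubled = residue_energies(two_residue_complex, cfg)
        assert np.allclose(doubled.e_elec, 2.0 * base.e_elec, rtol=1e-12)
        assert np.allclose(doubled.e_vdw, base.e_vdw, rtol=1e-12)

    def test_brute_force_oracle_random_fixture(self):
        spec = SyntheticSpec(
            n_ligands=1, n_residues=4, atoms_per_residue=4, atoms_per_ligand=4, seed=20
        )
        cx = make_toy_complexes(spec)[0]
        assert sum(len(g.atoms) for g in cx.protein_residues) + len(cx.ligand_atoms) == 20
        cfg = EnergeticsConfig()
        res = residue_energies(cx, cfg)
        total = float(np.sum(res.e_vdw) + np.sum(res.e_elec))
        assert total == pytest.approx(brute_force_total(cx, cfg), rel=1e-9)

    def test_cutoff_matches_filtered_brute_force(self):
        spec = SyntheticSpec(n_ligands=1, n_residues=3, atoms_per_residue=3, seed=21)
        cx = make_toy_complexes(spec)[0]
        cfg = EnergeticsConfig(cutoff=6.0)
        res = residue_energies(cx, cfg)
        total = float(np.sum(res.e_vdw) + np.sum(res.e_elec))
        assert total == pytest.approx(brute_force_total(cx, cfg), rel=1e-9)

    def test_coincident_atoms_error_names_pair(self, two_residue_complex):
        two_residue_complex.ligand_atoms[0].position = np.array([0.0, 0.0, 0.0])
        with pytest.raises(EnergeticsError, match="L1"):
            residue_energies(two_residue_complex)

    def test_rigid_motion_invariance(self):
        spec = SyntheticSpec(n_ligands=1, n_residues=3, seed=22)
        cx = make_toy_complexes(spec)[0]
        cfg = EnergeticsConfig()
        before = residue_energies(cx, cfg)
        # rotate about z by 35 degrees, then translate
        theta = np.deg2rad(35.0)
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shift = np.array([3.0, -7.0, 11.0])
        for atom in list(cx.protein_atoms()) + cx.ligand_atoms:
            atom.position = rot @ atom.position + shift
        after = residue_energies(cx, cfg)
        assert np.max(np.abs(after.e_vdw - before.e_vdw)) < 1e-8
        assert np.max(np.abs(after.e_elec - before.e_elec)) < 1e-8


class TestBuildMatrix:
    def test_shape(self):
        spec = SyntheticSpec(n_ligands=3, n_residues=4, seed=23)
        X = build_matrix(make_toy_complexes(spec))
        assert X.shape == (3, 8)
        assert X.columns[:4] == [f"vdw_RES{i}" for i in range(1, 5)]
        assert X.columns[4:] == [f"elec_RES{i}" for i in range(1, 5)]

    def test_single_complex_row_equals_energies(self, small_complexes):
        cx = small_complexes[0]
        X = build_matrix([cx])
        assert X.shape == (1, 2 * cx.n_residues)
        assert np.allclose(X.values[0], residue_energies(cx).concatenated(), rtol=1e-12)

    def test_row_order_follows_input(self, small_complexes):
        forward = build_matrix(small_complexes[:4])
        reversed_ = build_matrix(small_complexes[:4][::-1])
        assert np.allclose(forward.values, reversed_.values[::-1], rtol=1e-12)
        assert forward.complex_ids == reversed_.complex_ids[::-1]

    def test_inconsistent_residues_error(self, small_complexes):
        import copy

        other = copy.deepcopy(small_complexes[1])
        other.protein_residues[0].label = "XXX9"
        with pytest.raises(EnergeticsError, match="XXX9"):
            build_matrix([small_complexes[0], other])


def test_decomposition_conservation_property(small_complexes):
    cfg = EnergeticsConfig()
    for cx in small_complexes:
        res = residue_energies(cx, cfg)
        total = float(np.sum(res.e_vdw) + np.sum(res.e_elec))
        assert total == pytest.approx(brute_force_total(cx, cfg), rel=1e-9)
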