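"""Per-residue ligand-protein interaction energies and X-matrix assembly.

The total intermolecular nonbonded energy of a complex is decomposed into
per-residue van der Waals and electrostatic terms: the vdW pair energy uses
the AMBER-style Lennard-Jones Rmin/epsilon form with Lorentz-Berthelot
combining (arithmetic Rmin, geometric epsilon), and the electrostatic pair
energy is a Coulomb term screened by a uniform dielectric constant
(default 4).  Only ligand x protein pairs contribute; there are no
intramolecular terms and no 1-4 scaling.

Descriptor rows are ``[E_1^vdW .. E_np^vdW | E_1^elec .. E_np^elec]`` in
residue order, stacked over complexes into an N x 2*n_p matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from koffkit.complex_io import AtomRecord, ParameterizedComplex

__all__ = [
    "COULOMB_CONSTANT",
    "EnergeticsConfig",
    "EnergeticsError",
    "InteractionEnergyMatrix",
    "ResidueEnergies",
    "build_matrix",
    "pair_energy_elec",
    "pair_energy_vdw",
    "residue_energies",
]

#: AMBER electrostatic conversion factor, kcal*Angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.0522173


class EnergeticsError(ValueError):
    """Raised for invalid geometry or inconsistent complex sets."""


@dataclass
class EnergeticsConfig:
    """Settings for the pairwise nonbonded energy model.

    ``cutoff`` (Angstrom) truncates pair sums; the default (None) keeps every
    intermolecular pair, matching full COMBINE-style sums.
    """

    dielectric: float = 4.0
    coulomb_constant: float = COULOMB_CONSTANT
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.dielectric > 0:
            raise EnergeticsError("dielectric must be > 0")
        if not self.coulomb_constant > 0:
            raise EnergeticsError("coulomb_constant must be > 0")
        if self.cutoff is not None and not self.cutoff > 0:
            raise EnergeticsError("cutoff must be > 0 when given")


@dataclass
class ResidueEnergies:
    """Per-residue interaction energies of one complex (kcal/mol)."""

    complex_id: str
    e_vdw: np.ndarray
    e_elec: np.ndarray

    def __post_init__(self) -> None:
        self.e_vdw = np.asarray(self.e_vdw, dtype=float)
        self.e_elec = np.asarray(self.e_elec, dtype=float)
        if self.e_vdw.shape != self.e_elec.shape or self.e_vdw.ndim != 1:
            raise EnergeticsError(f"{self.complex_id}: e_vdw/e_elec must be 1-D, same length")
        if not (np.all(np.isfinite(self.e_vdw)) and np.all(np.isfinite(self.e_elec))):
            raise EnergeticsError(f"{self.complex_id}: non-finite residue energy")

    @property
    def n_residues(self) -> int:
        return self.e_vdw.shape[0]

    def concatenated(self) -> np.ndarray:
        """Row ``[e_vdw | e_elec]`` as used in the descriptor matrix."""
        return np.concatenate([self.e_vdw, self.e_elec])


@dataclass
class InteractionEnergyMatrix:
    """N x 2*n_p descriptor matrix: vdW block then electrostatic block."""

    complex_ids: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise EnergeticsError("matrix values must be 2-D")
        if self.values.shape != (len(self.complex_ids), len(self.columns)):
            raise EnergeticsError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.complex_ids)} ids x {len(self.columns)} columns"
            )
        if len(set(self.columns)) != len(self.columns):
            raise EnergeticsError("matrix column labels must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_residues(self) -> int:
        return len(self.columns) // 2


def pair_energy_vdw(atom_i: AtomRecord, atom_j: AtomRecord, r: float) -> float:
    """Lennard-Jones pair energy eps_ij*[(Rmin_ij/r)^12 - 2*(Rmin_ij/r)^6].

    Rmin_ij is the sum of the per-atom Rmin/2 values; eps_ij is the geometric
    mean of the well depths.  Minimum of -eps_ij at r = Rmin_ij.
    """
    if not r > 0:
        raise EnergeticsError(f"pair distance must be > 0, got {r}")
    eps = np.sqrt(atom_i.lj_epsilon * atom_j.lj_epsilon)
    if eps == 0.0:
        return 0.0
    rmin = atom_i.lj_rmin_half + atom_j.lj_rmin_half
    s6 = (rmin / r) ** 6
    return float(eps * (s6 * s6 - 2.0 * s6))


def pair_energy_elec(
    atom_i: AtomRecord, atom_j: AtomRecord, r: float, cfg: EnergeticsConfig | None = None
) -> float:
    """Coulomb pair energy k_e*q_i*q_j/(eps_r*r) with a uniform dielectric."""
    cfg = cfg if cfg is not None else EnergeticsConfig()
    if not r > 0:
        raise EnergeticsError(f"pair distance must be > 0, got {r}")
    # group the charge product first so the energy is bitwise symmetric in i, j
    return float(cfg.coulomb_constant * (atom_i.charge * atom_j.charge) / (cfg.dielectric * r))


def _arrays(atoms: Sequence[AtomRecord]):
    pos = np.array([a.position for a in atoms], dtype=float)
    q = np.array([a.charge for a in atoms], dtype=float)
    rmin_half = np.array([a.lj_rmin_half for a in atoms], dtype=float)
    eps = np.array([a.lj_epsilon for a in atoms], dtype=float)
    return pos, q, rmin_half, eps


def residue_energies(
    complex_: ParameterizedComplex, cfg: EnergeticsConfig | None = None
) -> ResidueEnergies:
    """Decompose the ligand-protein nonbonded energy into per-residue terms.

    For residue k, ``e_vdw[k]`` (resp. ``e_elec[k]``) sums the pairwise vdW
    (resp. electrostatic) energies over every (ligand atom, residue-k atom)
    pair.  Summing both vectors over k reproduces the brute-force total over
    all intermolecular pairs.  Coincident atoms (r = 0) are a hard error
    naming the offending pair.
    """
    cfg = cfg if cfg is not None else EnergeticsConfig()
    lig_pos, lig_q, lig_rh, lig_eps = _arrays(complex_.ligand_atoms)

    n_p = complex_.n_residues
    e_vdw = np.zeros(n_p)
    e_elec = np.zeros(n_p)
    for k, group in enumerate(complex_.protein_residues):
        res_pos, res_q, res_rh, res_eps = _arrays(group.atoms)
        diff = lig_pos[:, None, :] - res_pos[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        if np.any(r == 0.0):
            li, ri = np.argwhere(r == 0.0)[0]
            raise EnergeticsError(
                f"{complex_.complex_id}: coincident atoms, ligand "
                f"{complex_.ligand_atoms[li].atom_name} and residue {group.label} "
                f"atom {group.atoms[ri].atom_name} (r = 0)"
            )
        mask = np.ones_like(r, dtype=bool)
        if cfg.cutoff is not None:
            mask = r <= cfg.cutoff

        eps_ij = np.sqrt(lig_eps[:, None] * res_eps[None, :])
        rmin_ij = lig_rh[:, None] + res_rh[None, :]
        s6 = (rmin_ij / r) ** 6
        e_vdw[k] = np.sum((eps_ij * (s6 * s6 - 2.0 * s6))[mask])

        qq = lig_q[:, None] * res_q[None, :]
        e_elec[k] = np.sum((cfg.coulomb_constant * qq / (cfg.dielectric * r))[mask])
    return ResidueEnergies(complex_.complex_id, e_vdw, e_elec)


def build_matrix(
    complexes: Sequence[ParameterizedComplex], cfg: EnergeticsConfig | None = None
) -> InteractionEnergyMatrix:
    """Stack per-complex residue-energy rows into the descriptor matrix.

    All complexes must share the same protein residue sequence (count and
    labels); the row order follows the input list.
    """
    if not complexes:
        raise EnergeticsError("no complexes given")
    cfg = cfg if cfg is not None else EnergeticsConfig()
    labels = complexes[0].residue_labels
    for c in complexes[1:]:
        if c.residue_labels != labels:
            raise EnergeticsError(
                f"inconsistent residue sets: {complexes[0].complex_id} has {labels}, "
                f"{c.complex_id} has {c.residue_labels}"
            )
    rows = [residue_energies(c, cfg).concatenated() for c in complexes]
    columns = [f"vdw_{lab}" for lab in labels] + [f"elec_{lab}" for lab in labels]
    return InteractionEnergyMatrix(
        complex_ids=[c.complex_id for c in complexes],
        columns=columns,
        values=np.vstack(rows),
    )
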