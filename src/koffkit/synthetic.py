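"""Synthetic fixtures: toy parameterized complexes and planted pkoff labels.

One shared protein scaffold (same residues and labels across all ligands,
as build_matrix requires) is decorated with per-complex random ligands whose
atoms sit within interaction distance of the protein but never clash.
Labels are planted as a (optionally tanh-squashed) linear function of the
interaction-energy descriptors plus Gaussian noise, with an optional
correlated pKd for BEP-fit tests.

No attempt is made to mimic real chemistry or force-field realism; the
point is statistical structure the pipeline can be validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from koffkit.complex_io import (
    AtomRecord,
    KineticDataset,
    KineticEntry,
    ParameterizedComplex,
    ResidueGroup,
)

__all__ = ["SyntheticError", "SyntheticSpec", "make_toy_complexes", "plant_pkoff", "simulate_dataset"]

_ELEMENTS = ("C", "N", "O")
_MIN_SEPARATION = 1.5  # Angstrom, hard floor on any interatomic distance
_MAX_PLACEMENT_TRIES = 500


class SyntheticError(RuntimeError):
    pass


@dataclass
class SyntheticSpec:
    n_ligands: int = 20
    n_residues: int = 4
    atoms_per_residue: int = 3
    atoms_per_ligand: int = 4
    coordinate_scale: float = 1.2  # jitter half-width, Angstrom
    charge_scale: float = 0.5  # |q| upper bound (clipped at 1 e)
    planted_weights: np.ndarray | None = None  # over descriptor columns; None -> N(0,1)
    noise_sd: float = 0.3  # pkoff units
    nonlinearity: str = "none"  # none | tanh
    seed: int = 0
    # label placement and the optional correlated pKd channel
    label_center: float = 2.0
    label_scale: float = 1.0
    include_pkd: bool = False
    bep_alpha: float = 0.8
    bep_beta: float = 0.5
    pkd_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_ligands", "n_residues", "atoms_per_residue", "atoms_per_ligand"):
            if getattr(self, name) < 1:
                raise SyntheticError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.pkd_noise_sd < 0:
            raise SyntheticError("noise standard deviations must be >= 0")
        if self.nonlinearity not in ("none", "tanh"):
            raise SyntheticError(f"unknown nonlinearity {self.nonlinearity!r}")


def _place(
    rng: np.random.Generator,
    center: np.ndarray,
    half_width: float,
    obstacles: list[np.ndarray],
    min_dist: float,
    far_check: tuple[np.ndarray, float, float] | None = None,
) -> np.ndarray:
    """Rejection-sample a point near ``center`` respecting distance constraints."""
    for _ in range(_MAX_PLACEMENT_TRIES):
        pos = center + rng.uniform(-half_width, half_width, size=3)
        if obstacles:
            d = np.linalg.norm(np.asarray(obstacles) - pos, axis=1)
            if d.min() < min_dist:
                continue
        if far_check is not None:
            anchors, lo, hi = far_check
            d = np.linalg.norm(anchors - pos, axis=1)
            if d.min() < lo or d.min() > hi:
                continue
        return pos
    raise SyntheticError("atom placement failed after bounded retries; loosen the spec")


def _draw_params(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[float, float, float]:
    charge = float(np.clip(rng.uniform(-spec.charge_scale, spec.charge_scale), -1.0, 1.0))
    rmin_half = float(rng.uniform(1.3, 2.1))
    epsilon = float(rng.uniform(0.02, 0.3))
    return charge, rmin_half, epsilon


def make_toy_complexes(spec: SyntheticSpec) -> list[ParameterizedComplex]:
    """Generate ``n_ligands`` complexes over one shared protein scaffold.

    Deterministic under ``spec.seed``; ligand atoms sit 2.5-8 A from the
    nearest protein atom and no interatomic distance falls below 1.5 A.
    """
    rng = np.random.default_rng(spec.seed)

    # shared scaffold: residue centers strung along x, atoms jittered locally
    protein_groups: list[ResidueGroup] = []
    protein_positions: list[np.ndarray] = []
    for k in range(spec.n_residues):
        center = np.array([6.0 * k, 0.0, 0.0])
        group = ResidueGroup(label=f"RES{k + 1}")
        for a in range(spec.atoms_per_residue):
            pos = _place(
                rng, center, max(spec.coordinate_scale, 1.2), protein_positions, _MIN_SEPARATION
            )
            protein_positions.append(pos)
            element = _ELEMENTS[(k + a) % 3]
            charge, rmin_half, epsilon = _draw_params(rng, spec)
            group.atoms.append(
                AtomRecord(
                    atom_name=f"{element}{a + 1}",
                    element=element,
                    position=pos,
                    charge=charge,
                    lj_rmin_half=rmin_half,
                    lj_epsilon=epsilon,
                    residue_index=k,
                    molecule_role="protein",
                )
            )
        protein_groups.append(group)
    protein_arr = np.asarray(protein_positions)
    centroid = protein_arr.mean(axis=0)

    complexes: list[ParameterizedComplex] = []
    for i in range(spec.n_ligands):
        lig_center = centroid + np.array([0.0, float(rng.uniform(4.5, 5.5)), 0.0])
        lig_positions: list[np.ndarray] = []
        lig_atoms: list[AtomRecord] = []
        for a in range(spec.atoms_per_ligand):
            pos = _place(
                rng,
                lig_center,
                1.5,
                lig_positions,
                _MIN_SEPARATION,
                far_check=(protein_arr, 2.5, 8.0),
            )
            lig_positions.append(pos)
            element = _ELEMENTS[a % 3]
            charge, rmin_half, epsilon = _draw_params(rng, spec)
            lig_atoms.append(
                AtomRecord(
                    atom_name=f"{element}{a + 1}",
                    element=element,
                    position=pos,
                    charge=charge,
                    lj_rmin_half=rmin_half,
                    lj_epsilon=epsilon,
                    residue_index=0,
                    molecule_role="ligand",
                )
            )
        # fresh protein AtomRecords per complex so mutation of one complex
        # cannot silently alter another
        groups = [
            ResidueGroup(
                label=g.label,
                atoms=[
                    AtomRecord(
                        a.atom_name, a.element, a.position.copy(), a.charge,
                        a.lj_rmin_half, a.lj_epsilon, a.residue_index, a.molecule_role,
                    )
                    for a in g.atoms
                ],
            )
            for g in protein_groups
        ]
        complexes.append(ParameterizedComplex(f"lig{i + 1:03d}", groups, lig_atoms))
    return complexes


def plant_pkoff(X, spec: SyntheticSpec) -> KineticDataset:
    """Plant pkoff labels as g(X.w) + Gaussian noise over descriptor rows.

    The linear signal is standardized before the optional tanh squash, then
    mapped to ``label_center + label_scale * g(z)``.  With ``include_pkd``
    a correlated pKd channel is added via the inverse BEP proxy line.
    The generator parameters are recorded on the returned dataset as the
    ``provenance`` attribute.
    """
    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    ids = list(X.complex_ids) if hasattr(X, "complex_ids") else [
        f"lig{i + 1:03d}" for i in range(values.shape[0])
    ]
    rng = np.random.default_rng([spec.seed, 1])
    if spec.planted_weights is None:
        w = rng.standard_normal(values.shape[1])
    else:
        w = np.asarray(spec.planted_weights, dtype=float)
    if w.shape != (values.shape[1],):
        raise SyntheticError(
            f"planted_weights length {w.shape} does not match {values.shape[1]} columns"
        )
    z = values @ w
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    g = np.tanh(z) if spec.nonlinearity == "tanh" else z
    pkoff = spec.label_center + spec.label_scale * g + rng.normal(0.0, spec.noise_sd, len(g))

    pkd = None
    if spec.include_pkd:
        pkd = (pkoff - spec.bep_beta) / spec.bep_alpha + rng.normal(
            0.0, spec.pkd_noise_sd, len(pkoff)
        )
    entries = [
        KineticEntry(ids[i], float(pkoff[i]), float(pkd[i]) if pkd is not None else None)
        for i in range(len(ids))
    ]
    dataset = KineticDataset(entries)
    dataset.provenance = {
        "planted_weights": w.tolist(),
        "noise_sd": spec.noise_sd,
        "nonlinearity": spec.nonlinearity,
        "label_center": spec.label_center,
        "label_scale": spec.label_scale,
        "seed": spec.seed,
        "include_pkd": spec.include_pkd,
        "bep_alpha": spec.bep_alpha,
        "bep_beta": spec.bep_beta,
        "pkd_noise_sd": spec.pkd_noise_sd,
    }
    return dataset


def simulate_dataset(spec: SyntheticSpec, cfg=None):
    """Convenience: complexes + descriptor matrix + planted labels in one call."""
    from koffkit.energetics import EnergeticsConfig, build_matrix

    complexes = make_toy_complexes(spec)
    X = build_matrix(complexes, cfg if cfg is not None else EnergeticsConfig())
    dataset = plant_pkoff(X, spec)
    return complexes, X, dataset
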