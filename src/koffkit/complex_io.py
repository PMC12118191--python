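"""I/O for parameterized protein-ligand complexes and tabular data.

A *parameterized complex* is a PDB structure (ATOM/HETATM subset) paired
with a per-atom parameter sidecar (partial charge, Lennard-Jones Rmin/2 and
well depth) in CSV or JSON.  The ligand is identified by a configurable
HETATM residue name (default ``"LIG"``).  Protein residues are re-indexed
consecutively from 0 on read, regardless of gaps in the PDB numbering; the
original residue label is retained for descriptor column naming.

Also provided: a deterministic element-rule "toy" parameterizer for fixture
generation (explicitly not force-field accurate), and CSV readers/writers
for kinetic datasets and interaction-energy matrices.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ComplexIOError",
    "KineticDataset",
    "KineticEntry",
    "ParameterizedComplex",
    "ResidueGroup",
    "read_complex",
    "read_dataset",
    "read_matrix",
    "toy_parameterize",
    "write_complex",
    "write_dataset",
    "write_matrix",
]

#: Residue names treated as solvent/ions and excluded (with a warning) when
#: reading complexes: neither protein nor ligand.
NON_PROTEIN_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP", "TIP3", "SPC", "NA", "CL", "K", "MG", "CA", "ZN", "SO4", "PO4"}
)


class ComplexIOError(ValueError):
    """Raised for malformed or incomplete complex/table inputs."""


@dataclass
class AtomRecord:
    """One atom with coordinates and nonbonded parameters.

    Units: position in Angstrom, charge in elementary charges, ``lj_rmin_half``
    (Rmin/2) in Angstrom, ``lj_epsilon`` (well depth) in kcal/mol.
    """

    atom_name: str
    element: str
    position: np.ndarray
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    residue_index: int
    molecule_role: str  # "protein" | "ligand"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ComplexIOError(f"atom {self.atom_name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ComplexIOError(f"atom {self.atom_name}: non-finite position")
        if not math.isfinite(self.charge):
            raise ComplexIOError(f"atom {self.atom_name}: non-finite charge")
        if not self.lj_rmin_half > 0:
            raise ComplexIOError(f"atom {self.atom_name}: lj_rmin_half must be > 0")
        if self.lj_epsilon < 0:
            raise ComplexIOError(f"atom {self.atom_name}: lj_epsilon must be >= 0")
        if self.molecule_role not in ("protein", "ligand"):
            raise ComplexIOError(f"atom {self.atom_name}: bad role {self.molecule_role!r}")
        if self.residue_index < 0:
            raise ComplexIOError(f"atom {self.atom_name}: negative residue_index")


@dataclass
class ResidueGroup:
    """A protein residue: display label plus its atoms."""

    label: str
    atoms: list[AtomRecord] = field(default_factory=list)


@dataclass
class ParameterizedComplex:
    """Atoms partitioned into ordered protein residues and one ligand."""

    complex_id: str
    protein_residues: list[ResidueGroup]
    ligand_atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.protein_residues:
            raise ComplexIOError(f"{self.complex_id}: no protein residues")
        if not self.ligand_atoms:
            raise ComplexIOError(f"{self.complex_id}: no ligand atoms")
        for k, group in enumerate(self.protein_residues):
            for atom in group.atoms:
                if atom.residue_index != k:
                    raise ComplexIOError(
                        f"{self.complex_id}: residue_index {atom.residue_index} of atom "
                        f"{atom.atom_name} does not match its group position {k}"
                    )
                if atom.molecule_role != "protein":
                    raise ComplexIOError(
                        f"{self.complex_id}: non-protein atom {atom.atom_name} in residue group"
                    )
        for atom in self.ligand_atoms:
            if atom.molecule_role != "ligand":
                raise ComplexIOError(
                    f"{self.complex_id}: non-ligand atom {atom.atom_name} in ligand"
                )

    @property
    def n_residues(self) -> int:
        return len(self.protein_residues)

    @property
    def residue_labels(self) -> list[str]:
        return [g.label for g in self.protein_residues]

    def protein_atoms(self) -> Iterable[AtomRecord]:
        for group in self.protein_residues:
            yield from group.atoms


@dataclass
class KineticEntry:
    complex_id: str
    pkoff: float
    pkd: float | None = None


@dataclass
class KineticDataset:
    """Ordered kinetic records: complex id, pkoff (= -log10 koff), optional pKd."""

    entries: list[KineticEntry]

    def __post_init__(self) -> None:
        ids = [e.complex_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ComplexIOError(f"duplicate complex_id(s): {dupes}")
        for e in self.entries:
            if not math.isfinite(e.pkoff):
                raise ComplexIOError(f"{e.complex_id}: non-finite pkoff")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def complex_ids(self) -> list[str]:
        return [e.complex_id for e in self.entries]

    @property
    def pkoff(self) -> np.ndarray:
        return np.array([e.pkoff for e in self.entries], dtype=float)

    @property
    def pkd(self) -> np.ndarray:
        """pKd values with NaN where absent."""
        return np.array(
            [e.pkd if e.pkd is not None else np.nan for e in self.entries], dtype=float
        )


# ---------------------------------------------------------------------------
# PDB + sidecar reading


def _load_sidecar(params_path: str | Path) -> dict[int, tuple[float, float, float]]:
    """Map atom serial -> (charge_e, rmin_half_A, epsilon_kcal_mol)."""
    params_path = Path(params_path)
    if params_path.suffix.lower() == ".json":
        raw = json.loads(params_path.read_text())
        records = raw["atoms"] if isinstance(raw, dict) and "atoms" in raw else raw
        if isinstance(records, dict):
            records = [
                {"atom_serial": int(k), **v} for k, v in records.items()
            ]
        frame = pd.DataFrame(records)
    else:
        frame = pd.read_csv(params_path)
    required = {"atom_serial", "charge_e", "rmin_half_A", "epsilon_kcal_mol"}
    missing = required - set(frame.columns)
    if missing:
        raise ComplexIOError(f"{params_path}: sidecar missing columns {sorted(missing)}")
    out: dict[int, tuple[float, float, float]] = {}
    for row in frame.itertuples(index=False):
        serial = int(row.atom_serial)
        if serial in out:
            raise ComplexIOError(f"{params_path}: duplicate atom_serial {serial}")
        out[serial] = (float(row.charge_e), float(row.rmin_half_A), float(row.epsilon_kcal_mol))
    return out


def _parse_structure(structure_path: str | Path):
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(structure_path).stem, str(structure_path))
    models = list(structure)
    if not models:
        raise ComplexIOError(f"{structure_path}: no model records")
    return models[0]


def read_complex(
    structure_path: str | Path,
    params_path: str | Path,
    ligand_name: str = "LIG",
    complex_id: str | None = None,
) -> ParameterizedComplex:
    """Read a PDB structure plus parameter sidecar into a ParameterizedComplex.

    Protein residues are taken from ATOM records in file order and re-indexed
    consecutively from 0; the ligand is every residue named ``ligand_name``.
    Water/ion residues are excluded with a warning.  Every atom must have an
    entry in the sidecar (keyed by atom serial) or a hard error names it.
    """
    model = _parse_structure(structure_path)
    sidecar = _load_sidecar(params_path)
    cid = complex_id if complex_id is not None else Path(structure_path).stem

    protein_groups: list[ResidueGroup] = []
    ligand_atoms: list[AtomRecord] = []

    def _params_for(atom, residue) -> tuple[float, float, float]:
        serial = int(atom.get_serial_number())
        if serial not in sidecar:
            raise ComplexIOError(
                f"{cid}: no sidecar parameters for atom serial {serial} "
                f"({atom.get_name()} in {residue.get_resname()}{residue.id[1]})"
            )
        return sidecar[serial]

    def _atoms_of(residue):
        if residue.is_disordered():
            warnings.warn(
                f"{cid}: residue {residue.get_resname()}{residue.id[1]} has alternate "
                "locations; keeping the first altloc only",
                stacklevel=2,
            )
        for atom in residue:
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]
            yield atom

    for chain in model:
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            resname = residue.get_resname().strip()
            if resname == ligand_name:
                for atom in _atoms_of(residue):
                    charge, rmin_half, eps = _params_for(atom, residue)
                    ligand_atoms.append(
                        AtomRecord(
                            atom_name=atom.get_name(),
                            element=(atom.element or "X").strip(),
                            position=np.asarray(atom.coord, dtype=float),
                            charge=charge,
                            lj_rmin_half=rmin_half,
                            lj_epsilon=eps,
                            residue_index=0,
                            molecule_role="ligand",
                        )
                    )
            elif hetflag != " " or resname in NON_PROTEIN_RESNAMES:
                warnings.warn(
                    f"{cid}: excluding non-protein, non-ligand residue "
                    f"{resname}{resseq}",
                    stacklevel=2,
                )
            else:
                k = len(protein_groups)
                group = ResidueGroup(label=f"{resname}{resseq}")
                for atom in _atoms_of(residue):
                    charge, rmin_half, eps = _params_for(atom, residue)
                    group.atoms.append(
                        AtomRecord(
                            atom_name=atom.get_name(),
                            element=(atom.element or "X").strip(),
                            position=np.asarray(atom.coord, dtype=float),
                            charge=charge,
                            lj_rmin_half=rmin_half,
                            lj_epsilon=eps,
                            residue_index=k,
                            molecule_role="protein",
                        )
                    )
                protein_groups.append(group)

    if not ligand_atoms:
        raise ComplexIOError(
            f"{cid}: no ligand atoms found (looked for residue name {ligand_name!r})"
        )
    if not protein_groups:
        raise ComplexIOError(f"{cid}: no protein residues found")
    return ParameterizedComplex(cid, protein_groups, ligand_atoms)


def toy_parameterize(
    structure_path: str | Path,
    rules: Mapping[str, tuple[float, float, float]],
    ligand_name: str = "LIG",
    complex_id: str | None = None,
) -> ParameterizedComplex:
    """Assign per-element (charge, Rmin/2, epsilon) parameters from a rule table.

    Fixture-quality only: deterministic and convenient, in no way
    force-field accurate.  Unknown elements are a hard error.
    """
    model = _parse_structure(structure_path)
    cid = complex_id if complex_id is not None else Path(structure_path).stem

    protein_groups: list[ResidueGroup] = []
    ligand_atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            resname = residue.get_resname().strip()
            is_ligand = resname == ligand_name
            if not is_ligand and (hetflag != " " or resname in NON_PROTEIN_RESNAMES):
                warnings.warn(
                    f"{cid}: excluding non-protein, non-ligand residue {resname}{resseq}",
                    stacklevel=2,
                )
                continue
            group = None
            if not is_ligand:
                group = ResidueGroup(label=f"{resname}{resseq}")
            for atom in residue:
                element = (atom.element or "").strip().capitalize()
                if element not in rules:
                    raise ComplexIOError(
                        f"{cid}: no parameter rule for element {element!r} "
                        f"(atom {atom.get_name()} in {resname}{resseq})"
                    )
                charge, rmin_half, eps = rules[element]
                record = AtomRecord(
                    atom_name=atom.get_name(),
                    element=element,
                    position=np.asarray(atom.coord, dtype=float),
                    charge=float(charge),
                    lj_rmin_half=float(rmin_half),
                    lj_epsilon=float(eps),
                    residue_index=0 if is_ligand else len(protein_groups),
                    molecule_role="ligand" if is_ligand else "protein",
                )
                if is_ligand:
                    ligand_atoms.append(record)
                else:
                    group.atoms.append(record)
            if group is not None:
                protein_groups.append(group)
    if not ligand_atoms:
        raise ComplexIOError(f"{cid}: no ligand atoms (residue name {ligand_name!r})")
    return ParameterizedComplex(cid, protein_groups, ligand_atoms)


# ---------------------------------------------------------------------------
# PDB + sidecar writing (fixtures, round-trips)


def write_complex(
    complex_: ParameterizedComplex,
    structure_path: str | Path,
    params_path: str | Path,
    ligand_name: str = "LIG",
) -> None:
    """Write a complex as a PDB file (protein ATOM, ligand HETATM) + sidecar CSV.

    Coordinates are truncated to PDB's fixed %8.3f precision; the sidecar
    carries full-precision parameters keyed by atom serial.
    """
    lines: list[str] = []
    sidecar_rows: list[dict] = []
    serial = 0

    def _emit(record: str, atom: AtomRecord, resname: str, resseq: int) -> None:
        nonlocal serial
        serial += 1
        name = atom.atom_name[:4]
        name_field = name if len(name) == 4 else f" {name:<3s}"
        x, y, z = atom.position
        lines.append(
            f"{record:<6s}{serial:5d} {name_field}{'':1s}{resname:<3s} A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element[:2]:>2s}"
        )
        sidecar_rows.append(
            {
                "atom_serial": serial,
                "charge_e": atom.charge,
                "rmin_half_A": atom.lj_rmin_half,
                "epsilon_kcal_mol": atom.lj_epsilon,
            }
        )

    for k, group in enumerate(complex_.protein_residues):
        resname = "".join(c for c in group.label if c.isalpha())[:3] or "RES"
        for atom in group.atoms:
            _emit("ATOM", atom, resname, k + 1)
    lines.append("TER")
    for atom in complex_.ligand_atoms:
        _emit("HETATM", atom, ligand_name, complex_.n_residues + 1)
    lines.append("END")
    Path(structure_path).write_text("\n".join(lines) + "\n")
    pd.DataFrame(sidecar_rows).to_csv(params_path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Tabular data


def read_dataset(csv_path: str | Path) -> KineticDataset:
    """Read a kinetic dataset CSV with columns complex_id, pkoff[, pkd]."""
    frame = pd.read_csv(csv_path)
    for col in ("complex_id", "pkoff"):
        if col not in frame.columns:
            raise ComplexIOError(f"{csv_path}: missing required column {col!r}")
    try:
        pkoff = pd.to_numeric(frame["pkoff"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ComplexIOError(f"{csv_path}: non-numeric pkoff value ({exc})") from exc
    if pkoff.isna().any():
        bad = frame.loc[pkoff.isna(), "complex_id"].tolist()
        raise ComplexIOError(f"{csv_path}: missing pkoff for {bad}")
    pkd = None
    if "pkd" in frame.columns:
        pkd = pd.to_numeric(frame["pkd"], errors="coerce").astype(float)
    entries = []
    for i in range(len(frame)):
        entry_pkd = None
        if pkd is not None and math.isfinite(pkd.iloc[i]):
            entry_pkd = float(pkd.iloc[i])
        entries.append(
            KineticEntry(str(frame["complex_id"].iloc[i]), float(pkoff.iloc[i]), entry_pkd)
        )
    return KineticDataset(entries)


def write_dataset(dataset: KineticDataset, csv_path: str | Path) -> None:
    rows = [
        {"complex_id": e.complex_id, "pkoff": e.pkoff, "pkd": e.pkd} for e in dataset.entries
    ]
    frame = pd.DataFrame(rows)
    if frame["pkd"].isna().all():
        frame = frame.drop(columns=["pkd"])
    frame.to_csv(csv_path, index=False, float_format="%.12g")


def write_matrix(matrix, csv_path: str | Path) -> None:
    """Write an InteractionEnergyMatrix to CSV (complex_id + named columns)."""
    frame = pd.DataFrame(matrix.values, columns=matrix.columns)
    frame.insert(0, "complex_id", matrix.complex_ids)
    frame.to_csv(csv_path, index=False, float_format="%.17g")


def read_matrix(csv_path: str | Path):
    """Read an interaction-energy matrix CSV back into an InteractionEnergyMatrix."""
    from koffkit.energetics import InteractionEnergyMatrix

    frame = pd.read_csv(csv_path)
    if "complex_id" not in frame.columns:
        raise ComplexIOError(f"{csv_path}: missing complex_id column")
    value_cols = [c for c in frame.columns if c != "complex_id"]
    bad = [c for c in value_cols if not (c.startswith("vdw_") or c.startswith("elec_"))]
    if bad:
        raise ComplexIOError(f"{csv_path}: unrecognized matrix columns {bad}")
    return InteractionEnergyMatrix(
        complex_ids=[str(c) for c in frame["complex_id"]],
        columns=value_cols,
        values=frame[value_cols].to_numpy(dtype=float),
    )
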