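"""Molecular structures and tabular inputs.

Atoms are held in a lightweight :class:`Structure` container addressable by
``(residue_seq, name)`` so that downstream geometry operations can name the
atoms they act on (the adduct phosphorus ``P``, the catalytic serine
``OG``, the phosphoryl oxygen ``O1P``, the fluoride probe ``F`` ...).
PDB reading and writing is delegated to biotite; HETATM records are treated
identically to ATOM records because organophosphate moieties and the
fluoride ion appear as heteroatoms in deposited entries.

Partial charges are *not* read from PDB files — the format has no reliable
charge column and the charges used for scoring come from semiempirical
calculations external to the structure file.  They enter through the
tabular adduct-record route (:mod:`opreact.scoring`) or explicit per-atom
assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .errors import (
    AmbiguousSelectionError,
    AtomLookupError,
    PDBParseError,
    SchemaError,
)

#: Residue names recognised as water (crystal structures write HOH,
#: GROMACS writes SOL).
WATER_RESNAMES: frozenset[str] = frozenset({"HOH", "WAT", "SOL"})

#: Case-insensitive sentinel used in docking pose tables when no productive
#: conformation was found at a site.
ABSENT_SENTINEL = "not found"


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue context, Cartesian coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    coords: np.ndarray
    charge: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        if self.charge is not None and not math.isfinite(self.charge):
            raise ValueError(f"atom {self.serial}: charge must be finite")

    def is_water(self, water_resnames: frozenset[str] = WATER_RESNAMES) -> bool:
        return self.residue_name.upper() in water_resnames


@dataclass
class Structure:
    """An ordered collection of atoms with unique serials."""

    atoms: list[AtomRecord] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError("atom serials must be unique")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords_array(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def water_oxygens(
        self, water_resnames: frozenset[str] = WATER_RESNAMES
    ) -> list[AtomRecord]:
        """Oxygen atoms of water residues (used for hydration counting)."""
        return [
            a
            for a in self.atoms
            if a.is_water(water_resnames) and a.element.upper() == "O"
        ]

    def with_atom(self, atom: AtomRecord) -> "Structure":
        """A new Structure with ``atom`` appended (serial uniqueness enforced)."""
        return Structure(atoms=[*self.atoms, atom], title=self.title)

    def index_of(self, residue_seq: int, name: str) -> int:
        """Positional index of the unique atom matching (residue_seq, name)."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_seq == residue_seq and a.name == name
        ]
        if not hits:
            raise AtomLookupError(
                f"no atom with residue_seq={residue_seq}, name={name!r}"
            )
        if len(hits) > 1:
            raise AmbiguousSelectionError(
                f"{len(hits)} atoms match residue_seq={residue_seq}, name={name!r}"
            )
        return hits[0]


def select_atom(structure: Structure, residue_seq: int, name: str) -> AtomRecord:
    """Return the unique atom matching ``(residue_seq, name)``.

    Raises :class:`AtomLookupError` when no atom matches and
    :class:`AmbiguousSelectionError` when more than one does.
    """
    return structure.atoms[structure.index_of(residue_seq, name)]


@dataclass(frozen=True)
class PoseRecord:
    """One docking pose: binding-site label, functional-atom distance, ΔG.

    ``dist_functional`` is the distance (Å) between the attacking atom of
    the catalytic residue (Ser/Tyr O or His/Lys N) and the attacked atom of
    the ligand (P or methylene C); ``None`` marks sites where no productive
    conformation was found.  ``delta_g`` is the estimated binding free
    energy in kcal/mol.
    """

    site_label: str
    dist_functional: float | None
    delta_g: float | None = None

    def __post_init__(self) -> None:
        if self.dist_functional is not None and self.dist_functional <= 0:
            raise ValueError(f"{self.site_label}: distance must be > 0 or absent")


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _atoms_from_atom_array(array: struc.AtomArray) -> list[AtomRecord]:
    serials = (
        array.get_annotation("atom_id")
        if "atom_id" in array.get_annotation_categories()
        else np.arange(1, array.array_length() + 1)
    )
    atoms = []
    for i in range(array.array_length()):
        element = str(array.element[i]) or str(array.atom_name[i])[:1]
        atoms.append(
            AtomRecord(
                serial=int(serials[i]),
                name=str(array.atom_name[i]),
                element=element,
                residue_name=str(array.res_name[i]),
                residue_seq=int(array.res_id[i]),
                chain=str(array.chain_id[i]) or "A",
                coords=np.asarray(array.coord[i], dtype=float),
            )
        )
    return atoms


def _atom_array_from_structure(structure: Structure) -> struc.AtomArray:
    n = len(structure)
    array = struc.AtomArray(n)
    array.add_annotation("atom_id", int)
    for i, a in enumerate(structure.atoms):
        array.atom_id[i] = a.serial
        array.atom_name[i] = a.name
        array.element[i] = a.element
        array.res_name[i] = a.residue_name
        array.res_id[i] = a.residue_seq
        array.chain_id[i] = a.chain
        array.hetero[i] = a.residue_name.upper() not in _STANDARD_RESNAMES
        array.coord[i] = a.coords
    return array


_STANDARD_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL""".split()
)


def read_pdb(path: str | Path, model: int = 1) -> Structure:
    """Parse one model of a PDB file into a :class:`Structure`.

    ATOM and HETATM records are parsed alike.  Models beyond ``model`` are
    ignored here; multi-model trajectories are read by
    :func:`opreact.trajectory.read_multimodel_pdb`.
    """
    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        array = pdb_file.get_structure(model=model, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises assorted parse errors
        raise PDBParseError(f"{path}: {exc}") from exc
    if array.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return Structure(atoms=_atoms_from_atom_array(array), title=path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a single-model PDB file."""
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_atom_array_from_structure(structure))
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Pose tables
# ---------------------------------------------------------------------------


def read_pose_table(path: str | Path) -> list[PoseRecord]:
    """Read a docking pose table (CSV/TSV with header) into PoseRecords.

    Required columns: ``site``, ``distance``, ``delta_g``.  The distance
    column may contain the case-insensitive sentinel ``"not found"``, which
    yields a record with an absent distance.
    """
    import pandas as pd

    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"site", "distance", "delta_g"} - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        raw_dist = row["distance"].strip()
        absent = raw_dist == "" or raw_dist.lower() == ABSENT_SENTINEL
        dist = None if absent else float(raw_dist)
        raw_dg = row["delta_g"].strip()
        delta_g = float(raw_dg) if raw_dg else None
        records.append(PoseRecord(row["site"].strip(), dist, delta_g))
    return records
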