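"""Trajectory distance analysis and hydration counting.

A trajectory is a fixed atom set (shared with a reference
:class:`~opreact.structures.Structure`) plus per-frame coordinates and
strictly increasing times in picoseconds.  The portable on-disk format is
multi-model PDB (MODEL/ENDMDL); binary MD formats are deliberately out of
scope so that the analysis is testable without an MD toolchain.

The quantities computed here mirror how fluoride-reactivation simulations
are read out: the P–F distance time series, its mean over a chosen stable
interval, the residence time of the ion in the productive position (first
contiguous run under the attack cutoff), and the number of water molecules
hydrating the ion in a given frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure.io.pdb as pdbio

from .errors import PDBParseError
from .geometry import ATTACK_CUTOFF
from .structures import (
    AtomRecord,
    Structure,
    WATER_RESNAMES,
    _atom_array_from_structure,
    _atoms_from_atom_array,
)

#: Default ion-to-water-oxygen cutoff for hydration counting, Å.
HYDRATION_CUTOFF = 3.5


@dataclass
class Trajectory:
    """Per-frame coordinates of a fixed atom set."""

    reference: Structure
    times: np.ndarray  # ps, strictly increasing
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("one time per frame required")
        if self.coords.shape[1] != len(self.reference):
            raise ValueError("frame atom count must match the reference structure")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def frame(self, i: int) -> Structure:
        """The i-th frame as a Structure (reference identities, frame coords)."""
        atoms = [
            AtomRecord(
                serial=a.serial,
                name=a.name,
                element=a.element,
                residue_name=a.residue_name,
                residue_seq=a.residue_seq,
                chain=a.chain,
                coords=self.coords[i, j],
                charge=a.charge,
            )
            for j, a in enumerate(self.reference.atoms)
        ]
        return Structure(atoms=atoms, title=f"{self.reference.title} frame {i}")


@dataclass
class DistanceSeries:
    """A scalar distance time series derived from a trajectory."""

    times: np.ndarray  # ps
    values: np.ndarray  # Å
    label: str = "dist"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV (time_ps, dist_A)."""
        import pandas as pd

        pd.DataFrame({"time_ps": self.times, "dist_A": self.values}).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------


def read_multimodel_pdb(path: str | Path, dt: float = 1.0, t0: float = 0.0) -> Trajectory:
    """Read a MODEL/ENDMDL trajectory; frame times are ``t0 + i*dt`` ps.

    PDB carries no time axis, so the frame spacing is supplied by the
    caller (fixed-step MD output is assumed).
    """
    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(extra_fields=["atom_id"])
    except Exception as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    first = stack[0] if stack.stack_depth() > 0 else stack
    reference = Structure(atoms=_atoms_from_atom_array(first), title=path.stem)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None, :, :]
    times = t0 + dt * np.arange(coords.shape[0])
    return Trajectory(reference=reference, times=times, coords=coords)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    import biotite.structure as struc

    template = _atom_array_from_structure(traj.reference)
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Analysis operations
# ---------------------------------------------------------------------------


def distance_series(
    traj: Trajectory, atom_a: int, atom_b: int, label: str | None = None
) -> DistanceSeries:
    """Per-frame Euclidean distance between two atoms (positional indices)."""
    n_atoms = traj.coords.shape[1]
    for idx in (atom_a, atom_b):
        if not 0 <= idx < n_atoms:
            raise IndexError(f"atom index {idx} out of range for {n_atoms} atoms")
    diffs = traj.coords[:, atom_a, :] - traj.coords[:, atom_b, :]
    values = np.linalg.norm(diffs, axis=1)
    if label is None:
        a = traj.reference.atoms[atom_a].name
        b = traj.reference.atoms[atom_b].name
        label = f"dist{a}-{b}"
    return DistanceSeries(times=traj.times.copy(), values=values, label=label)


def interval_mean(series: DistanceSeries, t0: float, t1: float) -> float:
    """Arithmetic mean of series values with t0 ≤ t ≤ t1 (ps), in Å."""
    if t0 >= t1:
        raise ValueError(f"empty interval: t0={t0} must be < t1={t1}")
    mask = (series.times >= t0) & (series.times <= t1)
    if not np.any(mask):
        raise ValueError(f"interval [{t0}, {t1}] ps contains no frames")
    return float(series.values[mask].mean())


def productive_runs(
    series: DistanceSeries, cutoff: float = ATTACK_CUTOFF
) -> list[tuple[float, float]]:
    """Contiguous (t_start, t_end) runs with value ≤ cutoff.

    Re-entries into the productive position are reported as separate runs;
    the first run's end is what :func:`residence_time` returns.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    below = series.values <= cutoff
    runs: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((float(series.times[start]), float(series.times[i - 1])))
            start = None
    if start is not None:
        runs.append((float(series.times[start]), float(series.times[-1])))
    return runs


def residence_time(series: DistanceSeries, cutoff: float = ATTACK_CUTOFF) -> float:
    """Duration (ps) the ion initially remains in the productive position.

    Defined as the time of the last frame of the first contiguous run with
    value ≤ cutoff; 0 when the very first frame already exceeds the cutoff.
    Re-entries earn no credit here (see :func:`productive_runs`).
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if series.values[0] > cutoff:
        return 0.0
    above = np.nonzero(series.values > cutoff)[0]
    last = above[0] - 1 if above.size else len(series) - 1
    return float(series.times[last])


def hydration_count(
    structure_frame: Structure,
    ion: AtomRecord,
    cutoff: float = HYDRATION_CUTOFF,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> int:
    """Number of distinct water molecules hydrating an ion in one frame.

    A water counts when its oxygen lies within ``cutoff`` Å of the ion;
    distinct waters are distinguished by (chain, residue_seq).  Returns 0
    when the frame contains no waters.
    """
    seen: set[tuple[str, int]] = set()
    for ox in structure_frame.water_oxygens(water_resnames):
        if np.linalg.norm(ox.coords - ion.coords) <= cutoff:
            seen.add((ox.chain, ox.residue_seq))
    return len(seen)
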