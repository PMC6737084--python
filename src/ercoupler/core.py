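"""Domain types and I/O shared by all analysis stages.

The in-memory model is deliberately small: a :class:`Topology` (ordered atom
records with residue/chain metadata), a :class:`Trajectory` (frames × atoms ×
3 coordinates in Å over that topology), a :class:`SegmentMap` naming residue
ranges (the LBD helices H1…H12 in the intended application), and an
:class:`AtomSelection` resolving a predicate to sorted atom ids.

Readers accept plain-text formats only — PDB (single model for topology,
multi-MODEL for trajectories) and multi-frame XYZ — and report parse errors
with the offending line or frame.  Input trajectories are assumed
whole-molecule imaged; no periodic-boundary handling is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "SegmentMap",
    "Segment",
    "AtomSelection",
    "TrajectoryFormatError",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "read_segment_map",
    "write_segment_map",
    "resolve_selection",
    "select",
]

# Elements that a PDB atom-name column can start with; two-letter symbols
# checked before one-letter so "CL" does not resolve to carbon.
_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "CU", "SE", "SI",
}


class TrajectoryFormatError(ValueError):
    """A coordinate or topology file violates its format contract."""


@dataclass(frozen=True)
class Atom:
    atom_id: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    is_hydrogen: bool


class Topology:
    """Ordered list of atoms with unique, contiguous 1-based atom ids."""

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        ids = [a.atom_id for a in atoms]
        if ids != list(range(1, len(atoms) + 1)):
            raise ValueError("atom ids must be unique and contiguous from 1")
        self.atoms: list[Atom] = atoms
        # column views used by vectorised selection
        self._names = np.array([a.atom_name for a in atoms])
        self._elements = np.array([a.element for a in atoms])
        self._residue_indices = np.array([a.residue_index for a in atoms])
        self._residue_names = np.array([a.residue_name for a in atoms])
        self._chain_ids = np.array([a.chain_id for a in atoms])
        self._is_hydrogen = np.array([a.is_hydrogen for a in atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        nres = len(set(zip(self._chain_ids.tolist(), self._residue_indices.tolist())))
        return f"<Topology: {len(self)} atoms, {nres} residues>"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def column(self, name: str) -> np.ndarray:
        try:
            return {
                "atom_name": self._names,
                "name": self._names,
                "element": self._elements,
                "residue_index": self._residue_indices,
                "residue_name": self._residue_names,
                "chain_id": self._chain_ids,
                "is_hydrogen": self._is_hydrogen,
            }[name]
        except KeyError:
            raise KeyError(
                f"unknown topology field {name!r}; known fields: atom_name, "
                "element, residue_index, residue_name, chain_id, is_hydrogen"
            ) from None


class Trajectory:
    """Frames × atoms × 3 coordinates in Å over a fixed :class:`Topology`."""

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        frame_times_ps: np.ndarray | None = None,
    ):
        coords = np.asarray(coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != len(topology) or coords.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (n_frames, {len(topology)}, 3); "
                f"got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.topology = topology
        self.coordinates = coords
        self.frame_times_ps = (
            None if frame_times_ps is None else np.asarray(frame_times_ps, dtype=float)
        )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __repr__(self) -> str:
        return f"<Trajectory: {self.n_frames} frames × {self.n_atoms} atoms>"


@dataclass(frozen=True)
class Segment:
    """Named inclusive 1-based residue range on one chain."""

    name: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"segment {self.name}: empty range [{self.start}, {self.end}]")

    def contains(self, residue_index: int, chain_id: str) -> bool:
        return chain_id == self.chain_id and self.start <= residue_index <= self.end


class SegmentMap:
    """Partition of residues into named segments (e.g. LBD helices).

    A residue may belong to at most one segment per chain; overlapping
    definitions are rejected at construction.
    """

    def __init__(self, segments: Iterable[Segment]):
        self.segments: list[Segment] = list(segments)
        seen: dict[tuple[str, int], str] = {}
        for seg in self.segments:
            for r in range(seg.start, seg.end + 1):
                key = (seg.chain_id, r)
                if key in seen:
                    raise ValueError(
                        f"residue {r} on chain {seg.chain_id!r} belongs to both "
                        f"{seen[key]!r} and {seg.name!r}"
                    )
                seen[key] = seg.name

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def get(self, name: str) -> list[Segment]:
        found = [s for s in self.segments if s.name == name]
        if not found:
            raise KeyError(f"no segment named {name!r}")
        return found


@dataclass(frozen=True)
class AtomSelection:
    """Resolved, sorted atom ids together with the predicate description."""

    resolved_atom_ids: tuple[int, ...]
    description: str = ""

    def __post_init__(self):
        ids = tuple(sorted(set(self.resolved_atom_ids)))
        object.__setattr__(self, "resolved_atom_ids", ids)

    def __len__(self) -> int:
        return len(self.resolved_atom_ids)

    def indices(self) -> np.ndarray:
        """0-based array indices into topology/coordinate arrays."""
        return np.asarray(self.resolved_atom_ids, dtype=int) - 1


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def resolve_selection(
    topology: Topology,
    predicate: Callable[[Topology], np.ndarray],
    description: str = "",
) -> AtomSelection:
    """Resolve a boolean predicate over topology columns to an AtomSelection.

    ``predicate`` receives the topology and must return a boolean mask of
    length ``n_atoms``.  An empty result is allowed but warned about, since a
    silent empty selection usually indicates a typo in an atom name.
    """
    mask = np.asarray(predicate(topology))
    if mask.shape != (len(topology),) or mask.dtype != bool:
        raise ValueError("selection predicate must return a boolean mask over atoms")
    ids = np.nonzero(mask)[0] + 1
    if ids.size == 0:
        warnings.warn(f"selection {description or predicate!r} matched no atoms")
    return AtomSelection(tuple(int(i) for i in ids), description)


def select(
    topology: Topology,
    name: str | Sequence[str] | None = None,
    residue_range: tuple[int, int] | None = None,
    chain_id: str | None = None,
    element: str | None = None,
    heavy_only: bool = False,
) -> AtomSelection:
    """Convenience selection by atom name, residue range, chain and element."""
    mask = np.ones(len(topology), dtype=bool)
    desc = []
    if name is not None:
        names = [name] if isinstance(name, str) else list(name)
        mask &= np.isin(topology.column("atom_name"), names)
        desc.append(f"name in {names}")
    if residue_range is not None:
        lo, hi = residue_range
        resi = topology.column("residue_index")
        mask &= (resi >= lo) & (resi <= hi)
        desc.append(f"residue in [{lo}, {hi}]")
    if chain_id is not None:
        mask &= topology.column("chain_id") == chain_id
        desc.append(f"chain {chain_id}")
    if element is not None:
        mask &= topology.column("element") == element.upper()
        desc.append(f"element {element}")
    if heavy_only:
        mask &= ~topology.column("is_hydrogen")
        desc.append("heavy")
    return resolve_selection(topology, lambda _t: mask, " and ".join(desc) or "all")


def segment_selection(
    topology: Topology, segments: SegmentMap, segment_name: str, atom_name: str | None = "CA"
) -> AtomSelection:
    """Atoms belonging to a named segment, optionally restricted by atom name."""
    mask = np.zeros(len(topology), dtype=bool)
    resi = topology.column("residue_index")
    chain = topology.column("chain_id")
    for seg in segments.get(segment_name):
        mask |= (chain == seg.chain_id) & (resi >= seg.start) & (resi <= seg.end)
    if atom_name is not None:
        mask &= topology.column("atom_name") == atom_name
    return resolve_selection(topology, lambda _t: mask, f"segment {segment_name}")


# ---------------------------------------------------------------------------
# element inference
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, explicit: str = "") -> str:
    explicit = explicit.strip()
    if explicit:
        return explicit.upper().capitalize() if len(explicit) > 1 else explicit.upper()
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    # Protein-atom convention: the first alphabetic character is the element
    # ("CA" is Cα carbon, not calcium — calcium ions come with an explicit
    # element column or a blank-padded name we do not special-case here).
    first = stripped[0].upper()
    if first in "CHNOSP":
        return first
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS:
        return two.capitalize()
    return first


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int, atom_id: int) -> tuple[Atom, np.ndarray]:
    if len(line.rstrip("\n")) < 54:
        raise TrajectoryFormatError(
            f"line {lineno}: truncated ATOM/HETATM record (needs 54 columns, "
            f"got {len(line.rstrip())})"
        )
    try:
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        residue_index = int(line[22:26])
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise TrajectoryFormatError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    elem = _infer_element(name, element)
    atom = Atom(
        atom_id=atom_id,
        atom_name=name,
        element=elem,
        residue_index=residue_index,
        residue_name=residue_name,
        chain_id=chain_id,
        is_hydrogen=(elem == "H"),
    )
    return atom, xyz


def read_topology(path: str | Path, format: str = "pdb") -> Topology:
    """Read a topology from a PDB file (first MODEL if several).

    ATOM and HETATM records are kept in file order; the element is taken from
    columns 77–78 when present, otherwise inferred from the atom name.
    """
    if format != "pdb":
        raise ValueError(f"unsupported topology format {format!r}")
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                atom, _ = _parse_pdb_atom_line(line, lineno, len(atoms) + 1)
                atoms.append(atom)
            elif rec == "ENDMDL":
                break
    if not atoms:
        raise TrajectoryFormatError(f"{path}: no ATOM/HETATM records found")
    return Topology(atoms)


def _read_pdb_models(path: str | Path, n_atoms: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    current: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                current = []
            elif rec in ("ATOM", "HETATM"):
                _, xyz = _parse_pdb_atom_line(line, lineno, len(current) + 1)
                current.append(xyz)
            elif rec == "ENDMDL":
                frames.append(np.array(current))
                current = []
    if current:  # file without trailing ENDMDL, or no MODEL records at all
        frames.append(np.array(current))
    for i, fr in enumerate(frames):
        if fr.shape != (n_atoms, 3):
            raise TrajectoryFormatError(
                f"frame {i}: expected {n_atoms} atoms, got {fr.shape[0]}"
            )
    return np.array(frames)


# ---------------------------------------------------------------------------
# multi-frame XYZ
# ---------------------------------------------------------------------------

def _read_xyz_frames(path: str | Path, n_atoms: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"line {i + 1}: expected atom count, got {lines[i].strip()!r}"
            ) from exc
        if count != n_atoms:
            raise TrajectoryFormatError(
                f"frame {frame_index}: expected {n_atoms} atoms, header says {count}"
            )
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise TrajectoryFormatError(
                f"frame {frame_index}: truncated (has {len(block)} of {count} atom lines)"
            )
        coords = np.empty((count, 3))
        for j, atom_line in enumerate(block):
            parts = atom_line.split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"line {i + 3 + j}: malformed XYZ atom line {atom_line.strip()!r}"
                )
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + count
        frame_index += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return np.array(frames)


def read_trajectory(
    path: str | Path, topology: Topology, format: str = "xyz_multiframe"
) -> Trajectory:
    """Read a multi-frame coordinate file over an existing topology.

    Formats: ``xyz_multiframe`` (mandatory dialect) and ``pdb_multimodel``.
    Coordinates are stored as read, in Å.
    """
    if format == "xyz_multiframe":
        frames = _read_xyz_frames(path, len(topology))
    elif format == "pdb_multimodel":
        frames = _read_pdb_models(path, len(topology))
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    return Trajectory(topology, frames)


def write_trajectory(
    traj: Trajectory, path: str | Path, format: str = "xyz_multiframe"
) -> None:
    """Write a trajectory as multi-frame XYZ or multi-MODEL PDB (Å, %.3f)."""
    top = traj.topology
    if format == "xyz_multiframe":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\nframe {f}\n")
                for a, atom in enumerate(top.atoms):
                    x, y, z = traj.coordinates[f, a]
                    fh.write(f"{atom.element:<2s} {x:12.3f} {y:12.3f} {z:12.3f}\n")
    elif format == "pdb_multimodel":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                for a, atom in enumerate(top.atoms):
                    x, y, z = traj.coordinates[f, a]
                    fh.write(
                        f"ATOM  {atom.atom_id:5d} {atom.atom_name:<4.4s}"
                        f"{atom.residue_name:>4.3s} {atom.chain_id:1.1s}"
                        f"{atom.residue_index:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                        f"          {atom.element:>2.2s}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")


# ---------------------------------------------------------------------------
# segment tables
# ---------------------------------------------------------------------------

def read_segment_map(path: str | Path) -> SegmentMap:
    """Read a TSV with columns segment_name, chain_id, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"segment_name": str, "chain_id": str})
    required = {"segment_name", "chain_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return SegmentMap(
        Segment(str(r.segment_name), str(r.chain_id), int(r.start), int(r.end))
        for r in df.itertuples()
    )


def write_segment_map(segments: SegmentMap, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"segment_name": s.name, "chain_id": s.chain_id, "start": s.start, "end": s.end}
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)
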