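"""PDB coordinate I/O, atom selection, and trajectory assembly.

Reads and writes fixed-column PDB v3.3 coordinate files (``ATOM`` /
``HETATM`` / ``MODEL`` / ``ENDMDL`` / ``TER``).  Alternate locations are
resolved at parse time to a single conformer: the highest-occupancy altloc
wins, ties break to the lexicographically first altloc identifier, so all
downstream geometry is deterministic.  Hydrogens are kept when present;
"heavy-atom" selections exclude element H/D.

Multi-model files double as the trajectory interchange format: a list of
models sharing one atom table converts to a :class:`Trajectory` whose frames
are a single ``(n_frames, n_atoms, 3)`` array.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "EmptyInputError",
    "IncompatibleModelsError",
    "parse_pdb",
    "parse_pdb_file",
    "write_pdb",
    "as_trajectory",
    "select_atoms",
]

#: Backbone atom names for standard polypeptides (OXT counts as backbone).
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBParseError(ValueError):
    """A fixed-width record could not be parsed (message names the line)."""


class EmptyInputError(ValueError):
    """The input contained no ATOM/HETATM records."""


class IncompatibleModelsError(ValueError):
    """Models passed to :func:`as_trajectory` do not share one atom table."""


@dataclass(frozen=True)
class AtomRecord:
    """One crystallographic/model atom.

    ``coord`` is in Å; ``occupancy`` in [0, 1]; ``bfactor`` in Å².
    """

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, resseq, icode) — residue identity within a model."""
        return (self.chain, self.resseq, self.icode)

    @property
    def atom_id(self) -> tuple[str, int, str, str]:
        """(chain, resseq, icode, name) — unique after altloc resolution."""
        return (self.chain, self.resseq, self.icode, self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES


@dataclass
class Structure:
    """An ordered atom table for one coordinate model."""

    atoms: list[AtomRecord]
    model_id: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str, str]] = set()
        for a in self.atoms:
            if a.atom_id in seen:
                raise ValueError(f"duplicate atom after altloc resolution: {a.atom_id}")
            seen.add(a.atom_id)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom table")
        atoms = [replace(a, coord=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms=atoms, model_id=self.model_id, metadata=dict(self.metadata))

    def atom_index(self, chain: str, resseq: int, name: str, icode: str = "") -> int:
        """Index of the uniquely identified atom; raises KeyError if absent."""
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resseq == resseq and a.name == name and a.icode == icode:
                return i
        raise KeyError(f"atom not found: chain={chain!r} resseq={resseq} name={name!r} icode={icode!r}")


@dataclass
class Trajectory:
    """Fixed atom table plus ordered coordinate frames.

    ``frames`` is ``(n_frames, n_atoms, 3)`` in Å; ``dt`` is the time between
    consecutive frames in ps (default 10 ps, i.e. 500 ns ↔ 50,000 frames).
    """

    topology: Structure
    frames: np.ndarray
    dt: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"frames must have shape (n_frames, {len(self.topology)}, 3), "
                f"got {self.frames.shape}"
            )
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """Conjunction of atom predicates; ``None`` means "no constraint".

    ``heavy=True`` excludes H/D.  ``backbone``/``sidechain`` use the standard
    polypeptide backbone atom-name set; both set to True is a contradiction
    that simply selects nothing.
    """

    chain: str | None = None
    resseq: int | tuple[int, int] | None = None
    resname: str | frozenset | None = None
    name: str | frozenset | None = None
    element: str | None = None
    heavy: bool = False
    backbone: bool | None = None
    sidechain: bool | None = None

    def matches(self, a: AtomRecord) -> bool:
        if self.chain is not None and a.chain != self.chain:
            return False
        if self.resseq is not None:
            if isinstance(self.resseq, tuple):
                lo, hi = self.resseq
                if not lo <= a.resseq <= hi:
                    return False
            elif a.resseq != self.resseq:
                return False
        if self.resname is not None:
            names = {self.resname} if isinstance(self.resname, str) else set(self.resname)
            if a.resname not in names:
                return False
        if self.name is not None:
            names = {self.name} if isinstance(self.name, str) else set(self.name)
            if a.name not in names:
                return False
        if self.element is not None and a.element.upper() != self.element.upper():
            return False
        if self.heavy and a.is_hydrogen:
            return False
        if self.backbone is not None and a.is_backbone != self.backbone:
            return False
        if self.sidechain is not None and (not a.is_backbone) != self.sidechain:
            return False
        return True


def select_atoms(s: Structure, sel: Selection) -> list[int]:
    """Indices of atoms satisfying every predicate, in file order."""
    return [i for i, a in enumerate(s.atoms) if sel.matches(a)]


# ---------------------------------------------------------------------------
# parsing


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    # PDB v3.3 fixed columns (1-based): serial 7-11, name 13-16, altloc 17,
    # resname 18-20, chain 22, resseq 23-26, icode 27, x/y/z 31-54,
    # occupancy 55-60, bfactor 61-66, element 77-78.
    line = line.rstrip("\n").ljust(80)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        icode = line[26].strip()
        coord = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        bf_field = line[60:66].strip()
        bfactor = float(bf_field) if bf_field else 0.0
        element = line[76:78].strip()
    except ValueError as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper()
    if not name:
        raise PDBParseError(f"empty atom name at line {lineno}")
    occupancy = min(max(occupancy, 0.0), 1.0)
    return AtomRecord(
        serial=serial, name=name, altloc=altloc, resname=resname, chain=chain,
        resseq=resseq, icode=icode, element=element, coord=coord,
        occupancy=occupancy, bfactor=bfactor, het=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom: highest occupancy, tie → first altloc."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = a.atom_id
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                best[key] = a
    out = []
    for key in order:
        a = best[key]
        if a.altloc:
            a = replace(a, altloc="")
        out.append(a)
    return out


def _altloc_rank(altloc: str) -> float:
    # higher rank wins a tie; lexicographically earlier altloc ranks higher
    return -ord(altloc) if altloc else 1.0


def parse_pdb(source: str | io.TextIOBase) -> list[Structure]:
    """Parse a PDB character stream into one :class:`Structure` per model.

    Files without MODEL/ENDMDL yield a single structure.  Raises
    :class:`PDBParseError` for malformed fixed-width records and
    :class:`EmptyInputError` when no ATOM/HETATM record is present.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    models: list[Structure] = []
    current: list[AtomRecord] = []
    metadata: dict = {}
    model_id = 1
    in_model = False
    n_atom_lines = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                models.append(Structure(_resolve_altlocs(current), model_id, dict(metadata)))
                current = []
            try:
                model_id = int(line[10:14])
            except ValueError:
                model_id = len(models) + 1
            in_model = True
        elif rec == "ENDMDL":
            models.append(Structure(_resolve_altlocs(current), model_id, dict(metadata)))
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
            n_atom_lines += 1
        elif rec == "HEADER":
            metadata["header"] = line[10:].strip()
        elif rec == "REMARK" and "RESOLUTION." in line:
            try:
                metadata["resolution"] = float(line.split("RESOLUTION.")[1].split()[0])
            except (IndexError, ValueError):
                pass
    if current:
        models.append(Structure(_resolve_altlocs(current), model_id if in_model else 1, dict(metadata)))
    if n_atom_lines == 0:
        raise EmptyInputError("no ATOM/HETATM records in input")
    return [m for m in models if len(m) > 0]


def parse_pdb_file(path) -> list[Structure]:
    with open(path) as fh:
        return parse_pdb(fh)


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    record = "HETATM" if a.het else "ATOM  "
    # atom names of <4 chars start in column 14 unless element is 2 chars
    if len(a.name) >= 4 or len(a.element) == 2:
        name = f"{a.name:<4s}"[:4]
    else:
        name = f" {a.name:<3s}"
    return (
        f"{record}{serial:5d} {name}{a.altloc or ' ':1s}{a.resname:>3s} "
        f"{a.chain or ' ':1s}{a.resseq:4d}{a.icode or ' ':1s}   "
        f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def write_pdb(obj: Structure | Sequence[Structure] | Trajectory, stream=None) -> str:
    """Serialize structures (or a trajectory, as a multi-model file) to PDB text."""
    if isinstance(obj, Trajectory):
        models: Iterable[Structure] = (obj.frame_structure(i) for i in range(obj.n_frames))
        multi = obj.n_frames > 1
    elif isinstance(obj, Structure):
        models, multi = [obj], False
    else:
        models = list(obj)
        multi = len(models) > 1
    lines: list[str] = []
    for i, m in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for serial, a in enumerate(m.atoms, start=1):
            lines.append(_format_atom_line(a, serial))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def as_trajectory(models: Sequence[Structure], dt: float = 10.0) -> Trajectory:
    """Stack models sharing one atom table into a :class:`Trajectory`.

    Raises :class:`IncompatibleModelsError` if any model's atom identities
    (or their order) differ from the first model's.
    """
    if not models:
        raise ValueError("need at least one model")
    ref = [a.atom_id for a in models[0].atoms]
    for k, m in enumerate(models[1:], start=2):
        if [a.atom_id for a in m.atoms] != ref:
            raise IncompatibleModelsError(f"model {k} atom table differs from model 1")
    frames = np.stack([m.coords for m in models])
    return Trajectory(topology=models[0], frames=frames, dt=dt)


def concatenate(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Concatenate replicate trajectories sharing one topology."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    ref = [a.atom_id for a in trajectories[0].topology.atoms]
    for k, t in enumerate(trajectories[1:], start=2):
        if [a.atom_id for a in t.topology.atoms] != ref:
            raise IncompatibleModelsError(f"trajectory {k} atom table differs from trajectory 1")
    frames = np.concatenate([t.frames for t in trajectories])
    return Trajectory(topology=trajectories[0].topology, frames=frames, dt=trajectories[0].dt)
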