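"""Structure and trajectory I/O for fixed-column PDB files.

Single-MODEL files parse to :class:`Structure`; multi-MODEL files parse to
:class:`Trajectory` (frame times from an optional JSON sidecar, else assigned
uniformly).  Van der Waals radii are assigned from a :class:`RadiusTable` as a
separate, explicit step because every downstream geometric analysis (pore
profiling, solvent accessibility) depends on them.

Residue numbering follows author numbering (1-based); ranges are inclusive.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "RadiusTable",
    "PDBParseError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "assign_radii",
    "select",
    "residue_class",
    "RESIDUE_CLASSES",
]

#: Residue classes used throughout the contact analyses.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "basic": frozenset({"ARG", "LYS"}),
    "acidic": frozenset({"ASP", "GLU"}),
    "hydroxyl": frozenset({"SER", "THR", "TYR"}),
}

#: Atoms treated as backbone for side-chain selections.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBParseError(ValueError):
    """Malformed PDB input (message names the offending line number)."""


class PDBFormatError(ValueError):
    """Structure cannot be represented in PDB fixed-column layout."""


def residue_class(resname: str) -> str | None:
    """Return 'basic' / 'acidic' / 'hydroxyl' for *resname*, else ``None``."""
    for cls, members in RESIDUE_CLASSES.items():
        if resname in members:
            return cls
    return None


@dataclass
class Atom:
    """A typed PDB atom record.

    ``vdw_radius`` is NaN until :func:`assign_radii` sets it.  ``element`` is
    inferred from the atom name when the element column is blank.
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    coords: np.ndarray
    insertion_code: str = ""
    element: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    vdw_radius: float = math.nan

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: coords must be a finite 3-vector")
        if not self.element:
            self.element = _infer_element(self.name)
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name!r}: element could not be resolved")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


def _infer_element(name: str) -> str:
    """Infer the element from a PDB atom name (columns 13-16).

    Standard PDB right-justifies one-letter elements into column 14, so a
    name like ' CA ' is carbon while 'CA  ' would be calcium.  We receive the
    already-stripped name plus a hint of whether column 13 was blank, which is
    lost here, so we use the common heuristic: leading digits are stripped and
    the first letter wins unless the full name matches a two-letter element.
    """
    stripped = re.sub(r"^[0-9']+", "", name.strip())
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "CL", "BR", "NA", "SE"} and len(name.strip()) <= 2:
        return two.capitalize()
    return stripped[0].upper()


class Structure:
    """An ordered collection of atoms with a residue index.

    Atom identity (chain, residue key, atom name, altloc) must be unique and
    residues must be contiguous runs of atoms.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        self._build_index()

    def _build_index(self) -> None:
        seen: set[tuple] = set()
        self.residue_index: dict[tuple[str, int, str], list[int]] = {}
        last_key = None
        for i, atom in enumerate(self.atoms):
            ident = (atom.chain_id, atom.residue_key, atom.name, atom.altloc)
            if ident in seen:
                raise ValueError(f"duplicate atom identity {ident}")
            seen.add(ident)
            key = atom.residue_key
            if key in self.residue_index and key != last_key:
                raise ValueError(f"residue {key} is not a contiguous run of atoms")
            self.residue_index.setdefault(key, []).append(i)
            last_key = key

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {coords.shape} != ({len(self.atoms)}, 3)")
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz.copy()

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.set_coords(coords)
        return out

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return list(self.residue_index)

    def residue_atoms(self, key: tuple[str, int, str]) -> list[Atom]:
        if key not in self.residue_index:
            raise KeyError(f"residue {key} not in structure")
        return [self.atoms[i] for i in self.residue_index[key]]

    def residue_name(self, key: tuple[str, int, str]) -> str:
        return self.residue_atoms(key)[0].residue_name

    def residues_of_class(self, cls: str) -> list[tuple[str, int, str]]:
        if cls not in RESIDUE_CLASSES:
            raise ValueError(f"unknown residue class {cls!r}")
        members = RESIDUE_CLASSES[cls]
        return [k for k in self.residue_index if self.residue_name(k) in members]

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms])

    def __repr__(self) -> str:
        return f"<Structure: {len(self.atoms)} atoms, {len(self.residue_index)} residues>"


class Trajectory:
    """A topology plus ordered coordinate frames with strictly increasing times (ns)."""

    def __init__(self, topology: Structure, frames: Sequence[np.ndarray], times: Sequence[float]):
        self.topology = topology
        self.frames = [np.asarray(f, dtype=float) for f in frames]
        self.times = np.asarray(times, dtype=float)
        n = len(topology)
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {i} has shape {f.shape}, expected ({n}, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must be congruent")
        if len(self.times) and (self.times[0] < 0 or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must start >= 0 and be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def __repr__(self) -> str:
        return f"<Trajectory: {len(self.frames)} frames x {len(self.topology)} atoms>"


@dataclass
class RadiusTable:
    """Van der Waals radii by element, with atom-name overrides and a fallback.

    The defaults (Bondi-flavoured) are embedded so results are reproducible;
    any entry can be overridden via :meth:`from_tsv` or the constructor.
    """

    by_element: dict[str, float] = field(
        default_factory=lambda: {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
    )
    by_atom_name: dict[str, float] = field(default_factory=dict)
    default: float = 1.70

    def __post_init__(self) -> None:
        for el, r in self.by_element.items():
            if not (0.5 < r < 3.0):
                raise ValueError(f"radius for {el} out of (0.5, 3.0) A: {r}")
        missing = {"H", "C", "N", "O", "S", "P"} - set(self.by_element)
        if missing:
            raise ValueError(f"radius table must cover H,C,N,O,S,P; missing {sorted(missing)}")

    def lookup(self, atom: Atom) -> float:
        if atom.name in self.by_atom_name:
            return self.by_atom_name[atom.name]
        el = atom.element.upper()
        if el in self.by_element:
            return self.by_element[el]
        logger.warning("element %r not in radius table; using default %.2f A", atom.element, self.default)
        return self.default

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "RadiusTable":
        table = cls(**kwargs)
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            el, radius = line.split("\t")[:2]
            table.by_element[el.upper()] = float(radius)
        return table


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom | None:
    """Parse one ATOM/HETATM record; returns None for dropped altlocs."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if altloc not in ("", "A"):
        return None
    return Atom(
        serial=serial, name=name, residue_name=resname, chain_id=chain,
        residue_number=resnum, insertion_code=icode, coords=np.array([x, y, z]),
        element=element, altloc="", occupancy=occ, b_factor=bfac,
    )


def read_pdb(source: str | Path, times_sidecar: str | Path | None = None,
             duration_ns: float = 1.0) -> Structure | Trajectory:
    """Read a PDB file (or raw text) into a Structure or Trajectory.

    Multi-MODEL input yields a Trajectory; frame times come from a JSON
    sidecar ``{"times_ns": [...]}`` (auto-detected as ``<file>.times.json``
    next to a path input) or are assigned uniformly over ``duration_ns``.
    Alternate locations other than blank/'A' are dropped (count logged).
    """
    path: Path | None = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        path = Path(source)
        text = path.read_text()
    else:
        text = str(source)

    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    saw_model = False
    n_dropped = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            saw_model = True
            in_model = True
            current = []
        elif record == "ENDMDL":
            in_model = False
            models.append(current)
        elif record in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            if atom is None:
                n_dropped += 1
            else:
                current.append(atom)
    if n_dropped:
        logger.info("dropped %d alternate-location atom records", n_dropped)
    if not saw_model:
        if not current:
            raise PDBParseError("no ATOM records found")
        return Structure(current)
    if in_model:
        raise PDBParseError("unterminated MODEL block (missing ENDMDL)")
    if not models or not models[0]:
        raise PDBParseError("no ATOM records found in MODEL blocks")

    topo = Structure(models[0])
    ref_ident = [(a.chain_id, a.residue_key, a.name) for a in models[0]]
    frames = []
    for m, atoms in enumerate(models):
        ident = [(a.chain_id, a.residue_key, a.name) for a in atoms]
        if ident != ref_ident:
            raise PDBParseError(f"MODEL block {m + 1} is not congruent with MODEL 1")
        frames.append(np.array([a.coords for a in atoms]))

    times = None
    if times_sidecar is None and path is not None:
        candidate = path.with_suffix(path.suffix + ".times.json")
        if candidate.exists():
            times_sidecar = candidate
    if times_sidecar is not None:
        times = np.asarray(json.loads(Path(times_sidecar).read_text())["times_ns"], dtype=float)
        if len(times) != len(frames):
            raise PDBParseError(
                f"sidecar has {len(times)} times for {len(frames)} MODEL blocks")
    if times is None:
        times = np.linspace(0.0, duration_ns, len(frames))
    return Trajectory(topo, frames, times)


def _format_coord(value: float) -> str:
    """Format a coordinate into the 8-column PDB field (3 decimals preferred)."""
    if not np.isfinite(value) or abs(value) > 9999.999:
        raise PDBFormatError(f"coordinate {value} exceeds PDB field width")
    for fmt in ("%8.3f", "%8.2f", "%8.1f"):
        s = fmt % value
        if len(s) == 8:
            return s
    raise PDBFormatError(f"coordinate {value} exceeds PDB field width")


def _atom_line(atom: Atom, serial: int) -> str:
    name = atom.name
    # standard alignment: 1-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    return (
        f"ATOM  {serial:5d} {name:<4s}{atom.altloc or ' ':1s}{atom.residue_name:<3s} "
        f"{atom.chain_id:1s}{atom.residue_number:4d}{atom.insertion_code or ' ':1s}   "
        f"{_format_coord(atom.coords[0])}{_format_coord(atom.coords[1])}{_format_coord(atom.coords[2])}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          {atom.element.upper():>2s}"
    )


def write_pdb(obj: Structure | Trajectory, path: str | Path | None = None) -> str:
    """Serialize a Structure or Trajectory to PDB text (and optionally a file).

    Round trip through :func:`read_pdb` reproduces atom identities and
    coordinates to PDB precision (3 decimals).  Trajectory times are written
    to a ``.times.json`` sidecar when *path* is given.
    """
    lines: list[str] = []
    if isinstance(obj, Structure):
        for i, atom in enumerate(obj.atoms, start=1):
            lines.append(_atom_line(atom, i))
        lines.append("END")
    elif isinstance(obj, Trajectory):
        for m in range(len(obj)):
            lines.append(f"MODEL     {m + 1:4d}")
            frame = obj.frames[m]
            for i, atom in enumerate(obj.topology.atoms):
                tmp = atom.copy()
                tmp.coords = frame[i]
                lines.append(_atom_line(tmp, i + 1))
            lines.append("ENDMDL")
        lines.append("END")
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
        if isinstance(obj, Trajectory):
            sidecar = Path(path).with_suffix(Path(path).suffix + ".times.json")
            sidecar.write_text(json.dumps({"times_ns": list(map(float, obj.times))}))
    return text


def assign_radii(structure: Structure, table: RadiusTable | None = None) -> Structure:
    """Assign a van der Waals radius to every atom (in place; returns structure)."""
    table = table or RadiusTable()
    for atom in structure.atoms:
        atom.vdw_radius = table.lookup(atom)
    return structure


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _parse_selection(spec: str):
    """Parse a conjunctive selection like ``chain A and resid 10-20 and name CA``.

    Supported predicates: ``chain <id>``, ``resid <n>`` / ``resid <a>-<b>``,
    ``name <atom name>``, ``class <basic|acidic|hydroxyl>``, ``all``.
    """
    predicates = []
    clauses = [c.strip() for c in spec.strip().split(" and ")]
    for clause in clauses:
        if not clause:
            raise ValueError(f"empty clause in selection {spec!r}")
        parts = clause.split()
        kw = parts[0].lower()
        if kw == "all" and len(parts) == 1:
            continue
        if len(parts) != 2:
            raise ValueError(f"invalid selection clause {clause!r}")
        arg = parts[1]
        if kw == "chain":
            predicates.append(lambda a, c=arg: a.chain_id == c)
        elif kw == "resid":
            m = _RANGE_RE.match(arg)
            if not m:
                raise ValueError(f"invalid residue range {arg!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            predicates.append(lambda a, lo=lo, hi=hi: lo <= a.residue_number <= hi)
        elif kw == "name":
            predicates.append(lambda a, n=arg: a.name == n)
        elif kw == "class":
            if arg not in RESIDUE_CLASSES:
                raise ValueError(f"unknown residue class {arg!r}")
            members = RESIDUE_CLASSES[arg]
            predicates.append(lambda a, m=members: a.residue_name in m)
        else:
            raise ValueError(f"unknown selection keyword {kw!r}")
    return predicates


def select(structure: Structure, spec: str) -> list[int]:
    """Return indices of atoms matching the selection expression (may be empty)."""
    predicates = _parse_selection(spec)
    return [i for i, a in enumerate(structure.atoms) if all(p(a) for p in predicates)]
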