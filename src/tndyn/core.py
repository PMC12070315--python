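"""Topology/trajectory data model, multi-model PDB and XYZ I/O, atom selections.

The model is deliberately minimal: a :class:`Topology` is an ordered list of
atoms tagged with a chain *role* (TnC, TnI, TnT, ligand, other), and a
:class:`Trajectory` binds an ``(n_frames, n_atoms, 3)`` coordinate array in
Angstrom to one topology.  Residue numbering is 1-based and taken verbatim
from the input file; the canonical troponin-core numbering (TnC 1-161,
TnI 1-169, TnT 202-288) is expressed through chain roles plus residue
ranges, never by renumbering.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "Selection",
    "SelectionTerm",
    "TopologyError",
    "PDBFormatError",
    "SelectionError",
    "parse_pdb_models",
    "write_pdb_models",
    "read_xyz_frames",
    "write_xyz_frames",
    "resolve_selection",
    "tn_resid",
    "tni_switch",
    "tnt_cterm",
    "calpha",
    "ligand_atoms",
    "ROLE_TNC",
    "ROLE_TNI",
    "ROLE_TNT",
    "ROLE_LIGAND",
]

ROLE_TNC = "TnC"
ROLE_TNI = "TnI"
ROLE_TNT = "TnT"
ROLE_LIGAND = "ligand"
ROLE_OTHER = "other"

#: Standard atomic masses (amu) for the elements a reduced troponin model uses.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "MG": 24.305,
    "K": 39.098,
    "CA": 40.078,
    "CL": 35.45,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
}
DEFAULT_MASS = 12.0


class TopologyError(ValueError):
    """Structural inconsistency in a topology or trajectory."""


class PDBFormatError(ValueError):
    """Malformed PDB record or value that does not fit the PDB format."""


class SelectionError(ValueError):
    """A selection that resolves to no atoms, or references unknown roles."""


def mass_of(element: str) -> float:
    m = ELEMENT_MASSES.get(element.upper())
    if m is None:
        logger.warning("unknown element %r: defaulting mass to %.1f amu", element, DEFAULT_MASS)
        return DEFAULT_MASS
    return m


@dataclass(frozen=True)
class Atom:
    index: int          # 1-based, contiguous
    name: str
    element: str
    residue_index: int  # 1-based, verbatim from input
    residue_name: str
    chain_id: str
    mass: float


@dataclass
class Topology:
    """Ordered atom list plus a chain_id -> role map.

    Invariants (checked on construction): atom indices are unique and
    contiguous from 1; every chain referenced by an atom has a role;
    residue indices are non-decreasing within each chain.
    """

    atoms: tuple[Atom, ...]
    chain_roles: dict[str, str]

    def __post_init__(self) -> None:
        self.atoms = tuple(self.atoms)
        indices = [a.index for a in self.atoms]
        if indices != list(range(1, len(indices) + 1)):
            raise TopologyError("atom_index values must be unique and contiguous from 1")
        last_resid: dict[str, int] = {}
        for a in self.atoms:
            if a.chain_id not in self.chain_roles:
                raise TopologyError(f"chain {a.chain_id!r} has no role in chain_roles")
            prev = last_resid.get(a.chain_id)
            if prev is not None and a.residue_index < prev:
                raise TopologyError(
                    f"residue_index decreases within chain {a.chain_id!r} "
                    f"({prev} -> {a.residue_index})"
                )
            last_resid[a.chain_id] = a.residue_index

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def role_of(self, atom: Atom) -> str:
        return self.chain_roles[atom.chain_id]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    """Coordinates (Angstrom) for an ordered list of frames over one topology."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    frame_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TopologyError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"atom count mismatch: topology has {self.topology.n_atoms} atoms, "
                f"frames have {self.coordinates.shape[1]}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise TopologyError("trajectory contains non-finite coordinates")
        if self.frame_labels is not None and len(self.frame_labels) != self.n_frames:
            raise TopologyError("frame_labels length must equal the number of frames")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column, multi-model)
# ---------------------------------------------------------------------------

def _parse_atom_record(line: str, lineno: int) -> tuple[str, str, str, int, str, str, float, float, float, str]:
    try:
        record = line[0:6].strip()
        name = line[12:16].strip()
        altloc = line[16:17]
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "_"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: unparseable {line[0:6].strip()} record: {exc}") from exc
    if not element:
        # derive from the atom name: first alphabetic character, honouring
        # two-letter elements written flush left in a 4-char name field
        stripped = line[12:16]
        two = stripped[:2].strip()
        if two.upper() in ELEMENT_MASSES and not two[0].isdigit() and len(two) == 2:
            element = two
        else:
            element = next((c for c in name if c.isalpha()), "C")
    return record, name, altloc, resid, resname, chain, x, y, z, element


def parse_pdb_models(source, chain_roles: dict[str, str] | None = None) -> Trajectory:
    """Parse a multi-model PDB into a trajectory.

    ``source`` is a text stream, a string of PDB text, or a path-like.  The
    topology is built from the first model; each MODEL/ENDMDL block becomes
    one frame.  A bare coordinate block without MODEL keywords yields a
    single-frame trajectory.  Chains of HETATM records default to role
    ``"ligand"``; ATOM chains to ``"other"`` — pass ``chain_roles`` to assign
    TnC/TnI/TnT roles.  altLoc 'A' or blank is kept, others dropped.
    """
    text = _as_text(source)
    lines = text.splitlines()

    frames: list[list[tuple[float, float, float]]] = []
    atoms: list[Atom] = []
    hetatm_chains: set[str] = set()
    seen_chains: list[str] = []
    current: list[tuple[float, float, float]] | None = None
    in_model = False
    model_labels: list[str] = []

    def _close(block: list | None) -> None:
        if block:
            if frames and len(block) != len(frames[0]):
                raise TopologyError(
                    f"atom count mismatch: model {len(frames) + 1} has {len(block)} atoms, "
                    f"model 1 has {len(frames[0])}"
                )
            frames.append(block)

    for lineno, line in enumerate(lines, start=1):
        rec = line[0:6].strip()
        if rec == "MODEL":
            _close(current)
            current = []
            in_model = True
            model_labels.append(line[6:].strip())
        elif rec == "ENDMDL":
            _close(current)
            current = None
        elif rec in ("ATOM", "HETATM"):
            parsed = _parse_atom_record(line, lineno)
            record, name, altloc, resid, resname, chain, x, y, z, element = parsed
            if altloc not in (" ", "", "A"):
                continue
            if current is None:
                if frames and not in_model:
                    raise PDBFormatError(f"line {lineno}: coordinate record outside MODEL block")
                current = []
            current.append((x, y, z))
            if not frames:  # first model: build topology
                atoms.append(
                    Atom(
                        index=len(atoms) + 1,
                        name=name,
                        element=element,
                        residue_index=resid,
                        residue_name=resname,
                        chain_id=chain,
                        mass=mass_of(element),
                    )
                )
                if chain not in seen_chains:
                    seen_chains.append(chain)
                if record == "HETATM":
                    hetatm_chains.add(chain)
    _close(current)

    if not frames:
        raise PDBFormatError("no coordinate records found")

    roles = {c: (ROLE_LIGAND if c in hetatm_chains else ROLE_OTHER) for c in seen_chains}
    if chain_roles:
        roles.update({c: r for c, r in chain_roles.items() if c in roles})
    topo = Topology(atoms=tuple(atoms), chain_roles=roles)
    coords = np.array(frames, dtype=float)
    labels = model_labels if len(model_labels) == len(frames) else None
    return Trajectory(topology=topo, coordinates=coords, frame_labels=labels)


_PDB_COORD_MIN, _PDB_COORD_MAX = -999.999, 9999.999


def write_pdb_models(trajectory: Trajectory, frame_indices: Sequence[int] | None = None) -> str:
    """Serialize frames as a multi-model PDB string.

    Round-trip contract: ``parse_pdb_models(write_pdb_models(t))`` reproduces
    the topology exactly and coordinates to 0.001 A (PDB column precision).
    ``frame_indices=[]`` yields a header-only file with zero models.
    """
    n = trajectory.n_frames
    if frame_indices is None:
        frame_indices = range(n)
    out = io.StringIO()
    out.write("REMARK   1 written by tndyn\n")
    topo = trajectory.topology
    for model_no, fi in enumerate(frame_indices, start=1):
        if not (-n <= fi < n):
            raise IndexError(f"frame index {fi} out of range for {n} frames")
        frame = trajectory.coordinates[fi]
        out.write(f"MODEL {model_no:>8}\n")
        for atom, (x, y, z) in zip(topo.atoms, frame):
            if not all(_PDB_COORD_MIN <= v <= _PDB_COORD_MAX for v in (x, y, z)):
                raise PDBFormatError(
                    f"coordinate ({x:.3f}, {y:.3f}, {z:.3f}) exceeds PDB field width"
                )
            rec = "HETATM" if topo.role_of(atom) == ROLE_LIGAND else "ATOM"
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
            out.write(
                f"{rec:<6}{atom.index % 100000:>5} {name}"
                f" {atom.residue_name:>3} {atom.chain_id[0]}{atom.residue_index:>4}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element[:2]:>2}\n"
            )
        out.write("ENDMDL\n")
    out.write("END\n")
    return out.getvalue()


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" in s or s.lstrip().startswith(("ATOM", "HETATM", "MODEL", "REMARK", "HEADER")):
        return s
    with open(s, "r") as fh:
        return fh.read()


# ---------------------------------------------------------------------------
# Whitespace-separated XYZ fixture format
# ---------------------------------------------------------------------------

def write_xyz_frames(trajectory: Trajectory, frame_indices: Sequence[int] | None = None) -> str:
    """Lightweight frame format: per frame a header line ``n_atoms`` then one
    ``name x y z`` line per atom.  Carries no topology beyond atom names."""
    if frame_indices is None:
        frame_indices = range(trajectory.n_frames)
    out = io.StringIO()
    for fi in frame_indices:
        frame = trajectory.coordinates[fi]
        out.write(f"{trajectory.topology.n_atoms}\n")
        for atom, (x, y, z) in zip(trajectory.topology.atoms, frame):
            out.write(f"{atom.name} {x:.6f} {y:.6f} {z:.6f}\n")
    return out.getvalue()


def read_xyz_frames(source, topology: Topology) -> Trajectory:
    """Read frames written by :func:`write_xyz_frames` against a known topology."""
    text = _as_text(source)
    tokens = text.split("\n")
    frames: list[np.ndarray] = []
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        i += 1
        if not line:
            continue
        try:
            n = int(line)
        except ValueError as exc:
            raise PDBFormatError(f"XYZ header line {i}: expected atom count, got {line!r}") from exc
        if n != topology.n_atoms:
            raise TopologyError(
                f"atom count mismatch: XYZ frame has {n}, topology has {topology.n_atoms}"
            )
        block = np.empty((n, 3), dtype=float)
        for k in range(n):
            parts = tokens[i].split()
            i += 1
            try:
                block[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except (IndexError, ValueError) as exc:
                raise PDBFormatError(f"XYZ line {i}: unparseable atom line") from exc
        frames.append(block)
    if not frames:
        raise PDBFormatError("no XYZ frames found")
    return Trajectory(topology=topology, coordinates=np.array(frames))


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionTerm:
    """One predicate over atoms: match chain role, optionally a residue range
    (inclusive) and an atom-name set."""

    role: str
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None

    def matches(self, topology: Topology, atom: Atom) -> bool:
        if topology.role_of(atom) != self.role:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_index <= hi):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True


@dataclass(frozen=True)
class Selection:
    """Named union of :class:`SelectionTerm` predicates.

    Resolution is a pure function of (topology, selection) and always yields
    an ascending, duplicate-free atom-position list; an empty resolution is
    an error at the point of use.
    """

    name: str
    terms: tuple[SelectionTerm, ...]

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(name=f"{self.name}|{other.name}", terms=self.terms + other.terms)


def resolve_selection(topology: Topology, selection: Selection) -> np.ndarray:
    """Resolve to 0-based atom positions (ascending).  Raises
    :class:`SelectionError` on an empty resolution, naming the selection."""
    hits = [
        i
        for i, atom in enumerate(topology.atoms)
        if any(t.matches(topology, atom) for t in selection.terms)
    ]
    if not hits:
        raise SelectionError(f"empty selection: {selection.name!r} matches no atoms")
    return np.array(hits, dtype=int)


def tn_resid(role: str, first: int, last: int, atom_names: Iterable[str] | None = None) -> Selection:
    names = frozenset(atom_names) if atom_names is not None else None
    return Selection(
        name=f"{role}_{first}..{last}" + (f"[{','.join(sorted(names))}]" if names else ""),
        terms=(SelectionTerm(role=role, residue_range=(first, last), atom_names=names),),
    )


def tni_switch() -> Selection:
    """cTnI switch-peptide region, residues 154-164 (all atoms)."""
    return Selection("TnI_switch", (SelectionTerm(ROLE_TNI, (154, 164)),))


def tnt_cterm() -> Selection:
    """cTnT C-terminal residues 276-278 (all atoms)."""
    return Selection("TnT_Cterm", (SelectionTerm(ROLE_TNT, (276, 278)),))


def calpha(role: str, residue_range: tuple[int, int] | None = None) -> Selection:
    return Selection(
        name=f"calpha({role})" + (f"{residue_range}" if residue_range else ""),
        terms=(SelectionTerm(role, residue_range, frozenset({"CA"})),),
    )


def protein_calpha() -> Selection:
    """All protein-chain C-alpha atoms (every non-ligand role)."""
    terms = tuple(
        SelectionTerm(role, None, frozenset({"CA"}))
        for role in (ROLE_TNC, ROLE_TNI, ROLE_TNT, ROLE_OTHER)
    )
    return Selection("protein_calpha", terms)


def ligand_atoms() -> Selection:
    return Selection("ligand", (SelectionTerm(ROLE_LIGAND),))
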