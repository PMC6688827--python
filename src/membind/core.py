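"""Domain types and structure/trajectory IO.

The in-memory model deliberately decouples particle metadata (:class:`Topology`)
from coordinates (:class:`Frame`, :class:`Trajectory`).  All lengths are in nm
and times in ns; file readers convert from the Angstrom/ps conventions of the
underlying formats.  Reading and writing of PDB/GRO structures and
XTC/TRR/DCD/multi-model-PDB trajectories is delegated to MDAnalysis.

A small selection language (``species``, ``resid``, ``subunit``, ``name``,
``headgroup`` combined with ``and``/``or``/``not`` and parentheses) selects
particles deterministically, and :class:`ResidueMap` implements the
simulation-to-crystal-structure residue renumbering used throughout the
kinase analyses (simulation residues 1-253 are crystal residues 57-309;
simulation residues 254-324 are crystal residues 356-426, the activation-loop
region rebuilt by homology modelling).
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SPECIES_CLASSES",
    "SpeciesTable",
    "DEFAULT_SPECIES_TABLE",
    "Particle",
    "Topology",
    "Frame",
    "Trajectory",
    "ResidueMap",
    "DEFAULT_RESIDUE_MAP",
    "DIMER_SUBUNIT_OFFSET",
    "FormatError",
    "TopologyError",
    "SelectionError",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "select",
    "map_residue",
]

#: Recognised particle species classes.
SPECIES_CLASSES = ("protein", "PC", "PS", "PI4P", "PIP2", "ion", "solvent")

#: Default offset between equivalent residues of the two kinase subunits in a
#: dimer: the catalytic lysine is simulation residue 182 in subunit A and 505
#: in subunit B, hence 505 - 182 = 323.  Overridable wherever it is consumed.
DIMER_SUBUNIT_OFFSET = 323


class FormatError(ValueError):
    """A structure or trajectory file could not be parsed."""


class TopologyError(ValueError):
    """Coordinates and topology are inconsistent."""


class SelectionError(ValueError):
    """A selection expression failed to parse or evaluate."""


# ---------------------------------------------------------------------------
# species classification
# ---------------------------------------------------------------------------

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HIE", "HID", "HIP", "CYX", "MSE",
}


@dataclass(frozen=True)
class SpeciesTable:
    """Editable lookup: residue name -> species class, plus headgroup names.

    ``headgroup_names`` maps each lipid class to the particle names flagged as
    headgroup.  Defaults cover coarse-grained bead names (phosphate ``PO4``,
    inositol ring ``C1/C2/C3``, 4'/5'-phosphates ``P4``/``P5``) and the
    phosphorus/inositol heavy atoms of common atomistic lipid topologies.
    """

    residues: dict[str, str]
    headgroup_names: dict[str, frozenset[str]]

    def classify(self, residue_name: str) -> str:
        name = residue_name.upper()
        if name in self.residues:
            return self.residues[name]
        if name in _AMINO_ACIDS:
            return "protein"
        warnings.warn(
            f"unknown residue name {residue_name!r}: classified as solvent",
            stacklevel=2,
        )
        return "solvent"

    def is_headgroup(self, species_class: str, particle_name: str) -> bool:
        names = self.headgroup_names.get(species_class)
        return names is not None and particle_name.upper() in names


DEFAULT_SPECIES_TABLE = SpeciesTable(
    residues={
        # phosphatidylcholine
        "POPC": "PC", "DOPC": "PC", "DPPC": "PC", "DLPC": "PC", "PC": "PC",
        # phosphatidylserine
        "POPS": "PS", "DOPS": "PS", "PS": "PS",
        # phosphatidylinositol 4-phosphate (substrate)
        "POP4": "PI4P", "PI4P": "PI4P", "PAP4": "PI4P", "POPI4": "PI4P",
        # phosphatidylinositol 4,5-bisphosphate (product)
        "POP2": "PIP2", "PIP2": "PIP2", "PAP2": "PIP2", "POPI25": "PIP2",
        # ions
        "NA": "ion", "NA+": "ion", "CL": "ion", "CL-": "ion", "ION": "ion",
        "K": "ion", "K+": "ion", "CA": "ion", "CA2+": "ion", "MG": "ion",
        # solvent
        "W": "solvent", "WF": "solvent", "SOL": "solvent", "WAT": "solvent",
        "HOH": "solvent", "TIP3": "solvent",
    },
    headgroup_names={
        "PC": frozenset({"NC3", "PO4", "P", "N"}),
        "PS": frozenset({"CNO", "PO4", "P", "N"}),
        "PI4P": frozenset({"C1", "C2", "C3", "PO4", "P4", "P",
                           "RP1", "RP2", "RP3"}),
        "PIP2": frozenset({"C1", "C2", "C3", "PO4", "P4", "P5", "P",
                           "RP1", "RP2", "RP3"}),
    },
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

Particle = namedtuple(
    "Particle",
    "particle_id name residue_index residue_name subunit mass species_class headgroup",
)


@dataclass
class Topology:
    """Column-wise particle metadata; particle ids are the array indices."""

    names: np.ndarray            # str
    residue_indices: np.ndarray  # int, 1-based
    residue_names: np.ndarray    # str
    subunits: np.ndarray         # str label
    masses: np.ndarray           # amu
    species: np.ndarray          # str, one of SPECIES_CLASSES
    headgroup: np.ndarray        # bool

    def __post_init__(self) -> None:
        n = len(self.names)
        arrays = (self.residue_indices, self.residue_names, self.subunits,
                  self.masses, self.species, self.headgroup)
        if any(len(a) != n for a in arrays):
            raise TopologyError("topology columns have unequal lengths")
        bad = set(np.unique(self.species)) - set(SPECIES_CLASSES)
        if bad:
            raise TopologyError(f"unknown species classes: {sorted(bad)}")
        if np.any(self.headgroup & (self.species == "protein")):
            raise TopologyError("headgroup flag set on protein particles")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_particles(self) -> int:
        return len(self.names)

    @property
    def particles(self) -> list[Particle]:
        return [
            Particle(i, self.names[i], int(self.residue_indices[i]),
                     self.residue_names[i], self.subunits[i],
                     float(self.masses[i]), self.species[i],
                     bool(self.headgroup[i]))
            for i in range(len(self))
        ]

    def concat(self, other: "Topology") -> "Topology":
        """Concatenate particles; the other topology's residues are renumbered
        to continue after this one's largest residue index."""
        shift = int(self.residue_indices.max(initial=0))
        return Topology(
            names=np.concatenate([self.names, other.names]),
            residue_indices=np.concatenate(
                [self.residue_indices, other.residue_indices + shift]),
            residue_names=np.concatenate(
                [self.residue_names, other.residue_names]),
            subunits=np.concatenate([self.subunits, other.subunits]),
            masses=np.concatenate([self.masses, other.masses]),
            species=np.concatenate([self.species, other.species]),
            headgroup=np.concatenate([self.headgroup, other.headgroup]),
        )


@dataclass
class Frame:
    """One time-stamped coordinate set (nm, ns) in an orthorhombic box."""

    time: float
    coordinates: np.ndarray  # (N, 3) nm
    box: np.ndarray          # (3,) edge lengths nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")


@dataclass
class Trajectory:
    """A topology plus time-ordered frames."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_particles
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise TopologyError(
                    f"frame has {f.coordinates.shape[0]} coordinates for "
                    f"{n} particles")
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def coordinates(self) -> np.ndarray:
        """(n_frames, N, 3) stacked coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# residue renumbering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueMap:
    """Piecewise-constant offset map between simulation and PDB numbering.

    ``segments`` are ``(sim_start, sim_end, pdb_offset)`` with inclusive,
    1-based bounds: a simulation residue *i* in a segment maps to PDB residue
    ``i + pdb_offset``.
    """

    segments: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        segs = sorted(self.segments)
        for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
            if s1 <= e0:
                raise ValueError("segments overlap in simulation numbering")
        pdb_ranges = sorted((s + off, e + off) for s, e, off in segs)
        for (_, e0), (s1, _) in zip(pdb_ranges, pdb_ranges[1:]):
            if s1 <= e0:
                raise ValueError("mapping is not injective in PDB numbering")

    def to_pdb(self, sim_index: int) -> int:
        for start, end, offset in self.segments:
            if start <= sim_index <= end:
                return sim_index + offset
        raise IndexError(f"simulation residue {sim_index} is in no segment")

    def to_sim(self, pdb_index: int) -> int:
        for start, end, offset in self.segments:
            if start + offset <= pdb_index <= end + offset:
                return pdb_index - offset
        raise IndexError(f"PDB residue {pdb_index} is in no segment")


#: The kinase construct's renumbering: crystal-structure numbering starts at
#: residue 57, and the modelled activation-loop region (simulation 254-324)
#: resumes at crystal residue 356 after the removed insert.
DEFAULT_RESIDUE_MAP = ResidueMap(segments=((1, 253, 56), (254, 324, 102)))


def map_residue(residue_map: ResidueMap, sim_index: int) -> int:
    """Simulation residue number -> PDB residue number."""
    return residue_map.to_pdb(sim_index)


# ---------------------------------------------------------------------------
# file IO (MDAnalysis-backed)
# ---------------------------------------------------------------------------

_NM_PER_ANGSTROM = 0.1
_NS_PER_PS = 1e-3
#: Mass assigned to particles whose element cannot be inferred (typical
#: MARTINI coarse-grained bead mass).
_DEFAULT_BEAD_MASS = 72.0


def _import_mda():
    import MDAnalysis as mda
    return mda


def _universe_to_topology(u, species_table: SpeciesTable) -> Topology:
    atoms = u.atoms
    names = atoms.names.astype(str)
    resnames = atoms.resnames.astype(str)
    resids = atoms.resids.astype(int)
    try:
        subunits = atoms.chainIDs.astype(str)
    except Exception:
        try:
            subunits = atoms.segids.astype(str)
        except Exception:
            subunits = np.full(len(atoms), "A")
    subunits = np.array([s if s.strip() else "A" for s in subunits])
    try:
        masses = atoms.masses.astype(float)
        masses = np.where(np.isfinite(masses) & (masses > 0),
                          masses, _DEFAULT_BEAD_MASS)
    except Exception:
        masses = np.full(len(atoms), _DEFAULT_BEAD_MASS)
    species = np.array([species_table.classify(rn) for rn in resnames])
    headgroup = np.array([
        species_table.is_headgroup(sp, nm)
        for sp, nm in zip(species, names)
    ])
    return Topology(names=names, residue_indices=resids,
                    residue_names=resnames, subunits=subunits, masses=masses,
                    species=species, headgroup=headgroup)


def _box_from_dimensions(dims) -> np.ndarray:
    if dims is None or not np.all(np.asarray(dims[:3]) > 0):
        raise FormatError("structure file has no usable box")
    return np.asarray(dims[:3], dtype=float) * _NM_PER_ANGSTROM


def load_structure(path: str | Path, format: str | None = None,
                   species_table: SpeciesTable = DEFAULT_SPECIES_TABLE,
                   ) -> tuple[Topology, Frame]:
    """Read a PDB or GRO file into a (Topology, Frame) pair.

    Species classes are inferred from residue names via *species_table*;
    unknown residue names are classified as solvent with a warning.  The box
    is taken from the CRYST1 record (PDB) or the box line (GRO).
    """
    mda = _import_mda()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kwargs = {}
    if format is not None:
        kwargs["format"] = format
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="MDAnalysis")
        try:
            u = mda.Universe(str(path), **kwargs)
        except Exception as exc:  # mda raises many flavours of parse error
            raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise FormatError(f"{path} contains no particles")
    topology = _universe_to_topology(u, species_table)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="MDAnalysis")
        frame = Frame(time=float(u.trajectory.ts.time) * _NS_PER_PS,
                      coordinates=u.atoms.positions * _NM_PER_ANGSTROM,
                      box=_box_from_dimensions(u.dimensions))
    return topology, frame


def _build_universe(topology: Topology, frame: Frame | None = None):
    """Construct an MDAnalysis Universe mirroring our topology."""
    mda = _import_mda()
    n = topology.n_particles
    # residues defined by (subunit, residue_index) runs
    res_keys = list(zip(topology.subunits, topology.residue_indices))
    residx = np.zeros(n, dtype=int)
    seen: dict[tuple, int] = {}
    for i, key in enumerate(res_keys):
        if key not in seen:
            seen[key] = len(seen)
        residx[i] = seen[key]
    n_res = len(seen)
    res_order = sorted(seen, key=seen.get)
    resids = np.array([int(k[1]) for k in res_order])
    segids_per_res = np.array([str(k[0]) for k in res_order])
    resnames = np.empty(n_res, dtype=object)
    for i in range(n):
        resnames[residx[i]] = topology.residue_names[i]
    seg_labels = list(dict.fromkeys(segids_per_res))
    segidx = np.array([seg_labels.index(s) for s in segids_per_res])
    u = mda.Universe.empty(n_atoms=n, n_residues=n_res,
                           n_segments=len(seg_labels),
                           atom_resindex=residx,
                           residue_segindex=segidx,
                           trajectory=True)
    u.add_TopologyAttr("names", topology.names)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("resnames", resnames.astype(str))
    u.add_TopologyAttr("segids", seg_labels)
    u.add_TopologyAttr("chainIDs",
                       [str(topology.subunits[i])[:1] for i in range(n)])
    u.add_TopologyAttr("masses", topology.masses)
    u.add_TopologyAttr("elements", [""] * n)
    if frame is not None:
        u.atoms.positions = frame.coordinates / _NM_PER_ANGSTROM
        u.dimensions = [*(frame.box / _NM_PER_ANGSTROM), 90.0, 90.0, 90.0]
    return u


def write_structure(topology: Topology, frame: Frame, path: str | Path) -> None:
    """Write a single snapshot as GRO or PDB (by extension)."""
    u = _build_universe(topology, frame)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")
        u.atoms.write(str(path))


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write all frames as a multi-model PDB (or any MDAnalysis-writable
    trajectory format chosen by extension)."""
    mda = _import_mda()
    u = _build_universe(trajectory.topology, trajectory.frames[0])
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")
        with mda.Writer(str(path), n_atoms=trajectory.topology.n_particles,
                        multiframe=True) as w:
            for f in trajectory.frames:
                u.atoms.positions = f.coordinates / _NM_PER_ANGSTROM
                u.dimensions = [*(f.box / _NM_PER_ANGSTROM), 90., 90., 90.]
                u.trajectory.ts.time = f.time / _NS_PER_PS
                w.write(u.atoms)


def _pdb_header_box(path: Path) -> np.ndarray | None:
    """First CRYST1 record of a PDB file as box edges in nm, if any."""
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    edges = np.array([float(line[6:15]), float(line[15:24]),
                                      float(line[24:33])])
                    if np.all(edges > 0):
                        return edges * _NM_PER_ANGSTROM
                    return None
                if line.startswith(("ATOM", "HETATM")):
                    break
    except (OSError, UnicodeDecodeError, ValueError):
        return None
    return None


def load_trajectory(path: str | Path, topology: Topology,
                    dt: float | None = None,
                    box: Sequence[float] | None = None) -> Trajectory:
    """Read a trajectory (XTC/TRR/DCD/multi-model PDB) against *topology*.

    If the file stores no (or all-zero) frame times, a uniform grid with
    spacing *dt* ns is applied (default 1 ns).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = _build_universe(topology)
    try:
        u.load_new(str(path))
    except Exception as exc:
        msg = str(exc)
        if "atoms" in msg or "Timestep" in msg:
            raise TopologyError(
                f"{path}: particle count does not match topology "
                f"({topology.n_particles} expected): {msg}") from exc
        raise FormatError(f"could not parse {path}: {exc}") from exc
    frames = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Reader has no dt")
        for ts in u.trajectory:
            if ts.positions.shape[0] != topology.n_particles:
                raise TopologyError(
                    f"{path}: frame has {ts.positions.shape[0]} particles, "
                    f"topology has {topology.n_particles}")
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                fbox = np.asarray(ts.dimensions[:3], float) * _NM_PER_ANGSTROM
            elif box is not None:
                fbox = np.asarray(box, float)
            else:
                # multi-model PDBs carry one CRYST1 in the header, which
                # MDAnalysis does not attach to per-model timesteps
                header_box = _pdb_header_box(path)
                if header_box is None:
                    raise FormatError(
                        f"{path}: no box in file and none supplied")
                fbox = header_box
            frames.append(Frame(time=float(ts.time) * _NS_PER_PS,
                                coordinates=ts.positions * _NM_PER_ANGSTROM,
                                box=fbox))
    times = np.array([f.time for f in frames])
    if len(frames) > 1 and not np.all(np.diff(times) > 0):
        step = 1.0 if dt is None else float(dt)
        for i, f in enumerate(frames):
            f.time = i * step
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "(", ")", "species", "resid", "subunit",
             "name", "headgroup"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expression):
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expression) and not expression[j].isspace() \
                and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser producing a boolean mask over particles."""

    def __init__(self, tokens: list[tuple[str, int]], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def advance(self) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            end = self.tokens[-1][1] + len(self.tokens[-1][0]) \
                if self.tokens else 0
            raise SelectionError(
                f"unexpected end of selection expression (at position {end})")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, message: str) -> None:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else -1
        raise SelectionError(f"{message} (at position {at})")

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.pos != len(self.tokens):
            self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.advance()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.advance()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.advance()
            return ~self.factor()
        if tok == "(":
            self.advance()
            mask = self.expr()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.advance()
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.advance()[0])
        if not vals:
            self.fail("expected at least one value")
        return vals

    def primary(self) -> np.ndarray:
        tok, at = self.advance()
        if tok == "species":
            vals = self._values()
            for v in vals:
                if v not in SPECIES_CLASSES:
                    raise SelectionError(
                        f"unknown species class {v!r} (at position {at})")
            return np.isin(self.top.species, vals)
        if tok == "name":
            return np.isin(self.top.names, self._values())
        if tok == "subunit":
            return np.isin(self.top.subunits, self._values())
        if tok == "headgroup":
            return self.top.headgroup.copy()
        if tok == "resid":
            mask = np.zeros(len(self.top), dtype=bool)
            for v in self._values():
                if "-" in v[1:]:  # allow negative start guard
                    lo_s, _, hi_s = v.partition("-")
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionError(
                            f"bad residue range {v!r} (at position {at})")
                    mask |= ((self.top.residue_indices >= lo)
                             & (self.top.residue_indices <= hi))
                else:
                    try:
                        mask |= self.top.residue_indices == int(v)
                    except ValueError:
                        raise SelectionError(
                            f"bad residue id {v!r} (at position {at})")
            return mask
        raise SelectionError(f"unknown keyword {tok!r} (at position {at})")


def select(topology: Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression to a sorted array of particle ids.

    Grammar: ``species <class>...``, ``resid <n | a-b>...``,
    ``subunit <label>...``, ``name <name>...``, ``headgroup``, combined with
    ``and``, ``or``, ``not`` and parentheses.  An empty result is legal.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    return np.flatnonzero(mask)
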