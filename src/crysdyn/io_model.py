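"""Structures, trajectories, atom selections and named residue regions.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of atoms plus one or more coordinate sets (PDB ``MODEL`` blocks), and a
:class:`Trajectory` is a single-model topology plus a time-ordered stack of
coordinate frames in Å.  Residues are indexed two ways: an internal 1-based
sequential index (used by every matrix-valued analysis) and the author residue
number from the PDB file (used by region definitions, because published region
bounds such as "G61~A64" refer to author numbering).
"""

from __future__ import annotations

import configparser
import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Region",
    "RegionMap",
    "AtomSelection",
    "PDBParseError",
    "RegionConfigError",
    "SelectionError",
    "MAINCHAIN_ATOMS",
    "DEFAULT_REGIONS",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "trajectory_from_structure",
    "select_atoms",
    "load_regions",
    "residue_composition",
]

MAINCHAIN_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a PDB file violates the fixed-column contract."""


class RegionConfigError(ValueError):
    """Raised for malformed or inconsistent region definitions."""


class SelectionError(KeyError):
    """Raised when an atom selection predicate cannot be resolved."""


@dataclass(frozen=True)
class Atom:
    """One atom of the topology.

    ``residue_index`` is the internal 1-based sequential index;
    ``author_residue_number`` preserves the numbering printed in the source
    file.  ``is_heavy`` is True for every element except hydrogen.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str
    author_residue_number: int

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


class Structure:
    """An ordered atom list with one or more coordinate models (Å)."""

    def __init__(self, atoms: Sequence[Atom], models: Sequence[np.ndarray]):
        atoms = list(atoms)
        if not atoms:
            raise PDBParseError("structure contains no atoms")
        models = [np.asarray(m, dtype=float) for m in models]
        if not models:
            raise ValueError("structure needs at least one coordinate model")
        for k, m in enumerate(models):
            if m.shape != (len(atoms), 3):
                raise ValueError(
                    f"model {k} has shape {m.shape}, expected ({len(atoms)}, 3)"
                )
            if not np.all(np.isfinite(m)):
                raise ValueError(f"model {k} contains non-finite coordinates")
        self.atoms = atoms
        self.models = models
        self.residue_index = np.array([a.residue_index for a in atoms], dtype=int)
        self.heavy_mask = np.array([a.is_heavy for a in atoms], dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max())

    def coords(self, model: int = 0) -> np.ndarray:
        return self.models[model]

    def residues(self) -> list[tuple[int, str, str, int]]:
        """(internal index, 3-letter name, chain, author number) per residue."""
        seen: dict[int, tuple[int, str, str, int]] = {}
        for a in self.atoms:
            seen.setdefault(
                a.residue_index,
                (a.residue_index, a.residue_name, a.chain, a.author_residue_number),
            )
        return [seen[i] for i in sorted(seen)]

    def first_model(self) -> "Structure":
        return Structure(self.atoms, [self.models[0]])


class Trajectory:
    """A topology plus time-ordered coordinate frames.

    ``times_ns`` must be strictly increasing; frame 0 is the reference state
    every time-zero-normalised analysis (contact fraction, domain rotation)
    compares against.
    """

    def __init__(self, topology: Structure, times_ns: np.ndarray, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        times_ns = np.asarray(times_ns, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {coords.shape} incompatible with "
                f"{topology.n_atoms}-atom topology"
            )
        if times_ns.shape != (coords.shape[0],):
            raise ValueError("one time per frame required")
        if times_ns.size and (np.any(np.diff(times_ns) <= 0) or times_ns[0] < 0):
            raise ValueError("frame times must be non-negative and strictly increasing")
        self.topology = topology.first_model()
        self.times_ns = times_ns
        self.coords = coords

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def sampled(self, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """(times, frames) subsampled every ``stride`` stored frames."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return self.times_ns[::stride], self.coords[::stride]


@dataclass(frozen=True)
class Region:
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise RegionConfigError(f"region start {self.start} > end {self.end}")


class RegionMap(dict):
    """Mapping of region name -> :class:`Region` (author numbering, inclusive)."""

    def add(self, name: str, start: int, end: int, label: str = "") -> None:
        if name in self:
            raise RegionConfigError(f"duplicate region name {name!r}")
        self[name] = Region(int(start), int(end), label)

    def resolve(self, name: str) -> Region:
        try:
            return self[name]
        except KeyError:
            raise SelectionError(f"unknown region {name!r}") from None


#: Default region map for the 173-residue mature chain of human γD-crystallin.
#: Bounds follow the published motif/strand annotations (author numbering).
DEFAULT_REGIONS: Mapping[str, tuple[int, int, str]] = {
    "motif2_beta3": (61, 64, "motif 2 β3-strand G61~A64"),
    "motif1_beta3": (33, 38, "motif 1 β3-strand C33~V38"),
    "motif2_beta2": (55, 58, "motif 2 β2-strand Q55~L58"),
    "motif3_loop": (109, 118, "motif 3 loop C109~F118"),
    "denovo_strand": (116, 119, "de novo β-strand forming region F116~N119"),
    "aggregation_stretch": (54, 58, "aggregation-prone stretch L54~L58"),
    "motif4_b2b3": (138, 162, "motif 4 β2/β3-strands N138~A162"),
    "N_td": (1, 82, "N-terminal domain"),
    "C_td": (88, 173, "C-terminal domain"),
}


@dataclass
class AtomSelection:
    """A resolved, order-preserving set of atom indices into a topology."""

    kind: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return int(self.indices.size)

    def intersect(self, other: "AtomSelection") -> "AtomSelection":
        common = np.intersect1d(self.indices, other.indices)
        return AtomSelection(f"{self.kind}&{other.kind}", common)


# ---------------------------------------------------------------------------
# PDB fixed-column reading/writing (ATOM/HETATM/MODEL/ENDMDL subset)
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    # Hydrogens like 1HG1 / HG21; everything starting with H after digit-strip
    if stripped[0] in "Hh":
        return "H"
    return stripped[0].upper()


def read_pdb(path: str | Path) -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    Only ``ATOM``/``HETATM`` coordinate records and ``MODEL``/``ENDMDL``
    bracketing are interpreted.  Hydrogens are retained and flagged
    non-heavy.  The first alternate location of an atom is kept; insertion
    codes are rejected.
    """
    path = Path(path)
    text = path.read_text()
    return _parse_pdb_text(text, source=str(path))


def _parse_pdb_text(text: str, source: str = "<string>") -> Structure:
    atoms: list[Atom] = []
    models: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    in_model = False
    any_model_records = False
    seen_altloc: set[tuple[str, int, str, str]] = set()
    res_counter = 0
    last_res_key: tuple[str, int, str] | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            any_model_records = True
            if in_model:
                raise PDBParseError(f"{source}:{lineno}: nested MODEL record")
            in_model = True
            current = []
            seen_altloc = set()
        elif rec == "ENDMDL":
            if not in_model:
                raise PDBParseError(f"{source}:{lineno}: ENDMDL without MODEL")
            in_model = False
            models.append(current)
        elif rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise PDBParseError(f"{source}:{lineno}: truncated coordinate record")
            altloc = line[16]
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21] if line[21] != " " else "A"
            icode = line[26]
            if icode not in (" ", ""):
                raise PDBParseError(
                    f"{source}:{lineno}: insertion codes are not supported"
                )
            try:
                serial = int(line[6:11])
                resseq = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise PDBParseError(
                    f"{source}:{lineno}: malformed numeric field ({exc})"
                ) from None
            if altloc not in (" ", ""):
                key = (chain, resseq, resname, name)
                if key in seen_altloc:
                    continue  # later altlocs of an already-seen atom are dropped
                seen_altloc.add(key)
            if not models:  # atom metadata comes from the first model only
                res_key = (chain, resseq, resname)
                if res_key != last_res_key:
                    res_counter += 1
                    last_res_key = res_key
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = _element_from_name(name)
                if not element:
                    raise PDBParseError(
                        f"{source}:{lineno}: cannot determine element for {name!r}"
                    )
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_index=res_counter,
                        residue_name=resname,
                        chain=chain,
                        author_residue_number=resseq,
                    )
                )
            current.append(xyz)

    if in_model:
        raise PDBParseError(f"{source}: MODEL block not closed by ENDMDL")
    if not any_model_records:
        models = [current]
    if not atoms:
        raise PDBParseError(f"{source}: no ATOM/HETATM records found")
    n = len(atoms)
    arrays = []
    for k, m in enumerate(models):
        if len(m) != n:
            raise PDBParseError(
                f"{source}: model {k + 1} has {len(m)} atoms, expected {n}"
            )
        arrays.append(np.array(m, dtype=float))
    return Structure(atoms, arrays)


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write ``structure`` in fixed-column PDB format (%8.3f coordinates)."""
    path = Path(path)
    buf = io.StringIO()
    multi = structure.n_models > 1
    for k, model in enumerate(structure.models, start=1):
        if multi:
            buf.write(f"MODEL     {k:4d}\n")
        for a, (x, y, z) in zip(structure.atoms, model):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            buf.write(
                f"ATOM  {a.serial:5d} {name:<4s} {a.residue_name:<3s} {a.chain}"
                f"{a.author_residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2s}\n"
            )
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    try:
        path.write_text(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc
    return path


def trajectory_from_structure(
    structure: Structure,
    dt_ns: float = 0.25,
    times_ns: Sequence[float] | None = None,
) -> Trajectory:
    """Interpret a multi-model structure as a trajectory.

    Models are taken as frames with uniform spacing ``dt_ns`` starting at
    t = 0, unless explicit ``times_ns`` are supplied.
    """
    n = structure.n_models
    if times_ns is None:
        times = np.arange(n, dtype=float) * float(dt_ns)
    else:
        times = np.asarray(times_ns, dtype=float)
        if times.shape != (n,):
            raise ValueError(f"{times.size} times given for {n} models")
    return Trajectory(structure, times, np.stack(structure.models))


def read_trajectory(
    path: str | Path,
    dt_ns: float = 0.25,
    times_path: str | Path | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory; optional sidecar time file.

    The sidecar is plain text with one time (ns) per line, one line per model.
    """
    structure = read_pdb(path)
    times = None
    if times_path is not None:
        times = [float(t) for t in Path(times_path).read_text().split()]
    return trajectory_from_structure(structure, dt_ns=dt_ns, times_ns=times)


# ---------------------------------------------------------------------------
# Selections and regions
# ---------------------------------------------------------------------------

def select_atoms(
    structure: Structure,
    predicate: str | tuple[int, int],
    regions: RegionMap | None = None,
) -> AtomSelection:
    """Resolve a selection predicate against a topology.

    Predicates: ``"heavy"``; ``"mainchain"`` / ``"backbone"`` (atoms named N,
    CA, C, O — the two words are aliases); ``"region:<name>"`` (requires a
    :class:`RegionMap`); a ``(start, end)`` author-residue-number range or
    ``"resid:<start>-<end>"``.  Returns indices in topology order.
    """
    atoms = structure.atoms
    if isinstance(predicate, tuple):
        lo, hi = predicate
        idx = [
            i for i, a in enumerate(atoms) if lo <= a.author_residue_number <= hi
        ]
        return AtomSelection(f"resid:{lo}-{hi}", np.array(idx, dtype=int))
    if predicate == "heavy":
        idx = [i for i, a in enumerate(atoms) if a.is_heavy]
    elif predicate in ("mainchain", "backbone"):
        idx = [i for i, a in enumerate(atoms) if a.name in MAINCHAIN_ATOMS]
    elif predicate.startswith("region:"):
        name = predicate.split(":", 1)[1]
        if regions is None:
            raise SelectionError("region predicate requires a RegionMap")
        region = regions.resolve(name)
        return select_atoms(structure, (region.start, region.end))
    elif predicate.startswith("resid:"):
        spec = predicate.split(":", 1)[1]
        lo, hi = (int(v) for v in spec.split("-"))
        return select_atoms(structure, (lo, hi))
    else:
        raise SelectionError(f"unknown selection predicate {predicate!r}")
    return AtomSelection(str(predicate), np.array(idx, dtype=int))


def load_regions(
    config_path: str | Path | None = None,
    include_defaults: bool = True,
) -> RegionMap:
    """Load named residue regions from a key-value config file.

    The file is INI-style with a ``[regions]`` section of ``name = start-end``
    (optionally ``start-end : label``) entries.  When ``config_path`` is None
    the packaged human γD-crystallin defaults are returned; when a file is
    given its entries override/extend the defaults unless
    ``include_defaults=False``.
    """
    rmap = RegionMap()
    if include_defaults:
        for name, (start, end, label) in DEFAULT_REGIONS.items():
            rmap.add(name, start, end, label)
    if config_path is None:
        return rmap
    parser = configparser.ConfigParser()
    try:
        with open(config_path) as fh:
            parser.read_file(fh)
    except configparser.DuplicateOptionError as exc:
        raise RegionConfigError(f"duplicate region name: {exc}") from None
    except configparser.Error as exc:
        raise RegionConfigError(f"cannot parse region config: {exc}") from None
    section = "regions" if parser.has_section("regions") else parser.default_section
    for name, value in parser.items(section):
        label = ""
        if ":" in value:
            value, label = (v.strip() for v in value.split(":", 1))
        try:
            lo, hi = (int(v) for v in value.split("-"))
        except ValueError:
            raise RegionConfigError(
                f"region {name!r}: expected 'start-end', got {value!r}"
            ) from None
        rmap.pop(name, None)  # config entries override defaults
        rmap.add(name, lo, hi, label)
    return rmap


def residue_composition(structure: Structure) -> tuple[Counter, int]:
    """Count residues by 3-letter name.

    Returns ``(counts, total)``; independent of how many coordinate models
    the structure carries.
    """
    counts: Counter = Counter()
    for _, resname, _, _ in structure.residues():
        counts[resname] += 1
    return counts, sum(counts.values())
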