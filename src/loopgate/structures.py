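"""Coordinate containers and PDB/mmCIF input-output.

The in-memory model is a light hierarchy ``Structure -> Residue -> Atom``
keyed by author residue numbering (chain id, sequence number, insertion
code), which is how crystallographic papers label residues (S228, Y196...).
Multi-model PDB files are treated as trajectory frames and returned as an
:class:`Ensemble`.  File parsing and writing are delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import FormatError, MissingAtomError, SelectionError, TopologyError

logger = logging.getLogger("loopgate.structures")

#: Residue names treated as water molecules.
WATER_RESIDUES = frozenset({"HOH", "WAT", "TIP3"})

#: Backbone atom names of amino-acid residues.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def infer_element(atom_name: str, residue_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Used when the element column is absent.  Handles the common two-letter
    elements found in protein files and defaults to the first alphabetic
    character otherwise.
    """
    name = atom_name.strip()
    if residue_name in WATER_RESIDUES:
        return "O" if name.startswith("O") else "H"
    stripped = name.lstrip("0123456789")
    if stripped[:2].upper() in {"CL", "BR", "NA", "MG", "ZN", "FE", "SE"} and len(name) >= 4:
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise FormatError(f"cannot infer element for atom name {atom_name!r}")


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue within a model."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def __str__(self) -> str:  # e.g. "A:228(SER)"
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.seq_number}{icode}({self.residue_name})"

    @property
    def id(self) -> tuple[str, int, str]:
        """Identity triple ignoring the residue name."""
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    vdw_radius: float | None = None
    is_sidechain: bool = False
    is_water: bool = False
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise FormatError(f"atom {self.name!r} has invalid coordinates {self.coords!r}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.occupancy,
                    self.vdw_radius, self.is_sidechain, self.is_water, self.altloc)


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[Atom] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.key.residue_name

    @property
    def is_water(self) -> bool:
        return self.name in WATER_RESIDUES

    @property
    def is_amino_acid(self) -> bool:
        return self.name in STANDARD_AA

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise MissingAtomError(f"residue {self.key} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def ca(self) -> Atom:
        """C-alpha atom; raises :class:`MissingAtomError` if absent."""
        return self.atom("CA")

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_sidechain]

    def copy(self) -> "Residue":
        return Residue(self.key, [a.copy() for a in self.atoms])


class Structure:
    """One coordinate model: an ordered collection of residues."""

    def __init__(self, residues: Iterable[Residue], model_id: int = 1,
                 metadata: dict | None = None):
        self.model_id = model_id
        self.metadata = dict(metadata or {})
        self._residues: list[Residue] = []
        self._index: dict[tuple[str, int, str], Residue] = {}
        for res in residues:
            if not res.atoms:
                raise FormatError(f"residue {res.key} has no atoms")
            if res.key.id in self._index:
                raise FormatError(f"duplicate residue key {res.key}")
            self._residues.append(res)
            self._index[res.key.id] = res

    def __len__(self) -> int:
        return len(self._residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self._residues)

    @property
    def residues(self) -> list[Residue]:
        return list(self._residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self._residues:
            seen.setdefault(r.key.chain_id, None)
        return list(seen)

    def residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> Residue:
        try:
            return self._index[(chain_id, seq_number, insertion_code)]
        except KeyError:
            raise MissingAtomError(
                f"no residue {chain_id}:{seq_number}{insertion_code} in model {self.model_id}"
            ) from None

    def has_residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> bool:
        return (chain_id, seq_number, insertion_code) in self._index

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self._residues:
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self._residues)

    def coords(self) -> np.ndarray:
        """All atom coordinates, file order, shape (n_atoms, 3)."""
        return np.array([a.coords for _, a in self.iter_atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise FormatError(f"coordinate array shape {xyz.shape} != ({self.n_atoms}, 3)")
        for i, (_, atom) in enumerate(self.iter_atoms()):
            atom.coords = xyz[i].copy()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly moved copy: ``x -> R x + t``."""
        out = self.copy()
        out.set_coords(out.coords() @ np.asarray(rotation, float).T + np.asarray(translation, float))
        return out

    def topology_keys(self) -> tuple[tuple[tuple[str, int, str, str], tuple[str, ...]], ...]:
        return tuple(
            ((r.key.chain_id, r.key.seq_number, r.key.insertion_code, r.key.residue_name),
             tuple(a.name for a in r.atoms))
            for r in self._residues
        )

    def copy(self) -> "Structure":
        return Structure((r.copy() for r in self._residues), self.model_id, self.metadata)

    # ------------------------------------------------------------------ #
    # selection grammar
    # ------------------------------------------------------------------ #
    def select(self, expression: str) -> "Selection":
        """Evaluate a selection expression against this structure.

        Grammar (case-insensitive keywords, PyMOL-flavoured)::

            expr      := term ("or" term)*
            term      := factor ("and" factor)*
            factor    := "not" factor | "(" expr ")" | predicate
            predicate := "chain" ID[,ID...] | "resi" N[-M][,...] |
                         "resn" NAME[,...]  | "name" NAME[,...] |
                         "sidechain" | "backbone" | "water" | "protein" | "all"

        Returns a :class:`Selection` preserving file order; an empty match is
        legal.  Malformed expressions raise :class:`SelectionError` naming the
        offending token position.
        """
        mask = _SelectionParser(expression).parse(self)
        pairs = [(res, atom) for (res, atom), keep in zip(self.iter_atoms(), mask) if keep]
        return Selection(pairs)


class Selection:
    """Ordered subset of (residue, atom) pairs from one structure."""

    def __init__(self, pairs: Sequence[tuple[Residue, Atom]]):
        self.pairs = list(pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[Residue, Atom]]:
        return iter(self.pairs)

    @property
    def atoms(self) -> list[Atom]:
        return [a for _, a in self.pairs]

    @property
    def residue_keys(self) -> list[ResidueKey]:
        seen: dict[tuple, ResidueKey] = {}
        for res, _ in self.pairs:
            seen.setdefault(res.key.id, res.key)
        return list(seen.values())

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)


class _SelectionParser:
    _KEYWORDS = {"and", "or", "not", "chain", "resi", "resn", "name",
                 "sidechain", "backbone", "water", "protein", "all"}

    def __init__(self, text: str):
        self.text = text
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        for raw in text.replace("(", " ( ").replace(")", " ) ").split():
            pos = text.find(raw.strip("()"), pos) if raw not in "()" else pos
            self.tokens.append((raw, pos))
        self.i = 0

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _next(self) -> str:
        if self.i >= len(self.tokens):
            raise SelectionError(f"unexpected end of selection {self.text!r}")
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    def parse(self, structure: Structure) -> np.ndarray:
        self.pairs = list(structure.iter_atoms())
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self._expr()
        if self.i != len(self.tokens):
            raise SelectionError(
                f"trailing tokens at position {self.i} in {self.text!r}")
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek() is not None and self._peek().lower() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek() is not None and self._peek().lower() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok = self._next()
        low = tok.lower()
        if low == "not":
            return ~self._factor()
        if tok == "(":
            mask = self._expr()
            if self._next() != ")":
                raise SelectionError(f"missing ')' in {self.text!r}")
            return mask
        if low == "chain":
            ids = set(self._next().split(","))
            return self._atom_mask(lambda r, a: r.key.chain_id in ids)
        if low == "resi":
            ranges = []
            for part in self._next().split(","):
                lo, _, hi = part.partition("-")
                try:
                    ranges.append((int(lo), int(hi) if hi else int(lo)))
                except ValueError:
                    raise SelectionError(f"bad residue range {part!r} in {self.text!r}") from None
            return self._atom_mask(
                lambda r, a: any(lo <= r.key.seq_number <= hi for lo, hi in ranges))
        if low == "resn":
            names = {n.upper() for n in self._next().split(",")}
            return self._atom_mask(lambda r, a: r.name in names)
        if low == "name":
            names = {n.upper() for n in self._next().split(",")}
            return self._atom_mask(lambda r, a: a.name in names)
        if low == "sidechain":
            return self._atom_mask(lambda r, a: a.is_sidechain)
        if low == "backbone":
            return self._atom_mask(
                lambda r, a: r.is_amino_acid and a.name in BACKBONE_ATOMS)
        if low == "water":
            return self._atom_mask(lambda r, a: a.is_water)
        if low == "protein":
            return self._atom_mask(lambda r, a: r.is_amino_acid)
        if low == "all":
            return np.ones(len(self.pairs), dtype=bool)
        raise SelectionError(
            f"unknown token {tok!r} at position {self.i - 1} in {self.text!r}")

    def _atom_mask(self, pred) -> np.ndarray:
        return np.array([pred(r, a) for r, a in self.pairs], dtype=bool)


class Ensemble:
    """Ordered frames sharing one residue/atom topology."""

    def __init__(self, frames: Sequence[Structure], frame_times: Sequence[float] | None = None):
        frames = list(frames)
        if not frames:
            raise TopologyError("an ensemble needs at least one frame")
        ref = frames[0].topology_keys()
        for k, frame in enumerate(frames[1:], start=2):
            if frame.topology_keys() != ref:
                raise TopologyError(f"frame {k} does not share the topology of frame 1")
        self.frames = frames
        if frame_times is not None:
            frame_times = [float(t) for t in frame_times]
            if len(frame_times) != len(frames):
                raise TopologyError("frame_times length does not match frame count")
            if any(b <= a for a, b in zip(frame_times, frame_times[1:])):
                raise TopologyError("frame_times must be strictly increasing")
        self.frame_times = frame_times

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Structure:
        return self.frames[i]


# ---------------------------------------------------------------------- #
# input / output (gemmi-backed)
# ---------------------------------------------------------------------- #

def _from_gemmi_model(model, metadata: dict) -> Structure:
    import gemmi

    residues = []
    for chain in model:
        for res in chain:
            # altloc policy: highest occupancy wins, ties by altloc letter
            by_name: dict[str, list] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            seqnum = res.seqid.num
            icode = res.seqid.icode.strip()
            is_wat = res.name in WATER_RESIDUES
            for name, group in by_name.items():
                if len(group) > 1:
                    group.sort(key=lambda a: (-a.occ, a.altloc))
                    logger.info("altloc at %s %s/%d atom %s: keeping %r (occ %.2f)",
                                chain.name, res.name, seqnum, name,
                                group[0].altloc, group[0].occ)
                g = group[0]
                element = g.element.name
                if not element or element == "X":
                    element = infer_element(name, res.name)
                    logger.info("element inferred for %s/%s -> %s", res.name, name, element)
                atoms.append(Atom(
                    name=name,
                    element=element,
                    coords=np.array([g.pos.x, g.pos.y, g.pos.z]),
                    occupancy=g.occ,
                    is_sidechain=(res.name in STANDARD_AA and name not in BACKBONE_ATOMS
                                  and not name.startswith("H")),
                    is_water=is_wat,
                    altloc=g.altloc.strip(),
                ))
            key = ResidueKey(chain.name, seqnum, icode, res.name)
            residues.append(Residue(key, atoms))
    try:
        model_id = int(model.num)
    except (TypeError, ValueError, AttributeError):
        model_id = 1
    return Structure(residues, model_id=model_id, metadata=metadata)


def read_structure(path: str | Path, model_policy: str = "first") -> Structure | Ensemble:
    """Read a PDB or mmCIF file.

    ``model_policy='first'`` returns the first model as a :class:`Structure`;
    ``'all'`` returns an :class:`Ensemble` whose frames are the models (a
    multi-model PDB standing in for trajectory frames).  Water residues
    (HOH/WAT/TIP3) are flagged; author numbering and insertion codes are
    preserved; the highest-occupancy alternate location is kept.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if model_policy not in {"first", "all"}:
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    metadata = {"name": st.name, "path": str(path)}
    if model_policy == "first":
        return _from_gemmi_model(st[0], metadata)
    frames = [_from_gemmi_model(m, metadata) for m in st]
    return Ensemble(frames)


def write_structure(obj: Structure | Ensemble, path: str | Path) -> None:
    """Write a Structure (one MODEL) or Ensemble (multi-model) as PDB."""
    import gemmi

    frames = obj.frames if isinstance(obj, Ensemble) else [obj]
    st = gemmi.Structure()
    st.name = frames[0].metadata.get("name", "loopgate")
    for k, frame in enumerate(frames, start=1):
        model = gemmi.Model(k)
        chains: dict[str, gemmi.Chain] = {}
        for res in frame:
            ch = chains.get(res.key.chain_id)
            if ch is None:
                ch = gemmi.Chain(res.key.chain_id)
                chains[res.key.chain_id] = ch
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.key.seq_number, res.key.insertion_code or " ")
            gres.het_flag = "H" if res.is_water else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\0"
                gres.add_atom(ga)
            ch.add_residue(gres)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------- #
# van der Waals radii
# ---------------------------------------------------------------------- #

def _load_radius_table() -> dict[str, dict[str, float]]:
    import csv
    from importlib.resources import files

    tables: dict[str, dict[str, float]] = {}
    with (files("loopgate.data") / "vdw_radii.csv").open() as fh:
        for row in csv.DictReader(fh):
            tables.setdefault(row["set"], {})[row["element"]] = float(row["radius"])
    return tables


_RADIUS_TABLES: dict[str, dict[str, float]] | None = None


def assign_radii(structure: Structure, radius_set: str = "bondi") -> Structure:
    """Assign per-element van der Waals radii in place (and return the input).

    ``radius_set`` is ``'bondi'`` or ``'chothia'`` (tabulated in
    ``loopgate/data/vdw_radii.csv``).  Elements missing from the table get
    the set's default radius with a logged warning.
    """
    global _RADIUS_TABLES
    if _RADIUS_TABLES is None:
        _RADIUS_TABLES = _load_radius_table()
    if radius_set not in _RADIUS_TABLES:
        raise ValueError(f"unknown radius set {radius_set!r}; "
                         f"available: {sorted(_RADIUS_TABLES)}")
    table = _RADIUS_TABLES[radius_set]
    default = table["*"]
    for _, atom in structure.iter_atoms():
        r = table.get(atom.element)
        if r is None:
            logger.warning("no %s radius for element %r; using default %.2f A",
                           radius_set, atom.element, default)
            r = default
        atom.vdw_radius = r
    return structure
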