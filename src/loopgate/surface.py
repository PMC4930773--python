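"""Solvent accessibility and spatial aggregation propensity.

SASA uses the Shrake–Rupley point-counting construction: each atom carries
a quasi-uniform shell of test points on its probe-expanded sphere
(deterministic Fibonacci lattice, so results are bit-reproducible); the
accessible area is the fraction of points not buried inside any
neighbour's expanded sphere times the full sphere area.

SAP scores each atom by summing, over side-chain atoms within a radius R,
the product of relative side-chain exposure (SASA over the fully exposed
value from an extended Gly-X-Gly reference peptide) and the residue
hydrophobicity (Black–Mould scale normalised so glycine is zero).
Positive SAP marks hydrophobic, exposed — aggregation-prone — patches;
the wild-type/mutant comparison then selects residues whose SAP is
positive in the mutant and increased relative to wild type.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib.resources import files

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnalysisError, ConfigurationError
from .structures import Atom, Residue, ResidueKey, Structure, assign_radii

logger = logging.getLogger("loopgate.surface")

AtomId = tuple[tuple[str, int, str], str]  # (residue id triple, atom name)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice, shape (n, 3)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    per_atom: dict[AtomId, float]
    per_residue: dict[ResidueKey, float]
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_atom.values()))

    def residue_sidechain(self, residue: Residue) -> float:
        """Summed SASA of a residue's side-chain atoms (Gly: CA stands in)."""
        names = [a.name for a in _sap_sidechain_atoms(residue)]
        return float(sum(self.per_atom.get((residue.key.id, nm), 0.0) for nm in names))


def sasa(structure: Structure, probe_radius: float = 1.4, n_points: int = 960,
         include_waters: bool = False) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area, per atom and residue.

    Requires van der Waals radii (see :func:`loopgate.structures.assign_radii`).
    Waters are excluded both as occluders and from the results unless
    ``include_waters`` is set.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable point density")
    entries: list[tuple[Residue, Atom]] = []
    for res, atom in structure.iter_atoms():
        if atom.is_water and not include_waters:
            continue
        if atom.vdw_radius is None:
            raise ConfigurationError(
                f"atom {res.key}/{atom.name} has no van der Waals radius; "
                "call assign_radii() first")
        entries.append((res, atom))
    if not entries:
        return SasaResult({}, {}, probe_radius, n_points)

    xyz = np.array([a.coords for _, a in entries])
    expanded = np.array([a.vdw_radius + probe_radius for _, a in entries])
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    max_r = expanded.max()
    neighbor_lists = tree.query_ball_point(xyz, r=expanded + max_r)

    per_atom: dict[AtomId, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for i, (res, atom) in enumerate(entries):
        pts = xyz[i] + expanded[i] * sphere
        free = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            if np.linalg.norm(xyz[j] - xyz[i]) >= expanded[i] + expanded[j]:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            free &= d2 > expanded[j] ** 2
            if not free.any():
                break
        area = 4.0 * np.pi * expanded[i] ** 2 * free.sum() / n_points
        per_atom[(res.key.id, atom.name)] = float(area)
        per_residue[res.key] = per_residue.get(res.key, 0.0) + float(area)
    return SasaResult(per_atom, per_residue, probe_radius, n_points)


def _subset(structure: Structure, chain_id: str) -> Structure:
    residues = [r for r in structure if r.key.chain_id == chain_id and not r.is_water]
    if not residues:
        raise AnalysisError(f"chain {chain_id!r} absent from structure")
    return Structure((r.copy() for r in residues), structure.model_id)


def delta_saa(dimer: Structure, chain_a: str, chain_b: str,
              probe_radius: float = 1.4, n_points: int = 960,
              radius_set: str = "bondi") -> tuple[float, float, float]:
    """Dimer SASA, summed isolated-chain SASA and interface-buried area.

    ``buried = saa(A alone) + saa(B alone) − saa(dimer)``; non-negative up
    to point-lattice noise.  An increase in dimer SASA at constant subunit
    SASA signals a loosened subunit interface.
    """
    full = assign_radii(dimer.copy(), radius_set)
    a = assign_radii(_subset(dimer, chain_a), radius_set)
    b = assign_radii(_subset(dimer, chain_b), radius_set)
    saa_dimer = sasa(full, probe_radius, n_points).total
    saa_monomers = (sasa(a, probe_radius, n_points).total
                    + sasa(b, probe_radius, n_points).total)
    return saa_dimer, saa_monomers, saa_monomers - saa_dimer


# ---------------------------------------------------------------------- #
# hydrophobicity scale and fully-exposed reference
# ---------------------------------------------------------------------- #

@lru_cache(maxsize=4)
def hydrophobicity_scale(name: str = "black-mould") -> dict[str, float]:
    """Residue hydrophobicity table (Black–Mould, glycine-normalised)."""
    fname = {"black-mould": "hydrophobicity_black_mould.csv"}.get(name)
    if fname is None:
        raise ConfigurationError(f"unknown hydrophobicity scale {name!r}")
    scale = {}
    with (files("loopgate.data") / fname).open() as fh:
        for row in csv.DictReader(fh):
            scale[row["residue"]] = float(row["hydrophobicity"])
    return scale


def _sap_sidechain_atoms(residue: Residue) -> list[Atom]:
    """Side-chain atoms entering the SAP sum; for Gly the Cα stands in."""
    if residue.name == "GLY":
        return [a for a in residue.atoms if a.name == "CA"]
    return [a for a in residue.atoms if a.is_sidechain and a.element != "H"]


@lru_cache(maxsize=8)
def fully_exposed_reference(radius_set: str = "bondi", probe_radius: float = 1.4,
                            n_points: int = 960) -> dict[tuple[str, str], float]:
    """Per-atom SASA of each residue type fully exposed, keyed (resname, atom).

    Computed by this same SASA engine on idealized extended Gly-X-Gly
    tripeptides, so the exposure ratio in SAP is self-consistent with the
    engine and radius set in use.  A versioned copy for the default
    parameters ships as ``loopgate/data/fully_exposed_sasa.csv``.
    """
    from .ideal import THREE_TO_ONE
    from .ideal import build_peptide

    ref: dict[tuple[str, str], float] = {}
    for resname, one in THREE_TO_ONE.items():
        tri = build_peptide(f"G{one}G")
        assign_radii(tri, radius_set)
        result = sasa(tri, probe_radius, n_points)
        central = tri.residue("A", 2)
        for atom in _sap_sidechain_atoms(central):
            ref[(resname, atom.name)] = result.per_atom[(central.key.id, atom.name)]
    return ref


@dataclass
class SapResult:
    per_atom: dict[AtomId, float]
    per_residue: dict[ResidueKey, float]
    radius_R: float
    scale_name: str = "black-mould"


def sap(structure: Structure, sasa_res: SasaResult, radius_R: float = 10.0,
        scale: str = "black-mould", radius_set: str = "bondi") -> SapResult:
    """Spatial aggregation propensity per atom and per residue.

    For atom i::

        SAP(i) = sum over side-chain atoms j with |x_i - x_j| <= R of
                 [SASA(j) / SASA_fully_exposed(j)] * hydrophobicity(res(j))

    Per-residue SAP is the mean over the residue's side-chain atoms (Gly:
    Cα).  Hydrophilic residues (negative scale value) produce negative
    contributions; buried side chains (zero SASA) contribute nothing.
    """
    table = hydrophobicity_scale(scale)
    ref = fully_exposed_reference(radius_set, sasa_res.probe_radius, sasa_res.n_points)

    entries = [(res, atom) for res, atom in structure.iter_atoms() if not atom.is_water]
    contrib_xyz, contrib_val = [], []
    for res in structure:
        if res.is_water or not res.is_amino_acid:
            continue
        h = table.get(res.name)
        if h is None:
            raise ConfigurationError(f"hydrophobicity scale {scale!r} lacks {res.name}")
        for atom in _sap_sidechain_atoms(res):
            ref_area = ref.get((res.name, atom.name))
            if ref_area is None or ref_area <= 0:
                logger.warning("no fully-exposed reference for %s/%s; skipped",
                               res.name, atom.name)
                continue
            area = sasa_res.per_atom.get((res.key.id, atom.name), 0.0)
            contrib_xyz.append(atom.coords)
            contrib_val.append((area / ref_area) * h)
    contrib_xyz = np.array(contrib_xyz).reshape(-1, 3)
    contrib_val = np.array(contrib_val)
    tree = cKDTree(contrib_xyz) if len(contrib_xyz) else None

    per_atom: dict[AtomId, float] = {}
    for res, atom in entries:
        if tree is None:
            per_atom[(res.key.id, atom.name)] = 0.0
            continue
        idx = tree.query_ball_point(atom.coords, r=radius_R)
        per_atom[(res.key.id, atom.name)] = float(contrib_val[idx].sum())

    per_residue: dict[ResidueKey, float] = {}
    for res in structure:
        if res.is_water or not res.is_amino_acid:
            continue
        vals = [per_atom[(res.key.id, a.name)] for a in _sap_sidechain_atoms(res)
                if (res.key.id, a.name) in per_atom]
        if vals:
            per_residue[res.key] = float(np.mean(vals))
    return SapResult(per_atom, per_residue, radius_R, scale)


def delta_sap_selection(wt: SapResult, mut: SapResult) -> list[tuple[ResidueKey, float]]:
    """Residues with positive mutant SAP that increased relative to wild type.

    Returns (residue, ΔSAP) pairs ranked by decreasing ΔSAP; requires both
    results to cover the same residue topology.
    """
    wt_ids = {k.id for k in wt.per_residue}
    mut_ids = {k.id for k in mut.per_residue}
    if wt_ids != mut_ids:
        raise AnalysisError("wild-type and mutant SAP cover different residues")
    wt_by_id = {k.id: v for k, v in wt.per_residue.items()}
    picked = [(k, v - wt_by_id[k.id]) for k, v in mut.per_residue.items()
              if v > 0 and v > wt_by_id[k.id]]
    picked.sort(key=lambda kv: -kv[1])
    return picked
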