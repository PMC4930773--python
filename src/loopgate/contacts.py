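"""Hydrogen bonds, salt bridges, interface energetics proxy and water counts.

H-bond detection is geometric.  Donor and acceptor atoms are typed per
residue (backbone amide N is a donor for every amino acid *except
proline*, which carries no amide hydrogen — the structural consequence a
Ser-to-Pro mutation has at its own backbone).  Because crystal structures
and stripped trajectory frames usually lack hydrogens, the default
criterion is hydrogen-less: heavy-atom donor–acceptor distance within a
cutoff and the angle at the donor (antecedent–donor···acceptor) at least
90°; when an explicit hydrogen is present, the conventional D–H···A angle
criterion is applied instead.

The subunit "binding energy" of the interface is an explicitly labelled
screened-Coulomb proxy — formal charges, distance-dependent dielectric
ε(r) = 4r, 12 Å cutoff — intended only for qualitative wild-type/mutant
comparison, not for absolute energetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ConfigurationError, MissingAtomError
from .structures import (BACKBONE_ATOMS, Atom, Ensemble, Residue, ResidueKey,
                         Structure)
from .surface import _sap_sidechain_atoms

logger = logging.getLogger("loopgate.contacts")

# (donor atom, covalent antecedent) per residue; backbone N handled separately
_SIDECHAIN_DONORS: dict[str, list[tuple[str, str]]] = {
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB")],
    "TYR": [("OH", "CZ")],
    "CYS": [("SG", "CB")],
    "ASN": [("ND2", "CG")],
    "GLN": [("NE2", "CD")],
    "ARG": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "LYS": [("NZ", "CE")],
    "HIS": [("ND1", "CG"), ("NE2", "CD2")],
    "TRP": [("NE1", "CD1")],
}

_SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "HIS": ["ND1", "NE2"],
    "MET": ["SD"],
}

_ACIDIC_ATOMS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
_BASIC_ATOMS = {"ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"]}

COULOMB_CONSTANT = 332.0  # kcal·Å/(mol·e²)


@dataclass
class HBond:
    donor_residue: ResidueKey
    donor_atom: str
    acceptor_residue: ResidueKey
    acceptor_atom: str
    distance: float          # donor-heavy to acceptor, Å
    angle: float             # D-H···A when H present, else antecedent-D···A, degrees
    category: str            # backbone-backbone | backbone-sidechain | sidechain-sidechain
    has_hydrogen: bool = False

    def involves(self, key_id: tuple[str, int, str]) -> bool:
        return self.donor_residue.id == key_id or self.acceptor_residue.id == key_id


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _donors(res: Residue) -> list[tuple[Atom, Atom | None]]:
    """(donor atom, antecedent) pairs for one residue."""
    out: list[tuple[Atom, Atom | None]] = []
    if res.is_amino_acid and res.name != "PRO" and res.has_atom("N"):
        ante = res.atom("CA") if res.has_atom("CA") else None
        out.append((res.atom("N"), ante))
    for donor_name, ante_name in _SIDECHAIN_DONORS.get(res.name, []):
        if res.has_atom(donor_name):
            ante = res.atom(ante_name) if res.has_atom(ante_name) else None
            out.append((res.atom(donor_name), ante))
    return out


def _acceptors(res: Residue) -> list[Atom]:
    out = []
    for name in ("O", "OXT"):
        if res.is_amino_acid and res.has_atom(name):
            out.append(res.atom(name))
    for name in _SIDECHAIN_ACCEPTORS.get(res.name, []):
        if res.has_atom(name):
            out.append(res.atom(name))
    return out


def _bound_hydrogens(res: Residue, donor: Atom) -> list[Atom]:
    return [a for a in res.atoms
            if a.element == "H" and np.linalg.norm(a.coords - donor.coords) < 1.3]


def detect_hbonds(structure: Structure, d_cutoff: float = 3.5,
                  angle_cutoff: float = 120.0) -> list[HBond]:
    """All geometric hydrogen bonds between typed donor/acceptor pairs.

    Pairs within the same residue are excluded.  Unknown residue types are
    skipped with a warning.  See the module docstring for the criteria.
    """
    residues = []
    for res in structure:
        if res.is_water:
            continue
        if not res.is_amino_acid:
            logger.warning("unknown residue type %s skipped in H-bond typing", res.key)
            continue
        residues.append(res)

    donors = [(res, d, ante) for res in residues for d, ante in _donors(res)]
    acceptors = [(res, a) for res in residues for a in _acceptors(res)]
    bonds: list[HBond] = []
    for dres, datom, ante in donors:
        hydrogens = _bound_hydrogens(dres, datom)
        for ares, aatom in acceptors:
            if ares.key.id == dres.key.id:
                continue
            dist = float(np.linalg.norm(datom.coords - aatom.coords))
            if dist > d_cutoff or dist < 1.5:
                continue
            if hydrogens:
                ang = max(_angle(datom.coords, h.coords, aatom.coords) for h in hydrogens)
                ok = ang >= angle_cutoff
                with_h = True
            else:
                if ante is None:
                    continue
                ang = _angle(ante.coords, datom.coords, aatom.coords)
                ok = ang >= 90.0
                with_h = False
            if not ok:
                continue
            cat = "-".join((
                "backbone" if datom.name in BACKBONE_ATOMS else "sidechain",
                "backbone" if aatom.name in BACKBONE_ATOMS else "sidechain",
            ))
            if cat == "sidechain-backbone":
                cat = "backbone-sidechain"
            bonds.append(HBond(dres.key, datom.name, ares.key, aatom.name,
                               dist, ang, cat, with_h))
    return bonds


def hbond_network(structure: Structure, focus: tuple[str, int],
                  partners: list[tuple[str, int]], d_cutoff: float = 3.5,
                  angle_cutoff: float = 120.0) -> list[HBond]:
    """H-bonds linking a focus residue to a named set of partners.

    ``focus`` and ``partners`` are (chain, seq_number) pairs in author
    numbering; all partners must exist.  Used to interrogate the serine
    lock of the gate loops (S228 against Y196/Y198/Y201) and its loss on
    mutation to proline.
    """
    structure.residue(*focus)  # raises if absent
    for p in partners:
        structure.residue(*p)
    focus_id = (focus[0], focus[1], "")
    partner_ids = {(c, s, "") for c, s in partners}
    out = []
    for hb in detect_hbonds(structure, d_cutoff, angle_cutoff):
        ends = {hb.donor_residue.id, hb.acceptor_residue.id}
        if focus_id in ends and (ends - {focus_id}) & partner_ids:
            out.append(hb)
    return out


@dataclass
class InterfaceReport:
    salt_bridges: list[tuple[ResidueKey, ResidueKey, float]]
    electrostatic_proxy: float    # kcal/mol; negative = attractive
    hbond_count: int
    chain_a: str = "A"
    chain_b: str = "B"


def _charge_groups(structure: Structure, chain_id: str) -> list[tuple[ResidueKey, float, np.ndarray]]:
    """Formal ±1 charge sites of one chain: Asp/Glu, Arg/Lys and termini."""
    groups = []
    chain_res = [r for r in structure if r.key.chain_id == chain_id and r.is_amino_acid]
    if not chain_res:
        raise AnalysisError(f"chain {chain_id!r} has no amino-acid residues")
    for res in chain_res:
        if res.name in _ACIDIC_ATOMS:
            atoms = [res.atom(n).coords for n in _ACIDIC_ATOMS[res.name] if res.has_atom(n)]
            if atoms:
                groups.append((res.key, -1.0, np.mean(atoms, axis=0)))
        elif res.name == "ARG" and res.has_atom("CZ"):
            groups.append((res.key, +1.0, res.atom("CZ").coords))
        elif res.name == "LYS" and res.has_atom("NZ"):
            groups.append((res.key, +1.0, res.atom("NZ").coords))
    first, last = chain_res[0], chain_res[-1]
    if first.has_atom("N"):
        groups.append((first.key, +1.0, first.atom("N").coords))
    cterm = "OXT" if last.has_atom("OXT") else "C"
    if last.has_atom(cterm):
        groups.append((last.key, -1.0, last.atom(cterm).coords))
    return groups


def interface_analysis(dimer: Structure, chain_a: str, chain_b: str,
                       acidic_basic_cutoff: float = 4.0,
                       coulomb_cutoff: float = 12.0) -> InterfaceReport:
    """Cross-chain salt bridges, H-bond count and screened-Coulomb proxy.

    Salt bridges pair Asp/Glu carboxylate oxygens with Arg/Lys/His
    side-chain nitrogens across the interface within
    ``acidic_basic_cutoff``.  The energy proxy sums
    ``332·q_i·q_j/(4r·r)`` over cross-chain formal-charge groups within
    ``coulomb_cutoff`` (ε(r) = 4r).  Qualitative use only.
    """
    res_a = [r for r in dimer if r.key.chain_id == chain_a and r.is_amino_acid]
    res_b = [r for r in dimer if r.key.chain_id == chain_b and r.is_amino_acid]
    if not res_a or not res_b:
        raise AnalysisError(f"both chains {chain_a!r} and {chain_b!r} must be present")

    salt_bridges = []
    for acid_side, base_side in ((res_a, res_b), (res_b, res_a)):
        for acid in acid_side:
            names = _ACIDIC_ATOMS.get(acid.name)
            if not names:
                continue
            a_xyz = [acid.atom(n).coords for n in names if acid.has_atom(n)]
            for base in base_side:
                bnames = _BASIC_ATOMS.get(base.name)
                if not bnames:
                    continue
                b_xyz = [base.atom(n).coords for n in bnames if base.has_atom(n)]
                if not a_xyz or not b_xyz:
                    continue
                dmin = min(float(np.linalg.norm(a - b)) for a in a_xyz for b in b_xyz)
                if dmin <= acidic_basic_cutoff:
                    salt_bridges.append((acid.key, base.key, dmin))

    energy = 0.0
    for _, qa, xa in _charge_groups(dimer, chain_a):
        for _, qb, xb in _charge_groups(dimer, chain_b):
            r = float(np.linalg.norm(xa - xb))
            if 0 < r <= coulomb_cutoff:
                energy += COULOMB_CONSTANT * qa * qb / (4.0 * r * r)

    cross = sum(
        1 for hb in detect_hbonds(dimer)
        if {hb.donor_residue.chain_id, hb.acceptor_residue.chain_id} == {chain_a, chain_b}
    )
    return InterfaceReport(salt_bridges, energy, cross, chain_a, chain_b)


@dataclass
class WaterPenetration:
    core_residues: list[ResidueKey]
    cutoff: float
    per_frame_counts: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_frame_counts))


def water_penetration(ensemble: Ensemble | Structure,
                      core_residues: list[tuple[str, int]],
                      cutoff: float = 4.0) -> WaterPenetration:
    """Waters inside the hydrophobic core, per frame.

    Counts water oxygens within ``cutoff`` of any side-chain heavy atom of
    the core residues (Gly: Cα).  A frame without waters contributes a
    count of zero with a warning.
    """
    if not core_residues:
        raise ConfigurationError("core residue set is empty")
    frames = ensemble.frames if isinstance(ensemble, Ensemble) else [ensemble]
    keys: list[ResidueKey] = []
    counts: list[int] = []
    for fi, frame in enumerate(frames):
        core_xyz = []
        for chain, seq in core_residues:
            res = frame.residue(chain, seq)
            if fi == 0:
                keys.append(res.key)
            core_xyz.extend(a.coords for a in _sap_sidechain_atoms(res))
        if not core_xyz:
            raise ConfigurationError("core residues have no side-chain atoms")
        core_xyz = np.array(core_xyz)
        waters = np.array([a.coords for res, a in frame.iter_atoms()
                           if a.is_water and a.element == "O"]).reshape(-1, 3)
        if waters.size == 0:
            logger.warning("frame %d has no waters; count is 0", fi + 1)
            counts.append(0)
            continue
        d2 = np.min(np.sum((waters[:, None, :] - core_xyz[None, :, :]) ** 2, axis=2), axis=1)
        counts.append(int(np.sum(d2 <= cutoff ** 2)))
    return WaterPenetration(keys, cutoff, counts)


def core_residues_by_burial(structure: Structure, chain_id: str,
                            rel_threshold: float = 0.10,
                            radius_set: str = "bondi") -> list[tuple[str, int]]:
    """Default hydrophobic-core set: side-chain relative SASA below threshold.

    Relative exposure is side-chain SASA over the fully exposed value from
    the extended Gly-X-Gly reference, computed with this package's own
    SASA engine on the reference structure.
    """
    from .structures import assign_radii
    from .surface import fully_exposed_reference, sasa

    st = assign_radii(structure.copy(), radius_set)
    result = sasa(st)
    ref = fully_exposed_reference(radius_set, result.probe_radius, result.n_points)
    out = []
    for res in st:
        if res.key.chain_id != chain_id or not res.is_amino_acid:
            continue
        full = sum(ref.get((res.name, a.name), 0.0) for a in _sap_sidechain_atoms(res))
        if full <= 0:
            continue
        if result.residue_sidechain(res) / full < rel_threshold:
            out.append((res.key.chain_id, res.key.seq_number))
    return out
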