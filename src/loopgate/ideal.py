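"""Idealized amino-acid geometry: NeRF backbone construction and
side-chain templates taken from the Chemical Component Dictionary ideal
conformers bundled with :mod:`biotite`.

These builders produce topologically correct, idealized residues — real
PDB atom naming, standard bond lengths and angles — which is what the
mutagenesis and synthetic-fixture code needs.  They make no claim of
physical plausibility beyond that (no packing, no minimization).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .errors import ConfigurationError
from .geometry import kabsch_superpose
from .structures import BACKBONE_ATOMS, Atom, Residue, ResidueKey, Structure

# Engh–Huber-style backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

#: chi1-defining gamma atom per residue type (absent entries have no chi1)
CHI1_GAMMA = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "SER": "OG", "THR": "OG1", "TRP": "CG",
    "TYR": "CG", "VAL": "CG1",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d.

    Returns the point at distance ``bond`` from ``c``, forming angle
    ``angle_deg`` at ``c`` with ``b`` and dihedral ``dihedral_deg`` around
    the b–c axis measured from ``a``.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-9:
        raise ConfigurationError("collinear reference atoms in NeRF placement")
    n /= n_norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@lru_cache(maxsize=32)
def ccd_template(residue_name: str) -> tuple[tuple[str, str, tuple[float, float, float]], ...]:
    """Heavy-atom ideal conformer of a standard residue (name, element, xyz).

    Drops hydrogens and the terminal OXT so the template matches a chain
    residue.  Raises :class:`ConfigurationError` for unknown residue names.
    """
    try:
        import biotite.structure.info as info
        arr = info.residue(residue_name.upper())
    except Exception as exc:  # pragma: no cover - depends on CCD lookup
        raise ConfigurationError(f"no ideal template for residue {residue_name!r}: {exc}") from exc
    if arr is None:
        raise ConfigurationError(f"no ideal template for residue {residue_name!r}")
    out = []
    for name, element, xyz in zip(arr.atom_name, arr.element, arr.coord):
        if element == "H" or name == "OXT":
            continue
        out.append((str(name), str(element).capitalize(), tuple(float(v) for v in xyz)))
    return tuple(out)


def sidechain_from_template(residue_name: str, n: np.ndarray, ca: np.ndarray,
                            c: np.ndarray, chi1: float | None = -60.0
                            ) -> list[tuple[str, str, np.ndarray]]:
    """Idealized side-chain atoms grafted onto an existing backbone frame.

    The CCD ideal conformer is superposed on its (N, CA, C) triad onto the
    given backbone coordinates and the side-chain heavy atoms are returned.
    ``chi1`` (degrees) rotates atoms distal to CB about the CA–CB bond to
    the requested first side-chain torsion (default −60°, the most common
    rotamer); ``None`` keeps the template torsion.  Pro and residues without
    a chi1 are returned as templated.
    """
    residue_name = residue_name.upper()
    template = ccd_template(residue_name)
    tpl = {name: np.array(xyz) for name, _, xyz in template}
    elements = {name: el for name, el, _ in template}
    for req in ("N", "CA", "C"):
        if req not in tpl:
            raise ConfigurationError(f"template {residue_name} lacks backbone atom {req}")
    sup = kabsch_superpose(np.array([n, ca, c]),
                           np.array([tpl["N"], tpl["CA"], tpl["C"]]))
    side = {name: sup.apply(xyz[None, :])[0] for name, xyz in tpl.items()
            if name not in BACKBONE_ATOMS}

    gamma = CHI1_GAMMA.get(residue_name)
    if (chi1 is not None and gamma is not None and residue_name != "PRO"
            and "CB" in side and gamma in side):
        cb = side["CB"]
        axis = cb - np.asarray(ca, float)
        axis /= np.linalg.norm(axis)
        current = dihedral(np.asarray(n, float), np.asarray(ca, float), cb, side[gamma])
        delta = np.deg2rad(current - chi1)  # sign matches the dihedral convention above
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(delta) * K + (1 - np.cos(delta)) * (K @ K)
        for name in side:
            if name != "CB":
                side[name] = cb + R @ (side[name] - cb)
    return [(name, elements[name], xyz) for name, xyz in side.items()]


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))


def build_peptide(sequence: str, chain_id: str = "A", start_seq: int = 1,
                  phi: float = -139.0, psi: float = 135.0, omega: float = 180.0,
                  chi1: float | None = -60.0) -> Structure:
    """Build an idealized peptide with the given backbone torsions.

    ``sequence`` is one-letter code; defaults give an extended (β-strand)
    conformation.  Side chains are grafted from CCD ideal templates.  The
    result carries real PDB atom naming so selection, SASA typing and
    H-bond typing work unmodified.
    """
    names = [ONE_TO_THREE[ch] for ch in sequence.upper()]
    # backbone trace via NeRF
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    th = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, len(names)):
        prev = bb[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        bb.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: O_i placed off psi (anti to the next N)
    for i, frame in enumerate(bb):
        psi_eff = psi if i < len(bb) - 1 else 135.0
        frame["O"] = place_atom(frame["N"], frame["CA"], frame["C"],
                                BOND_C_O, ANGLE_CA_C_O, psi_eff - 180.0)

    residues = []
    for i, resname in enumerate(names):
        frame = bb[i]
        atoms = [Atom(nm, nm[0], frame[nm]) for nm in ("N", "CA", "C", "O")]
        if resname != "GLY":
            for nm, el, xyz in sidechain_from_template(
                    resname, frame["N"], frame["CA"], frame["C"], chi1=chi1):
                atoms.append(Atom(nm, el, xyz, is_sidechain=True))
        key = ResidueKey(chain_id, start_seq + i, "", resname)
        residues.append(Residue(key, atoms))
    return Structure(residues)
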