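"""In-silico single-site point mutation.

A mutation replaces one residue's side chain with idealized template
geometry grafted onto the untouched backbone (N, CA, C, O fixed).  No
rotamer search, packing or minimization is performed: the product is a
topological starting point for downstream comparison, with steric clashes
reported but not repaired.  Mutating to proline removes the backbone
amide donor implicitly — H-bond typing (see :mod:`loopgate.contacts`)
never treats a Pro backbone N as a donor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import MutationError
from .ideal import sidechain_from_template
from .structures import STANDARD_AA, Atom, Residue, Structure, assign_radii

logger = logging.getLogger("loopgate.mutate")

_BACKBONE_KEEP = ("N", "CA", "C", "O", "OXT")
_CLASH_FACTOR = 0.6  # pairs closer than 0.6 x (r_i + r_j) are reported


@dataclass(frozen=True)
class MutationSpec:
    """``chain:seq:FROM>TO`` point mutation in author numbering."""

    chain_id: str
    seq_number: int
    from_res: str
    to_res: str

    def __post_init__(self) -> None:
        for res in (self.from_res, self.to_res):
            if res.upper() not in STANDARD_AA:
                raise MutationError(f"{res!r} is not a standard amino acid")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse ``'A:228:SER>PRO'``."""
        try:
            chain, seq, change = text.split(":")
            frm, to = change.split(">")
            return cls(chain, int(seq), frm.upper(), to.upper())
        except (ValueError, TypeError) as exc:
            raise MutationError(f"cannot parse mutation spec {text!r} "
                                "(expected CHAIN:SEQ:FROM>TO)") from exc

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.seq_number}:{self.from_res}>{self.to_res}"


def mutate_residue(structure: Structure, spec: MutationSpec,
                   chi1: float | None = -60.0) -> Structure:
    """Return a copy of ``structure`` with one residue mutated.

    The target's backbone coordinates are preserved exactly; its side chain
    (and any hydrogens) are replaced by the idealized template of the new
    residue type, first side-chain torsion set to ``chi1`` (default −60°,
    the most common rotamer; ``None`` keeps the template torsion).  All
    other residues are untouched.  A self-mutation returns an identical
    copy.  Steric clashes of the new side chain (pairs closer than 0.6 of
    the summed van der Waals radii) are logged and recorded under
    ``metadata['mutation_clashes']``.
    """
    target = structure.residue(spec.chain_id, spec.seq_number)
    if target.name != spec.from_res.upper():
        raise MutationError(
            f"identity mismatch at {spec.chain_id}:{spec.seq_number}: "
            f"template has {target.name}, mutation says {spec.from_res}")
    for req in ("N", "CA", "C", "O"):
        if not target.has_atom(req):
            raise MutationError(
                f"incomplete residue {target.key}: missing backbone atom {req}")

    out = structure.copy()
    if spec.to_res == spec.from_res:
        return out

    res = out.residue(spec.chain_id, spec.seq_number)
    backbone = [a for a in res.atoms if a.name in _BACKBONE_KEEP]
    n, ca, c = (res.atom(x).coords for x in ("N", "CA", "C"))
    new_side = [
        Atom(name, element, np.asarray(xyz, float), is_sidechain=True)
        for name, element, xyz in sidechain_from_template(spec.to_res, n, ca, c, chi1=chi1)
    ]
    new_res = Residue(res.key.__class__(spec.chain_id, spec.seq_number,
                                        res.key.insertion_code, spec.to_res.upper()),
                      backbone + new_side)
    # splice the rebuilt residue in place, preserving order
    residues = [new_res if r.key.id == res.key.id else r for r in out]
    result = Structure(residues, model_id=out.model_id, metadata=out.metadata)
    result.metadata["mutation"] = str(spec)
    result.metadata["mutation_clashes"] = _clash_report(result, new_res)
    return result


def _clash_report(structure: Structure, mutated: Residue) -> list[dict]:
    """Pairs of (new side-chain atom, other-residue atom) in steric overlap."""
    probe = assign_radii(structure.copy(), "bondi")
    new_names = {a.name for a in mutated.atoms if a.is_sidechain}
    side = [(a.name, a.coords, a.vdw_radius)
            for a in probe.residue(*mutated.key.id).atoms if a.name in new_names]
    clashes = []
    for res, atom in probe.iter_atoms():
        if res.key.id == mutated.key.id:
            continue
        for name, xyz, radius in side:
            d = float(np.linalg.norm(atom.coords - xyz))
            if d < _CLASH_FACTOR * (radius + atom.vdw_radius):
                clashes.append({"atom": name, "partner_residue": str(res.key),
                                "partner_atom": atom.name, "distance": round(d, 3)})
    if clashes:
        logger.warning("mutation introduces %d steric clash(es); not repaired",
                       len(clashes))
    return clashes
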