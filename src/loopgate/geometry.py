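"""Superposition, RMSD/RMSF analytics and the loop-gap statistic.

The central comparison of the pipeline is geometric: a wild-type and a
mutant conformation are superposed (Kabsch least squares), per-residue
displacements are measured, contiguous perturbed regions are selected by a
fixed displacement threshold (the 2 Å rule), and the opening of the two
hydrophobic-core gate loops is quantified by the Cα–Cα distance of a marked
residue pair in each domain.  That distance is internal to the structure,
so no superposition is involved in the loop-gap statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, MissingAtomError
from .structures import Ensemble, ResidueKey, Structure

logger = logging.getLogger("loopgate.geometry")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # 3-vector, Å
    rmsd: float               # post-fit, Å
    atom_count: int

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimising
    ``||R·mobile + t − reference||``; ``rmsd`` is the post-fit residual.
    Inputs are (N, 3) arrays with N ≥ 3 and must not be collinear.
    """
    P = np.asarray(reference, dtype=float)
    Q = np.asarray(mobile, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or Q.shape != P.shape:
        raise AnalysisError(
            f"paired coordinate sets required; got shapes {P.shape} and {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise AnalysisError(f"at least 3 atom pairs required, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    # collinear/degenerate sets leave the rotation under-determined
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise AnalysisError("degenerate (collinear) coordinates: rotation ill-conditioned")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, atom_count=n)


@dataclass
class PerResidueRMSD:
    entries: dict[ResidueKey, float]
    reference_tag: str = "reference"
    mobile_tag: str = "mobile"
    atom_scope: str = "CA"


_SCOPE_ATOMS = {
    "CA": lambda res: [a for a in res.atoms if a.name == "CA"],
    "backbone": lambda res: [a for a in res.atoms
                             if a.name in {"N", "CA", "C", "O"}],
    "heavy": lambda res: [a for a in res.atoms if a.element != "H"],
}


def _shared_residue_keys(reference: Structure, mobile: Structure,
                         chain: str | None = None) -> list[tuple[ResidueKey, ResidueKey]]:
    mob_index = {r.key.id: r.key for r in mobile if r.is_amino_acid}
    pairs = []
    for r in reference:
        if not r.is_amino_acid:
            continue
        if chain is not None and r.key.chain_id != chain:
            continue
        mk = mob_index.get(r.key.id)
        if mk is not None:
            pairs.append((r.key, mk))
    return pairs


def per_residue_rmsd(reference: Structure, mobile: Structure,
                     atom_scope: str = "CA",
                     fit_selection: str = "name CA and protein",
                     chain: str | None = None) -> PerResidueRMSD:
    """Per-residue displacement between two conformations.

    ``mobile`` is first superposed globally onto ``reference`` using the
    atoms matched by ``fit_selection`` (default: all shared Cα), then for
    every residue present in both structures the RMSD over ``atom_scope``
    atoms (``CA``, ``backbone`` or ``heavy``) is reported.  Residues missing
    their scope atoms in either structure are omitted with a log message.
    """
    if atom_scope not in _SCOPE_ATOMS:
        raise ValueError(f"atom_scope must be one of {sorted(_SCOPE_ATOMS)}")
    shared = _shared_residue_keys(reference, mobile, chain)
    if not shared:
        raise AnalysisError("no shared residues between reference and mobile")

    ref_sel = reference.select(fit_selection)
    mob_sel = mobile.select(fit_selection)
    ref_fit = {(r.key.id, a.name): a.coords for r, a in ref_sel}
    mob_fit = {(r.key.id, a.name): a.coords for r, a in mob_sel}
    common = [k for k in ref_fit if k in mob_fit]
    if len(common) < 3:
        raise AnalysisError("fewer than 3 shared fit atoms for superposition")
    sup = kabsch_superpose(np.array([ref_fit[k] for k in common]),
                           np.array([mob_fit[k] for k in common]))

    pick = _SCOPE_ATOMS[atom_scope]
    entries: dict[ResidueKey, float] = {}
    for rk, mk in shared:
        rres = reference.residue(*rk.id)
        mres = mobile.residue(*mk.id)
        ra = {a.name: a.coords for a in pick(rres)}
        ma = {a.name: a.coords for a in pick(mres)}
        names = sorted(set(ra) & set(ma))
        if not names:
            logger.info("residue %s lacks %s atoms in one structure; omitted", rk, atom_scope)
            continue
        dif = np.array([ra[n] for n in names]) - sup.apply(np.array([ma[n] for n in names]))
        entries[rk] = float(np.sqrt(np.mean(np.sum(dif ** 2, axis=1))))
    return PerResidueRMSD(entries=entries, atom_scope=atom_scope)


def select_perturbed_regions(prr: PerResidueRMSD, threshold: float = 2.0,
                             min_run: int = 3) -> list[tuple[ResidueKey, ResidueKey]]:
    """Contiguous residue runs whose per-residue RMSD exceeds ``threshold``.

    Runs are maximal stretches of consecutive sequence numbers within one
    chain, each at least ``min_run`` residues long; returned as (first, last)
    residue-key pairs in sequence order.  This is the fixed-threshold
    descriptive rule (default 2 Å) used to flag structurally perturbed loops;
    it is not a statistical test.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    keys = sorted(prr.entries, key=lambda k: (k.chain_id, k.seq_number, k.insertion_code))
    regions: list[tuple[ResidueKey, ResidueKey]] = []
    run: list[ResidueKey] = []

    def flush() -> None:
        if len(run) >= min_run:
            regions.append((run[0], run[-1]))
        run.clear()

    prev: ResidueKey | None = None
    for k in keys:
        exceeded = prr.entries[k] > threshold
        contiguous = (prev is not None and k.chain_id == prev.chain_id
                      and k.seq_number - prev.seq_number <= 1)
        if exceeded:
            if run and not contiguous:
                flush()
            run.append(k)
        else:
            flush()
        prev = k
    flush()
    return regions


@dataclass
class LoopGapSeries:
    """Per-frame Cα–Cα distances of the two gate-loop marker pairs."""

    pair_ntd: tuple[ResidueKey, ResidueKey]
    pair_ctd: tuple[ResidueKey, ResidueKey]
    distances_ntd: np.ndarray = field(default_factory=lambda: np.empty(0))
    distances_ctd: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def mean_ntd(self) -> float:
        return float(np.mean(self.distances_ntd))

    @property
    def mean_ctd(self) -> float:
        return float(np.mean(self.distances_ctd))

    @property
    def last_ntd(self) -> float:
        return float(self.distances_ntd[-1])

    @property
    def last_ctd(self) -> float:
        return float(self.distances_ctd[-1])


def _ca_coords(frame: Structure, key: tuple[str, int]) -> np.ndarray:
    chain_id, seq = key
    try:
        return frame.residue(chain_id, seq).ca.coords
    except MissingAtomError as exc:
        raise MissingAtomError(f"loop-gap marker {chain_id}:{seq}: {exc}") from exc


def loop_gap(ensemble: Ensemble | Structure,
             pair_ntd: tuple[tuple[str, int], tuple[str, int]],
             pair_ctd: tuple[tuple[str, int], tuple[str, int]]) -> LoopGapSeries:
    """Cα–Cα gate distance per frame for the NTD and CTD marker pairs.

    Pairs are given as ``((chain, seqnum), (chain, seqnum))``; the distance
    is the plain Euclidean Cα separation within each frame (an internal
    coordinate — rigid motion of a frame leaves it unchanged).
    """
    frames = ensemble.frames if isinstance(ensemble, Ensemble) else [ensemble]
    d_ntd, d_ctd = [], []
    for frame in frames:
        for pair, out in ((pair_ntd, d_ntd), (pair_ctd, d_ctd)):
            a = _ca_coords(frame, tuple(pair[0]))
            b = _ca_coords(frame, tuple(pair[1]))
            out.append(float(np.linalg.norm(a - b)))

    def _key(frame: Structure, p) -> ResidueKey:
        return frame.residue(p[0], p[1]).key

    f0 = frames[0]
    return LoopGapSeries(
        pair_ntd=(_key(f0, pair_ntd[0]), _key(f0, pair_ntd[1])),
        pair_ctd=(_key(f0, pair_ctd[0]), _key(f0, pair_ctd[1])),
        distances_ntd=np.array(d_ntd),
        distances_ctd=np.array(d_ctd),
    )


def rmsf(ensemble: Ensemble, atom_scope: str = "CA",
         fit_selection: str = "name CA and protein") -> dict[ResidueKey, float]:
    """Per-residue root-mean-square fluctuation about the ensemble mean.

    Every frame is superposed onto the first frame using ``fit_selection``
    atoms; the fluctuation of each scope atom about its mean fitted position
    is averaged (RMS) within each residue.  Requires at least two frames.
    """
    if atom_scope not in _SCOPE_ATOMS:
        raise ValueError(f"atom_scope must be one of {sorted(_SCOPE_ATOMS)}")
    if len(ensemble) < 2:
        raise AnalysisError("RMSF needs at least 2 frames")
    first = ensemble[0]
    ref_sel = first.select(fit_selection)
    ref_xyz = ref_sel.coords()
    fit_ids = [(r.key.id, a.name) for r, a in ref_sel]
    if len(fit_ids) < 3:
        raise AnalysisError("fewer than 3 fit atoms for RMSF superposition")

    pick = _SCOPE_ATOMS[atom_scope]
    scope_ids: list[tuple[ResidueKey, str]] = []
    for res in first:
        if res.is_amino_acid:
            scope_ids.extend((res.key, a.name) for a in pick(res))

    fitted = np.empty((len(ensemble), len(scope_ids), 3))
    for fi, frame in enumerate(ensemble):
        lookup = {(r.key.id, a.name): a.coords for r, a in frame.iter_atoms()}
        mob_xyz = np.array([lookup[k] for k in fit_ids])
        sup = kabsch_superpose(ref_xyz, mob_xyz)
        fitted[fi] = sup.apply(np.array([lookup[(rk.id, an)] for rk, an in scope_ids]))

    dev = fitted - fitted.mean(axis=0, keepdims=True)
    per_atom_msf = np.mean(np.sum(dev ** 2, axis=2), axis=0)  # mean over frames
    out: dict[ResidueKey, float] = {}
    sums: dict[ResidueKey, list[float]] = {}
    for (rk, _), msf in zip(scope_ids, per_atom_msf):
        sums.setdefault(rk, []).append(msf)
    for rk, vals in sums.items():
        out[rk] = float(np.sqrt(np.mean(vals)))
    return out
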