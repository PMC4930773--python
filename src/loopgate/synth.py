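"""Synthetic fixtures with recorded ground truth.

Everything the analysis pipeline consumes can be generated here without
downloads: a toy two-domain "gate" structure echoing the βB1-crystallin
loop arrangement (author numbering: N82/N108 in the N-terminal domain,
S173/G200 in the C-terminal domain, the S228 serine lock against
Y196/Y198/Y201), multi-frame ensembles with planted perturbed loops,
hydrated cores with planted water counts, and emission spectra /
titration curves / turbidity traces with known parameters.

The toy structures use real amino-acid atom naming so selection, SASA
typing, mutagenesis and H-bond typing run unmodified; they are idealized
scaffolds, not physically plausible proteins.  All generators are
seed-deterministic: the same seed reproduces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .ideal import build_peptide
from .spectro import Spectrum
from .structures import Atom, Ensemble, Residue, ResidueKey, Structure

#: default separation of the closed gate loops (Å) and of the opened mutant
CLOSED_GAP = 6.2
OPEN_GAP = 9.3


@dataclass
class FixtureManifest:
    seed: int
    kind: str
    ground_truth: dict = field(default_factory=dict)
    paths: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "kind": self.kind,
                   "ground_truth": self.ground_truth, "paths": self.paths}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _rot_z(structure: Structure, degrees: float) -> Structure:
    th = np.deg2rad(degrees)
    R = np.array([[np.cos(th), -np.sin(th), 0.0],
                  [np.sin(th), np.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    return structure.transformed(R, np.zeros(3))


def _translate_marker(structure: Structure, marker: tuple[str, int],
                      target: np.ndarray) -> Structure:
    """Translate so the marker residue's Cα lands exactly on ``target``."""
    shift = np.asarray(target, float) - structure.residue(*marker).ca.coords
    return structure.transformed(np.eye(3), shift)


def _merge(chain_id: str, *segments: Structure) -> Structure:
    residues: list[Residue] = []
    for seg in segments:
        for res in seg:
            key = ResidueKey(chain_id, res.key.seq_number, res.key.insertion_code,
                             res.key.residue_name)
            residues.append(Residue(key, [a.copy() for a in res.atoms]))
    residues.sort(key=lambda r: r.key.seq_number)
    return Structure(residues)


def make_gate_structure(gap: float = CLOSED_GAP, n_residues_per_loop: int = 5,
                        seed: int = 0, gap_ntd: float | None = None,
                        chain_id: str = "A") -> tuple[Structure, FixtureManifest]:
    """Toy two-domain scaffold with gate loops at an exact Cα–Cα separation.

    ``gap`` sets the C-terminal-domain marker distance (S173–G200);
    ``gap_ntd`` the N-terminal one (N82–N108, default: same closed 6.2 Å
    regardless of ``gap``, since the mutation opens only the CTD pair).
    The CTD carries the serine lock: S228 paired antiparallel against the
    Y196/Y198 strand with Y201 in the adjacent loop, so geometric H-bond
    detection finds the S228 backbone pair to Y196 and the side-chain
    network to the three tyrosines.  Marker pairs and the planted gaps are
    recorded in the manifest.
    """
    if gap <= 2.0:
        raise ConfigurationError(f"gap must exceed 2 Å, got {gap}")
    if n_residues_per_loop < 3 or n_residues_per_loop % 2 == 0:
        raise ConfigurationError("n_residues_per_loop must be odd and >= 3")
    if gap_ntd is None:
        gap_ntd = CLOSED_GAP
    half = n_residues_per_loop // 2

    def loop(seq: str, start: int) -> Structure:
        return build_peptide(seq, chain_id=chain_id, start_seq=start)

    # NTD gate loops: markers N82 and N108
    ntd1 = loop("AVNSA", 80) if n_residues_per_loop == 5 else _padded_loop("N", 82, half, chain_id)
    ntd2 = loop("GANTA", 106) if n_residues_per_loop == 5 else _padded_loop("N", 108, half, chain_id)
    ntd1 = _translate_marker(ntd1, (chain_id, 82), np.array([0.0, 0.0, 0.0]))
    ntd2 = _translate_marker(ntd2, (chain_id, 108), np.array([0.0, gap_ntd, 0.0]))

    # CTD gate loops: markers S173 and G200 (loop sequence PGYRG as in βB1)
    ctd1 = loop("PSDAV", 172) if n_residues_per_loop == 5 else _padded_loop("S", 173, half, chain_id)
    # CTD outer loop is anchored at P199 (not centred) so longer loops grow
    # away from the Y196-Y198 lock strand instead of colliding with it
    ctd2 = loop("PGYRG" + "A" * max(0, n_residues_per_loop - 5)
                if n_residues_per_loop >= 5 else "PGYRG"[:n_residues_per_loop], 199)
    ctd1 = _translate_marker(ctd1, (chain_id, 173), np.array([40.0, 0.0, 0.0]))
    ctd2 = _translate_marker(ctd2, (chain_id, 200), np.array([40.0, gap, 0.0]))

    # buried core strands under each loop pair: the hydrophobic floor the
    # gate loops shield, and the stable bulk that anchors global fits (the
    # perturbed loops are a small fraction of a real crystallin chain)
    core_segments = []
    ntd_strands = ((60, -5.5), (68, -9.0), (90, -12.5), (118, -16.0))
    ctd_strands = ((150, -5.5), (158, -9.0), (210, -12.5), (219, -16.0))
    for (start, z0), x0, y0 in (
            [(s, 0.0, gap_ntd / 2) for s in ntd_strands]
            + [(s, 40.0, CLOSED_GAP / 2) for s in ctd_strands]):
        seg = loop("VLIVALIV", start)
        seg = _translate_marker(seg, (chain_id, start + 3), np.array([x0, y0, z0]))
        core_segments.append(seg)

    # serine lock: Y196-R197-Y198 strand antiparallel to A227-S228-A229
    strand_y = loop("YRY", 196)
    # serine chi1 trans keeps OG clear of the Y196 ring across the pair
    strand_s = _rot_z(build_peptide("ASA", chain_id=chain_id, start_seq=227, chi1=180.0), 180.0)
    strand_y = _translate_marker(strand_y, (chain_id, 197), np.array([40.0, gap + 9.0, 4.0]))
    strand_s = _place_lock(strand_s, strand_y, chain_id)

    st = _merge(chain_id, ntd1, ntd2, ctd1, ctd2, strand_y, strand_s,
                *core_segments)
    manifest = FixtureManifest(
        seed=seed, kind="gate",
        ground_truth={
            "pair_ntd": [[chain_id, 82], [chain_id, 108]],
            "pair_ctd": [[chain_id, 173], [chain_id, 200]],
            "gap_ntd": gap_ntd, "gap_ctd": gap,
            "lock_focus": [chain_id, 228],
            "lock_partners": [[chain_id, 196], [chain_id, 198], [chain_id, 201]],
        })
    return st, manifest


def _padded_loop(center: str, center_seq: int, half: int, chain_id: str) -> Structure:
    seq = "A" * half + center + "A" * half
    return build_peptide(seq, chain_id=chain_id, start_seq=center_seq - half)


def _place_lock(strand_s: Structure, strand_y: Structure, chain_id: str) -> Structure:
    """Register the S228 strand against Y196 as a narrow antiparallel pair.

    Rigidly places the strand so that N(228) faces O(196) and O(228) faces
    N(196) at hydrogen-bond distance across the inter-strand direction
    (best-fit Kabsch onto explicit target points), reproducing the two
    backbone hydrogen bonds of the serine lock.
    """
    from .geometry import kabsch_superpose

    y196 = strand_y.residue(chain_id, 196)
    y198 = strand_y.residue(chain_id, 198)
    n196, o196, c196 = (y196.atom(x).coords for x in ("N", "O", "C"))
    e_x = y198.ca.coords - y196.ca.coords
    e_x /= np.linalg.norm(e_x)
    u = o196 - c196
    u -= (u @ e_x) * e_x          # inter-strand direction: carbonyl, perp to strand
    u /= np.linalg.norm(u)
    targets = {"N": o196 + 2.9 * u, "O": n196 + 2.9 * u}
    targets["CA"] = targets["N"] + 1.458 * u
    s228 = strand_s.residue(chain_id, 228)
    src = np.array([s228.atom(nm).coords for nm in ("N", "O", "CA")])
    dst = np.array([targets[nm] for nm in ("N", "O", "CA")])
    sup = kabsch_superpose(dst, src)
    return strand_s.transformed(sup.rotation, sup.translation)


def make_ensemble(base: Structure, n_frames: int = 11,
                  sigma_background: float = 0.05,
                  hot_regions: list[dict] | None = None,
                  seed: int = 0) -> tuple[Ensemble, FixtureManifest]:
    """Frames = base + noise, with planted coherently displaced hot loops.

    Every atom receives isotropic Gaussian jitter ``sigma_background`` (Å
    per coordinate).  Each hot region (``{'chain', 'start', 'stop',
    'amplitude': Å, 'sigma': Å}``) additionally drifts along a seeded
    random direction, linearly ramping from zero to ``amplitude`` at the
    last frame — a planted loop-opening — plus optional extra jitter
    ``sigma``.  The manifest records the hot residue set.
    """
    if base.n_atoms == 0:
        raise ConfigurationError("base structure is empty")
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    hot_regions = hot_regions or []
    rng = np.random.default_rng(seed)

    atom_index: dict[tuple, list[int]] = {}
    for i, (res, _) in enumerate(base.iter_atoms()):
        atom_index.setdefault((res.key.chain_id, res.key.seq_number), []).append(i)

    hot_truth: list[list] = []
    region_atoms: list[tuple[np.ndarray, np.ndarray, float]] = []
    for region in hot_regions:
        idx: list[int] = []
        for seq in range(region["start"], region["stop"] + 1):
            members = atom_index.get((region["chain"], seq))
            if members:
                idx.extend(members)
                hot_truth.append([region["chain"], seq])
        if not idx:
            raise ConfigurationError(f"hot region {region} matches no residues")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        region_atoms.append((np.array(idx), direction,
                             float(region.get("amplitude", 3.5))))

    base_xyz = base.coords()
    frames = []
    denom = max(n_frames - 1, 1)
    for fi in range(n_frames):
        xyz = base_xyz + rng.normal(scale=sigma_background, size=base_xyz.shape) \
            if sigma_background > 0 else base_xyz.copy()
        frac = fi / denom
        for (idx, direction, amplitude), region in zip(region_atoms, hot_regions):
            xyz[idx] += amplitude * frac * direction
            extra = float(region.get("sigma", 0.0))
            if extra > 0:
                xyz[idx] += rng.normal(scale=extra, size=(len(idx), 3))
        frame = base.copy()
        frame.model_id = fi + 1
        frame.set_coords(xyz)
        frames.append(frame)
    manifest = FixtureManifest(
        seed=seed, kind="ensemble",
        ground_truth={"hot_residues": hot_truth,
                      "sigma_background": sigma_background,
                      "n_frames": n_frames})
    return Ensemble(frames), manifest


def make_hydrated_core(base: Structure, core_residues: list[tuple[str, int]],
                       n_inside: int, n_outside: int, cutoff: float = 4.0,
                       seed: int = 0, clash_floor: float = 2.4
                       ) -> tuple[Structure, FixtureManifest]:
    """Plant water oxygens inside and outside a core shell.

    ``n_inside`` waters are placed within ``cutoff`` of a core side-chain
    heavy atom (but no closer than ``clash_floor`` to any heavy atom);
    ``n_outside`` beyond ``2*cutoff`` of every core atom.  Fails after
    1000 rejected attempts per water.
    """
    from .surface import _sap_sidechain_atoms

    if not core_residues:
        raise ConfigurationError("core residue set is empty")
    rng = np.random.default_rng(seed)
    core_xyz = []
    for chain, seq in core_residues:
        core_xyz.extend(a.coords for a in _sap_sidechain_atoms(base.residue(chain, seq)))
    core_xyz = np.array(core_xyz)
    heavy = np.array([a.coords for _, a in base.iter_atoms() if a.element != "H"])

    def clash_free(p: np.ndarray, placed: list[np.ndarray]) -> bool:
        if np.any(np.linalg.norm(heavy - p, axis=1) < clash_floor):
            return False
        return all(np.linalg.norm(p - q) >= clash_floor for q in placed)

    placed: list[np.ndarray] = []

    def sample(inside: bool) -> np.ndarray:
        for _ in range(1000):
            anchor = core_xyz[rng.integers(len(core_xyz))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if inside:
                p = anchor + direction * rng.uniform(clash_floor + 0.05, cutoff - 0.05)
                near = np.min(np.linalg.norm(core_xyz - p, axis=1))
                if near >= cutoff:
                    continue
            else:
                p = anchor + direction * rng.uniform(2 * cutoff + 1.0, 2 * cutoff + 8.0)
                if np.min(np.linalg.norm(core_xyz - p, axis=1)) <= 2 * cutoff:
                    continue
            if clash_free(p, placed):
                return p
        raise ConfigurationError("could not place water without clashes in 1000 attempts")

    waters = []
    for k in range(n_inside + n_outside):
        p = sample(inside=k < n_inside)
        placed.append(p)
        key = ResidueKey("W", 900 + k, "", "HOH")
        waters.append(Residue(key, [Atom("O", "O", p, is_water=True)]))
    hydrated = Structure([r.copy() for r in base] + waters, base.model_id)
    manifest = FixtureManifest(
        seed=seed, kind="hydrated",
        ground_truth={"n_inside": n_inside, "n_outside": n_outside,
                      "cutoff": cutoff,
                      "core_residues": [list(c) for c in core_residues]})
    return hydrated, manifest


def make_interface_dimer(separation: float = 5.0, seed: int = 0
                         ) -> tuple[Structure, FixtureManifest]:
    """Two-chain toy interface with the acidic/basic quartet of βB1.

    Chain A carries D169/D170, chain B carries R231/R233 on an antiparallel
    strand placed ``separation`` Å away, so cross-chain salt bridges form
    among the quartet.  Increasing ``separation`` weakens and eventually
    abolishes the contacts (used for monotone-decay property tests).
    """
    a = build_peptide("GDDG", chain_id="A", start_seq=168)
    b = _rot_z(build_peptide("ARARA", chain_id="B", start_seq=230), 180.0)
    acid_o = np.array([r.atom(n).coords for r in a
                       for n in ("OD1", "OD2") if r.has_atom(n)])
    basic_n = np.array([r.atom(n).coords for r in b
                        for n in ("NE", "NH1", "NH2") if r.has_atom(n)])
    shift = acid_o.mean(axis=0) + np.array([1.5, separation, 0.0]) - basic_n.mean(axis=0)
    b = b.transformed(np.eye(3), shift)
    dimer = Structure([r.copy() for r in a] + [r.copy() for r in b])
    manifest = FixtureManifest(
        seed=seed, kind="interface",
        ground_truth={"acidic": [["A", 169], ["A", 170]],
                      "basic": [["B", 231], ["B", 233]],
                      "separation": separation})
    return dimer, manifest


# ---------------------------------------------------------------------- #
# spectra, titrations, kinetics
# ---------------------------------------------------------------------- #

DEFAULT_SPECTRO_PARAMS: dict = {
    # emission band (nm): native buried Trp vs solvent-exposed intermediate;
    # the planted intermediate shift is the 8 nm red shift of interest
    "emax_native": 330.0, "emax_intermediate": 338.0, "emax_unfolded": 350.0,
    "band_sigma": 20.0, "band_intensity": 100.0,
    "wavelengths": (305.0, 420.0, 1.0),
    # three-state refolding: native below ~1.3 mol/L GdnHCl (dimeric
    # intermediate forms there), unfolding midpoint 2.2 mol/L
    "midpoints": (1.3, 2.2), "transition_widths": (0.12, 0.18),
    "conc_range": (0.1, 6.0, 0.1),
    # turbidity at 400 nm: first-order aggregation with a lag
    "plateau": 1.0, "rate_k": 0.05, "lag_time": 30.0, "baseline": 0.02,
    "time_range": (0.0, 600.0, 0.4),
    "spectrum_noise": 0.0, "trace_noise": 0.0,
}


def make_emission_spectrum(emax: float, sigma: float = 20.0,
                           wavelengths: np.ndarray | None = None,
                           intensity: float = 100.0, noise: float = 0.0,
                           rng: np.random.Generator | None = None,
                           label: str = "") -> Spectrum:
    """Gaussian emission band with optional multiplicative Gaussian noise."""
    if wavelengths is None:
        wavelengths = np.arange(305.0, 420.0 + 1e-9, 1.0)
    y = intensity * np.exp(-((wavelengths - emax) ** 2) / (2.0 * sigma ** 2))
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = np.clip(y * (1.0 + rng.normal(scale=noise, size=y.shape)), 0.0, None)
    return Spectrum(wavelengths, y, excitation=295.0, label=label)


def three_state_populations(conc: np.ndarray, midpoints=(1.3, 2.2),
                            widths=(0.12, 0.18)) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(native, intermediate, unfolded) fractions along the denaturant axis."""
    conc = np.asarray(conc, float)
    f_n = 1.0 / (1.0 + np.exp((conc - midpoints[0]) / widths[0]))
    f_u = 1.0 / (1.0 + np.exp(-(conc - midpoints[1]) / widths[1]))
    f_i = np.clip(1.0 - f_n - f_u, 0.0, 1.0)
    return f_n, f_i, f_u


def make_spectra_and_traces(params: dict | None = None, seed: int = 0,
                            out_dir: str | Path | None = None
                            ) -> tuple[dict, FixtureManifest]:
    """Emission spectra per denaturant concentration plus a turbidity trace.

    Returns ``(data, manifest)`` where ``data`` has ``spectra`` (list of
    ``(conc, Spectrum)``), ``time_s``/``turbidity`` arrays, and the two
    single-state spectra used for the planted red-shift comparison.  With
    ``out_dir`` the spectra and trace are also written as two-column CSV
    files next to a ``manifest.json``.
    """
    p = dict(DEFAULT_SPECTRO_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ConfigurationError(f"unknown spectro parameters: {sorted(unknown)}")
        p.update(params)
    rng = np.random.default_rng(seed)
    wl = np.arange(p["wavelengths"][0], p["wavelengths"][1] + 1e-9, p["wavelengths"][2])
    conc = np.arange(p["conc_range"][0], p["conc_range"][1] + 1e-9, p["conc_range"][2])

    f_n, f_i, f_u = three_state_populations(conc, p["midpoints"], p["transition_widths"])
    emax_axis = (f_n * p["emax_native"] + f_i * p["emax_intermediate"]
                 + f_u * p["emax_unfolded"])
    spectra = [
        (float(c),
         make_emission_spectrum(float(e), p["band_sigma"], wl, p["band_intensity"],
                                p["spectrum_noise"], rng, label=f"{c:.2f} mol/L"))
        for c, e in zip(conc, emax_axis)
    ]
    native_spectrum = make_emission_spectrum(p["emax_native"], p["band_sigma"], wl,
                                             p["band_intensity"], p["spectrum_noise"],
                                             rng, label="native-like")
    shifted_spectrum = make_emission_spectrum(p["emax_intermediate"], p["band_sigma"], wl,
                                              p["band_intensity"], p["spectrum_noise"],
                                              rng, label="intermediate")

    t = np.arange(p["time_range"][0], p["time_range"][1] + 1e-9, p["time_range"][2])
    y = np.full_like(t, p["baseline"])
    late = t >= p["lag_time"]
    y[late] += p["plateau"] * (1.0 - np.exp(-p["rate_k"] * (t[late] - p["lag_time"])))
    if p["trace_noise"] > 0:
        y = y + rng.normal(scale=p["trace_noise"] * p["plateau"], size=y.shape)

    data = {"spectra": spectra, "time_s": t, "turbidity": y,
            "native_spectrum": native_spectrum, "shifted_spectrum": shifted_spectrum,
            "conc": conc, "emax_axis": emax_axis}
    manifest = FixtureManifest(
        seed=seed, kind="spectra",
        ground_truth={
            "emax_native": p["emax_native"],
            "emax_intermediate": p["emax_intermediate"],
            "emax_shift": p["emax_intermediate"] - p["emax_native"],
            "midpoints": list(p["midpoints"]),
            "plateau": p["plateau"], "rate_k": p["rate_k"],
            "lag_time": p["lag_time"], "baseline": p["baseline"],
            "spectrum_noise": p["spectrum_noise"], "trace_noise": p["trace_noise"],
        })

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c, spec in spectra:
            fname = out / f"spectrum_{c:.2f}M.csv"
            _write_xy(fname, "wavelength_nm", "intensity",
                      spec.wavelengths, spec.intensities)
            manifest.paths.append(str(fname))
        trace_path = out / "turbidity_trace.csv"
        _write_xy(trace_path, "time_s", "a400", t, y)
        manifest.paths.append(str(trace_path))
        manifest.to_json(out / "manifest.json")
    return data, manifest


def _write_xy(path: Path, xname: str, yname: str,
              x: np.ndarray, y: np.ndarray) -> None:
    lines = [f"{xname},{yname}"]
    lines += [f"{a:.6g},{b:.6g}" for a, b in zip(x, y)]
    path.write_text("\n".join(lines) + "\n")
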