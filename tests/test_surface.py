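import csv
from importlib.resources import files

import numpy as np
import pytest

from loopgate.errors import AnalysisError, ConfigurationError
from loopgate.ideal import build_peptide
from loopgate.structures import Atom, Residue, ResidueKey, Structure, assign_radii
from loopgate.surface import (delta_saa, delta_sap_selection, fibonacci_sphere,
                              fully_exposed_reference, hydrophobicity_scale,
                              sap, sasa)


def _single_atom(radius=1.7):
    return Structure([Residue(ResidueKey("A", 1, "", "ALA"),
                              [Atom("CA", "C", [0.0, 0.0, 0.0], vdw_radius=radius)])])


def _two_spheres(d, radius=1.7):
    return Structure([
        Residue(ResidueKey("A", 1, "", "ALA"),
                [Atom("CA", "C", [0.0, 0.0, 0.0], vdw_radius=radius)]),
        Residue(ResidueKey("A", 2, "", "ALA"),
                [Atom("CA", "C", [d, 0.0, 0.0], vdw_radius=radius)]),
    ])


class TestSasa:
    def test_isolated_sphere_analytic(self):
        """A lone atom exposes its full probe-expanded sphere 4π(r+p)²."""
        result = sasa(_single_atom(), probe_radius=1.4, n_points=960)
        analytic = 4.0 * np.pi * 3.1 ** 2
        assert result.total == pytest.approx(analytic, rel=0.005)

    def test_fully_caged_atom_is_zero(self):
        center = Residue(ResidueKey("A", 1, "", "ALA"),
                         [Atom("CA", "C", [0.0, 0.0, 0.0], vdw_radius=1.7)])
        shell = []
        directions = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                      (0, 0, -1)] + [(sx, sy, sz) for sx in (-1, 1)
                                     for sy in (-1, 1) for sz in (-1, 1)]
        for i, d in enumerate(directions, start=2):
            u = np.array(d, float)
            u /= np.linalg.norm(u)
            shell.append(Residue(ResidueKey("A", i, "", "ALA"),
                                 [Atom("CA", "C", 1.5 * u, vdw_radius=1.7)]))
        result = sasa(Structure([center] + shell))
        assert result.per_atom[(("A", 1, ""), "CA")] == 0.0

    def test_two_spheres_match_cap_formula(self):
        """Occlusion of two equal spheres equals the analytic spherical cap."""
        r_exp = 1.7 + 1.4
        for d in (2.0, 3.0, 4.5, 5.5):
            result = sasa(_two_spheres(d), n_points=960)
            x0 = d / 2.0                       # radical plane (equal spheres)
            h = r_exp - x0
            analytic = 4.0 * np.pi * r_exp ** 2 - 2.0 * np.pi * r_exp * h
            for atom_id in result.per_atom:
                assert result.per_atom[atom_id] == pytest.approx(analytic, rel=0.02)

    def test_convergence_960_vs_3840(self, gate_closed):
        st, _ = gate_closed
        st = assign_radii(st.copy())
        coarse = sasa(st, n_points=960).total
        fine = sasa(st, n_points=3840).total
        assert abs(coarse - fine) / fine < 0.01

    def test_translation_invariance_exact(self, gate_closed):
        st, _ = gate_closed
        st = assign_radii(st.copy())
        base = sasa(st).total
        moved = sasa(st.transformed(np.eye(3), np.array([13.0, -7.0, 2.0]))).total
        assert abs(moved - base) / base < 1e-6

    def test_rotation_invariance_within_lattice_noise(self, gate_closed):
        from scipy.spatial.transform import Rotation
        st, _ = gate_closed
        st = assign_radii(st.copy())
        base = sasa(st).total
        R = Rotation.from_rotvec([0.4, 1.1, -0.7]).as_matrix()
        rotated = sasa(st.transformed(R, np.zeros(3))).total
        assert abs(rotated - base) / base < 0.01

    def test_missing_radius_is_configuration_error(self, gate_closed):
        st, _ = gate_closed
        with pytest.raises(ConfigurationError):
            sasa(st.copy())

    def test_fibonacci_lattice_deterministic_and_unit(self):
        pts = fibonacci_sphere(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, fibonacci_sphere(960))


class TestDeltaSaa:
    def test_distant_chains_bury_nothing(self):
        a = build_peptide("AAA", chain_id="A")
        b = build_peptide("AAA", chain_id="B").transformed(np.eye(3), [60.0, 0, 0])
        dimer = Structure(list(a) + list(b))
        _, _, buried = delta_saa(dimer, "A", "B")
        assert buried == pytest.approx(0.0, abs=1e-6)

    def test_buried_area_decays_monotonically_with_separation(self):
        a = build_peptide("AAA", chain_id="A")
        b0 = build_peptide("AAA", chain_id="B")
        burieds = []
        for dy in (4.0, 6.0, 9.0, 15.0, 40.0):
            b = b0.transformed(np.eye(3), [0.0, dy, 0.0])
            _, _, buried = delta_saa(Structure(list(a) + list(b)), "A", "B")
            burieds.append(buried)
        assert all(x >= y - 1e-6 for x, y in zip(burieds, burieds[1:]))
        assert burieds[0] > 10.0
        assert burieds[-1] == pytest.approx(0.0, abs=1e-6)

    def test_absent_chain_raises(self):
        a = build_peptide("AAA", chain_id="A")
        with pytest.raises(AnalysisError):
            delta_saa(a, "A", "B")


class TestSap:
    def test_single_exposed_alanine_equals_scale_value(self):
        """In the Gly-Ala-Gly reference context the exposure ratio is exactly
        one, so with R below any interatomic distance the CB score is the
        alanine hydrophobicity itself."""
        tri = assign_radii(build_peptide("GAG"))
        result = sap(tri, sasa(tri), radius_R=1.0)
        cb = result.per_atom[(("A", 2, ""), "CB")]
        assert cb == pytest.approx(hydrophobicity_scale()["ALA"], abs=1e-12)

    def test_buried_sidechain_contributes_nothing(self, gate_closed):
        # zeroing a side chain's SASA must zero its contribution everywhere
        st, _ = gate_closed
        st = assign_radii(st.copy())
        sr = sasa(st)
        target = ("A", 228)
        for (rid, name), _ in list(sr.per_atom.items()):
            if rid[:2] == target and name in ("CB", "OG"):
                sr.per_atom[(rid, name)] = 0.0
        result = sap(st, sr, radius_R=1.0)
        res = st.residue("A", 228)
        assert result.per_residue[res.key] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle_exactly(self, gate_closed):
        """Grid/tree implementation equals a naive all-pairs double loop."""
        st, _ = gate_closed
        st = assign_radii(st.copy())
        sr = sasa(st)
        result = sap(st, sr, radius_R=8.0)

        scale = hydrophobicity_scale()
        ref = fully_exposed_reference("bondi", sr.probe_radius, sr.n_points)
        from loopgate.surface import _sap_sidechain_atoms
        contributors = []
        for res in st:
            for atom in _sap_sidechain_atoms(res):
                ref_area = ref[(res.name, atom.name)]
                area = sr.per_atom[(res.key.id, atom.name)]
                contributors.append((atom.coords, (area / ref_area) * scale[res.name]))
        for res, atom in st.iter_atoms():
            expected = sum(v for xyz, v in contributors
                           if np.linalg.norm(atom.coords - xyz) <= 8.0)
            assert result.per_atom[(res.key.id, atom.name)] == pytest.approx(
                expected, abs=1e-9)

    def test_shipped_reference_table_matches_engine(self):
        """The versioned fully-exposed table equals a fresh computation."""
        ref = fully_exposed_reference("bondi", 1.4, 960)
        with (files("loopgate.data") / "fully_exposed_sasa.csv").open() as fh:
            rows = {(r["residue"], r["atom"]): float(r["sasa_A2"])
                    for r in csv.DictReader(fh)}
        assert set(rows) == set(ref)
        for key, val in rows.items():
            assert ref[key] == pytest.approx(val, abs=5e-4)


class TestDeltaSapSelection:
    def test_identical_inputs_select_nothing(self, gate_closed):
        st, _ = gate_closed
        st = assign_radii(st.copy())
        result = sap(st, sasa(st))
        assert delta_sap_selection(result, result) == []

    def test_opened_gate_exposes_ctd_loop(self, gate_closed, gate_open):
        """Opening the CTD gate increases exposure of the PGYRG loop, which
        the ΔSAP rule must pick up with a positive-SAP residue on top."""
        wt = assign_radii(gate_closed[0].copy())
        mut = assign_radii(gate_open[0].copy())
        sel = delta_sap_selection(sap(wt, sasa(wt)), sap(mut, sasa(mut)))
        assert sel
        picked = {k.seq_number for k, _ in sel}
        assert picked & set(range(199, 204))
        # every selected residue has positive mutant SAP by construction
        mut_sap = sap(mut, sasa(mut))
        for key, _ in sel:
            assert mut_sap.per_residue[key] > 0

    def test_negative_sap_residues_excluded(self, gate_closed, gate_open):
        wt = assign_radii(gate_closed[0].copy())
        mut = assign_radii(gate_open[0].copy())
        wt_sap, mut_sap = sap(wt, sasa(wt)), sap(mut, sasa(mut))
        sel_keys = {k.id for k, _ in delta_sap_selection(wt_sap, mut_sap)}
        wt_by_id = {k.id: v for k, v in wt_sap.per_residue.items()}
        for key, value in mut_sap.per_residue.items():
            if value <= 0 and value > wt_by_id[key.id]:
                assert key.id not in sel_keys
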