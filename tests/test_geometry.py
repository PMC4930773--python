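import numpy as np
import pytest

from loopgate.errors import AnalysisError, MissingAtomError
from loopgate.geometry import (kabsch_superpose, loop_gap, per_residue_rmsd,
                               rmsf, select_perturbed_regions)
from loopgate.structures import Ensemble
from loopgate.synth import make_ensemble, make_gate_structure


def _rigid(xyz, rotvec, translation, rng=None):
    from scipy.spatial.transform import Rotation
    R = Rotation.from_rotvec(rotvec).as_matrix()
    return xyz @ R.T + np.asarray(translation)


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        moved = _rigid(pts, [0, 0, np.pi / 2], [5.0, -2.0, 1.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd < 1e-8
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_one_atom_displaced_matches_bruteforce_oracle(self):
        """Post-fit rmsd for the one-atom-displaced quartet, frozen from a
        brute-force minimization over rotations and translations."""
        ref = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        mob = ref.copy()
        mob[0] += [2.0, 0, 0]
        assert kabsch_superpose(ref, mob).rmsd == pytest.approx(0.7974644, abs=1e-6)

    def test_scaled_tetrahedron_closed_form(self):
        """Radial scaling moves each vertex 1.0 Å and the optimal fit is the
        identity, so the post-fit rmsd equals the closed form exactly."""
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        tet *= 2.0 / np.linalg.norm(tet[0])          # circumradius 2 Å
        assert kabsch_superpose(tet, tet * 1.5).rmsd == pytest.approx(1.0, abs=1e-9)

    def test_count_mismatch_and_degenerate(self, rng):
        pts = rng.normal(size=(5, 3))
        with pytest.raises(AnalysisError):
            kabsch_superpose(pts, pts[:4])
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(AnalysisError):
            kabsch_superpose(line, line)

    def test_rmsd_invariant_under_joint_rigid_motion(self, rng):
        pts = rng.normal(size=(12, 3))
        mob = pts + rng.normal(scale=0.5, size=pts.shape)
        base = kabsch_superpose(pts, mob).rmsd
        for rotvec, t in [([0.3, -1.2, 0.5], [3, 4, -1]), ([2.0, 0.1, 0.1], [0, 0, 9])]:
            moved = kabsch_superpose(_rigid(pts, rotvec, t), _rigid(mob, rotvec, t)).rmsd
            assert moved == pytest.approx(base, abs=1e-9)


class TestPerResidueRMSD:
    def test_identity_gives_zero(self, gate_closed):
        st, _ = gate_closed
        prr = per_residue_rmsd(st, st.copy())
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in prr.entries.values())

    def test_planted_displacement_separates_regions(self, gate_closed):
        st, _ = gate_closed
        ens, manifest = make_ensemble(
            st, n_frames=11, sigma_background=0.05, seed=41,
            hot_regions=[{"chain": "A", "start": 199, "stop": 203, "amplitude": 3.5}])
        prr = per_residue_rmsd(st, ens[-1])
        hot = {tuple(x) for x in manifest.ground_truth["hot_residues"]}
        for key, value in prr.entries.items():
            if (key.chain_id, key.seq_number) in hot:
                assert value > 2.0
            else:
                assert value < 2.0

    def test_no_shared_residues_raises(self, gate_closed):
        st, _ = gate_closed
        other, _ = make_gate_structure(6.2)
        # same residues on a different chain id: nothing shared with st
        from loopgate.structures import Residue, ResidueKey, Structure
        moved = Structure([Residue(ResidueKey("Z", r.key.seq_number, "",
                                              r.key.residue_name),
                                   [a.copy() for a in r.atoms]) for r in other])
        with pytest.raises(AnalysisError):
            per_residue_rmsd(st, moved)


class TestRegionSelection:
    def _prr(self, values):
        from loopgate.geometry import PerResidueRMSD
        from loopgate.structures import ResidueKey
        return PerResidueRMSD({ResidueKey("A", i, "", "ALA"): v
                               for i, v in values.items()})

    def test_all_zero_gives_empty(self):
        assert select_perturbed_regions(self._prr({i: 0.0 for i in range(1, 20)})) == []

    def test_threshold_above_max_gives_empty(self):
        prr = self._prr({i: 1.5 for i in range(1, 10)})
        assert select_perturbed_regions(prr, threshold=5.0, min_run=1) == []

    def test_two_planted_runs_returned(self):
        vals = {i: 0.3 for i in range(160, 220)}
        vals.update({i: 3.0 for i in range(172, 177)})
        vals.update({i: 2.5 for i in range(199, 204)})
        regions = select_perturbed_regions(self._prr(vals), 2.0, 3)
        spans = [(a.seq_number, b.seq_number) for a, b in regions]
        assert spans == [(172, 176), (199, 203)]

    def test_min_run_suppresses_singletons(self):
        vals = {i: 0.1 for i in range(1, 30)}
        vals[15] = 9.0
        assert select_perturbed_regions(self._prr(vals), 2.0, 3) == []
        assert len(select_perturbed_regions(self._prr(vals), 2.0, 1)) == 1

    def test_monotone_nonincreasing_in_threshold(self, rng):
        vals = {i: float(abs(v)) for i, v in
                enumerate(rng.normal(scale=2.0, size=60), start=1)}
        prr = self._prr(vals)
        prev = None
        for threshold in (0.5, 1.0, 2.0, 3.0, 4.0):
            picked = set()
            for a, b in select_perturbed_regions(prr, threshold, 1):
                picked.update(range(a.seq_number, b.seq_number + 1))
            if prev is not None:
                assert picked <= prev
            prev = picked


class TestLoopGap:
    @pytest.mark.parametrize("gap", [6.2, 9.3])
    def test_planted_gap_recovered_exactly(self, gap):
        st, manifest = make_gate_structure(gap=gap)
        series = loop_gap(st, manifest.ground_truth["pair_ntd"],
                          manifest.ground_truth["pair_ctd"])
        assert series.mean_ctd == pytest.approx(gap, abs=1e-9)
        assert series.mean_ntd == pytest.approx(6.2, abs=1e-9)

    def test_two_identical_frames(self, gate_closed):
        st, manifest = gate_closed
        ens = Ensemble([st.copy(), st.copy()])
        series = loop_gap(ens, manifest.ground_truth["pair_ntd"],
                          manifest.ground_truth["pair_ctd"])
        assert series.distances_ctd[0] == series.distances_ctd[1]
        assert series.mean_ctd == series.distances_ctd[0]

    def test_superposition_independent(self, gate_closed, rng):
        """The gap is an internal coordinate: rigid motion leaves it unchanged."""
        st, manifest = gate_closed
        base = loop_gap(st, manifest.ground_truth["pair_ntd"],
                        manifest.ground_truth["pair_ctd"]).mean_ctd
        for _ in range(5):
            from scipy.spatial.transform import Rotation
            R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
            moved = st.transformed(R, rng.normal(scale=20, size=3))
            assert loop_gap(moved, manifest.ground_truth["pair_ntd"],
                            manifest.ground_truth["pair_ctd"]).mean_ctd == \
                pytest.approx(base, abs=1e-9)

    def test_missing_calpha_raises(self, gate_closed):
        st, manifest = gate_closed
        with pytest.raises(MissingAtomError):
            loop_gap(st, (("A", 82), ("A", 999)), manifest.ground_truth["pair_ctd"])


class TestRMSF:
    def test_identical_frames_give_zero(self, gate_closed):
        st, _ = gate_closed
        ens = Ensemble([st.copy() for _ in range(4)])
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in rmsf(ens).values())

    def test_single_frame_raises(self, gate_closed):
        st, _ = gate_closed
        with pytest.raises(AnalysisError):
            rmsf(Ensemble([st.copy()]))

    def test_isotropic_noise_matches_sigma_sqrt3(self):
        """One residue jittered with σ per coordinate → RMSF ≈ σ√3 (5%, 2000 frames)."""
        from loopgate.ideal import build_peptide
        base = build_peptide("AAAAAAAAAA")
        sigma = 0.4
        ens, _ = make_ensemble(
            base, n_frames=2000, sigma_background=0.0, seed=99,
            hot_regions=[{"chain": "A", "start": 5, "stop": 5,
                          "amplitude": 0.0, "sigma": sigma}])
        out = rmsf(ens, atom_scope="CA", fit_selection="resi 1-4,7-10 and name CA")
        noisy = [v for k, v in out.items() if k.seq_number == 5][0]
        assert noisy == pytest.approx(sigma * np.sqrt(3.0), rel=0.05)

    def test_planted_hot_residues_rank_top(self, gate_closed):
        st, manifest = gate_closed
        ens, eman = make_ensemble(
            st, n_frames=25, sigma_background=0.05, seed=17,
            hot_regions=[{"chain": "A", "start": 199, "stop": 203,
                          "amplitude": 2.0, "sigma": 0.3}])
        out = rmsf(ens)
        hot = {tuple(x) for x in eman.ground_truth["hot_residues"]}
        ranked = sorted(out, key=out.get, reverse=True)[: len(hot)]
        assert {(k.chain_id, k.seq_number) for k in ranked} == hot
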