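import numpy as np
import pytest

from loopgate.contacts import (COULOMB_CONSTANT, core_residues_by_burial,
                               detect_hbonds, hbond_network,
                               interface_analysis, water_penetration)
from loopgate.errors import ConfigurationError, MissingAtomError
from loopgate.ideal import build_peptide
from loopgate.mutate import MutationSpec, mutate_residue
from loopgate.structures import Atom, Residue, ResidueKey, Structure
from loopgate.synth import make_gate_structure, make_hydrated_core, make_interface_dimer


def _donor_acceptor_pair(distance, residue_b="GLY"):
    """Two glycines: backbone N of residue 2 faces backbone O of residue 1
    head-on at the requested distance (antecedent angle 180°)."""
    res1 = Residue(ResidueKey("A", 1, "", "GLY"), [
        Atom("N", "N", [-3.0, 1.0, 0.0]),
        Atom("CA", "C", [-2.0, 0.5, 0.0]),
        Atom("C", "C", [-1.2, 0.0, 0.0]),
        Atom("O", "O", [0.0, 0.0, 0.0]),
    ])
    res2 = Residue(ResidueKey("A", 9, "", residue_b), [
        Atom("N", "N", [distance, 0.0, 0.0]),
        Atom("CA", "C", [distance + 1.45, 0.0, 0.0]),
        Atom("C", "C", [distance + 2.0, 1.3, 0.0]),
        Atom("O", "O", [distance + 3.2, 1.3, 0.0]),
    ])
    return Structure([res1, res2])


class TestDetectHbonds:
    def test_ideal_pair_at_2p9(self):
        bonds = detect_hbonds(_donor_acceptor_pair(2.9))
        pairs = {(b.donor_residue.seq_number, b.donor_atom,
                  b.acceptor_residue.seq_number, b.acceptor_atom) for b in bonds}
        assert (9, "N", 1, "O") in pairs

    def test_distance_fail_at_4p5(self):
        bonds = detect_hbonds(_donor_acceptor_pair(4.5))
        assert not any(b.donor_residue.seq_number == 9 and b.donor_atom == "N"
                       for b in bonds)

    def test_proline_backbone_never_donates(self):
        """Pro has no amide H: its backbone N must never appear as a donor —
        the typing rule that encodes the S→P mechanistic consequence."""
        st = _donor_acceptor_pair(2.9, residue_b="PRO")
        assert not any(b.donor_atom == "N" and b.donor_residue.seq_number == 9
                       for b in detect_hbonds(st))

    def test_rigid_motion_invariance(self, gate_closed, rng):
        from scipy.spatial.transform import Rotation
        st, _ = gate_closed
        base = {(b.donor_residue.id, b.donor_atom, b.acceptor_residue.id,
                 b.acceptor_atom) for b in detect_hbonds(st)}
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        moved = st.transformed(R, rng.normal(scale=30, size=3))
        assert {(b.donor_residue.id, b.donor_atom, b.acceptor_residue.id,
                 b.acceptor_atom) for b in detect_hbonds(moved)} == base


class TestHbondNetwork:
    def test_serine_lock_network(self, gate_closed):
        """S228 ties the gate loops: ≥2 backbone bonds with Y196 and a
        non-empty network over the three tyrosines."""
        st, manifest = gate_closed
        focus = tuple(manifest.ground_truth["lock_focus"])
        partners = [tuple(p) for p in manifest.ground_truth["lock_partners"]]
        net = hbond_network(st, focus, partners)
        assert net
        to_y196 = [b for b in net
                   if 196 in (b.donor_residue.seq_number, b.acceptor_residue.seq_number)]
        backbone_228 = [b for b in to_y196
                        if (b.donor_residue.seq_number == 228 and b.donor_atom == "N")
                        or (b.acceptor_residue.seq_number == 228 and b.acceptor_atom == "O")]
        assert len(backbone_228) >= 2

    def test_mutation_removes_serine_donors(self, gate_closed):
        st, manifest = gate_closed
        mut = mutate_residue(st, MutationSpec.parse("A:228:SER>PRO"))
        net = hbond_network(mut, ("A", 228), [("A", 196), ("A", 198), ("A", 201)])
        for b in net:
            if b.donor_residue.seq_number == 228:
                assert b.donor_atom not in ("N", "OG")
            assert not (b.acceptor_residue.seq_number == 228
                        and b.acceptor_atom == "OG")

    def test_empty_partner_list(self, gate_closed):
        st, _ = gate_closed
        assert hbond_network(st, ("A", 228), []) == []

    def test_absent_partner_raises(self, gate_closed):
        st, _ = gate_closed
        with pytest.raises(MissingAtomError):
            hbond_network(st, ("A", 228), [("A", 999)])


class TestInterface:
    def test_quartet_salt_bridges(self):
        dimer, manifest = make_interface_dimer()
        report = interface_analysis(dimer, "A", "B")
        acidic = {tuple(x) for x in manifest.ground_truth["acidic"]}
        basic = {tuple(x) for x in manifest.ground_truth["basic"]}
        assert report.salt_bridges
        for acid, base, dist in report.salt_bridges:
            assert (acid.chain_id, acid.seq_number) in acidic
            assert (base.chain_id, base.seq_number) in basic
            assert dist <= 4.0
        assert report.electrostatic_proxy < 0  # net attractive quartet

    def test_separated_chains_have_no_interactions(self):
        dimer, _ = make_interface_dimer(separation=50.0)
        report = interface_analysis(dimer, "A", "B")
        assert report.salt_bridges == []
        assert report.electrostatic_proxy == pytest.approx(0.0, abs=1e-9)

    def test_point_charge_formula(self):
        """332·q₁q₂/(4r²) at 3.32 Å for a unit +/− pair is −7.53 kcal/mol."""
        r = 3.32
        assert COULOMB_CONSTANT * (-1.0) / (4.0 * r * r) == pytest.approx(-7.53, abs=0.01)

    def test_proxy_decays_monotonically_with_separation(self):
        mags = []
        for sep in (5.0, 8.0, 12.0, 20.0):
            dimer, _ = make_interface_dimer(separation=sep)
            mags.append(abs(interface_analysis(dimer, "A", "B").electrostatic_proxy))
        assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_salt_bridge_implies_close_contact(self):
        """Consistency: every salt bridge is within its own distance cutoff."""
        dimer, _ = make_interface_dimer()
        report = interface_analysis(dimer, "A", "B", acidic_basic_cutoff=4.0)
        assert all(d <= 4.0 for _, _, d in report.salt_bridges)


class TestWaterPenetration:
    CORE = [("A", 173), ("A", 200)]

    def test_planted_counts_recovered(self, gate_closed):
        st, _ = gate_closed
        hydrated, manifest = make_hydrated_core(st, self.CORE, n_inside=3,
                                                n_outside=10, seed=2)
        wp = water_penetration(hydrated, self.CORE, cutoff=4.0)
        assert wp.per_frame_counts == [manifest.ground_truth["n_inside"]]

    def test_zero_waters_warns_and_counts_zero(self, gate_closed, caplog):
        st, _ = gate_closed
        with caplog.at_level("WARNING", logger="loopgate.contacts"):
            wp = water_penetration(st, self.CORE)
        assert wp.per_frame_counts == [0]
        assert any("no waters" in rec.message for rec in caplog.records)

    def test_monotone_in_cutoff(self, gate_closed):
        st, _ = gate_closed
        hydrated, _ = make_hydrated_core(st, self.CORE, n_inside=4, n_outside=8, seed=5)
        counts = [water_penetration(hydrated, self.CORE, cutoff=c).per_frame_counts[0]
                  for c in (3.0, 4.0, 5.0, 7.0, 10.0)]
        assert counts == sorted(counts)

    def test_counts_invariant_under_rigid_motion(self, gate_closed, rng):
        from scipy.spatial.transform import Rotation
        st, _ = gate_closed
        hydrated, _ = make_hydrated_core(st, self.CORE, n_inside=3, n_outside=5, seed=9)
        base = water_penetration(hydrated, self.CORE).per_frame_counts
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        moved = hydrated.transformed(R, rng.normal(scale=15, size=3))
        assert water_penetration(moved, self.CORE).per_frame_counts == base

    def test_empty_core_is_configuration_error(self, gate_closed):
        st, _ = gate_closed
        with pytest.raises(ConfigurationError):
            water_penetration(st, [])


def test_core_residue_burial_rule():
    """A residue sandwiched between two neighbouring strands is buried
    relative to the Gly-X-Gly reference and enters the auto core set."""
    a = build_peptide("AVA", chain_id="A", start_seq=1)
    above = build_peptide("AAA", chain_id="A", start_seq=10).transformed(
        np.eye(3), [0.0, 4.5, 0.0])
    below = build_peptide("AAA", chain_id="A", start_seq=20).transformed(
        np.eye(3), [0.0, -4.5, 0.0])
    left = build_peptide("AAA", chain_id="A", start_seq=30).transformed(
        np.eye(3), [0.0, 0.0, 4.5])
    right = build_peptide("AAA", chain_id="A", start_seq=40).transformed(
        np.eye(3), [0.0, 0.0, -4.5])
    st = Structure([r.copy() for seg in (a, above, below, left, right) for r in seg])
    core = core_residues_by_burial(st, "A", rel_threshold=0.35)
    assert ("A", 2) in core
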