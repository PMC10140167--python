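import numpy as np
import pytest

from cambind.interface import (AnalysisConfig, FLMMPocket, anchor_timeline,
                               calcium_sites, classify_motif,
                               classify_orientation, contact_residues,
                               detect_anchors, lobe_dihedral, pocket_com,
                               pooled_salt_bridges, salt_bridges,
                               trp_shielding)
from cambind.model_io import ComplexPairing, StructureFrame, Trajectory
from cambind.synthetic import (EnsembleScript, HelixSpec, MELITTIN_SEQUENCE,
                               ScaffoldSpec, _tip_atom, build_complex,
                               build_ensemble, reverse_chain_numbering)


def _brute_force_anchors(frame, pairing, pocket, cutoff):
    """Independent oracle: explicit all-atom scan against the pocket CoM."""
    from cambind.geometry import mass_of
    cam = frame.residues(pairing.cam_chain, hetero=False)
    pool = []
    for seq in pocket.residues:
        for a in cam.get(seq, []):
            if a.atom_name not in ("N", "CA", "C", "O", "OXT") \
                    and a.element not in ("H", "D"):
                pool.append(a)
    masses = np.array([mass_of(a.element) for a in pool])
    coords = np.vstack([a.coords for a in pool])
    com = (coords * masses[:, None]).sum(0) / masses.sum()
    anchors = set()
    for seq, atoms in frame.residues(pairing.peptide_chain,
                                     hetero=False).items():
        for a in atoms:
            if a.atom_name in ("N", "CA", "C", "O", "OXT") or \
                    a.element in ("H", "D"):
                continue
            if np.linalg.norm(a.coords - com) < cutoff:
                anchors.add(seq)
    return anchors


class TestDetectAnchors:
    def test_constructed_distance_inside(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        com = pocket_com(frame, pockets[0])
        tip = _tip_atom(frame, "B", 9)
        tip.coords = com + np.array([0.0, 0.0, 2.0])
        assert 9 in detect_anchors(frame, pairing, pockets[0], 2.5)

    def test_constructed_distance_outside(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        com = pocket_com(frame, pockets[0])
        tip = _tip_atom(frame, "B", 6)
        tip.coords = com + np.array([0.0, 0.0, 2.6])
        assert detect_anchors(frame, pairing, pockets[0], 2.5) == set()

    def test_boundary_strict(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        com = pocket_com(frame, pockets[0])
        _tip_atom(frame, "B", 6).coords = com + np.array([0.0, 0.0, 2.5])
        assert 6 not in detect_anchors(frame, pairing, pockets[0], 2.5)

    def test_matches_brute_force_oracle(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        for pocket in pockets:
            for cutoff in (1.0, 2.5, 5.0, 12.0):
                assert detect_anchors(frame, pairing, pocket, cutoff) == \
                    _brute_force_anchors(frame, pairing, pocket, cutoff)

    def test_monotone_in_cutoff(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        prev = set()
        for cutoff in (0.5, 1.5, 2.5, 5.0, 10.0, 20.0):
            cur = detect_anchors(frame, pairing, pockets[1], cutoff)
            assert prev <= cur
            prev = cur

    def test_glycine_never_anchors(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        # Gly1 has no side-chain atoms, so even a huge cutoff excludes it
        anchors = detect_anchors(frame, pairing, pockets[0], 100.0)
        assert 1 not in anchors and 3 not in anchors  # Gly1, Gly3

    def test_missing_pocket_sidechain_warns(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        frame.atoms = [a for a in frame.atoms
                       if not (a.chain_id == "A" and a.residue_seq == 19
                               and a.atom_name not in ("N", "CA", "C", "O"))]
        frame = StructureFrame(frame.atoms, metadata=frame.metadata)
        with pytest.warns(UserWarning, match="no side-chain atoms"):
            detect_anchors(frame, pairing, pockets[0], 2.5)


class TestAnchorTimeline:
    def test_scripted_occupancies(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        script = EnsembleScript(n_frames=100, noise_sigma=0.05, seed=1,
                                anchor_schedule={("N", 6): 0.70,
                                                 ("N", 9): 0.08})
        traj = build_ensemble(frame, script, pairing, pockets)
        tl = anchor_timeline(traj, pairing, pockets)
        assert tl["N"].occupancy[6] == pytest.approx(0.70)
        assert tl["N"].occupancy[9] == pytest.approx(0.08)
        assert tl["N"].minor(0.10) == {9}

    def test_single_frame_occupancy_binary(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        traj = Trajectory([frame])
        tl = anchor_timeline(traj, pairing, pockets)
        assert all(v in (0.0, 1.0) for lobe in tl.values()
                   for v in lobe.occupancy.values())

    def test_no_anchors_empty_timeline(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        script = EnsembleScript(n_frames=5, seed=2,
                                anchor_schedule={("N", 6): 0.0,
                                                 ("C", 16): 0.0})
        traj = build_ensemble(frame, script, pairing, pockets)
        tl = anchor_timeline(traj, pairing, pockets)
        assert tl["N"].occupancy == {} and tl["C"].occupancy == {}


class TestClassifyMotif:
    @pytest.mark.parametrize("n, c, label", [
        ({2, 6}, {13, 16}, "1-5-12-15"),
        ({6}, {16}, "1-11"),
        ({6}, {13, 16}, "1-8-11"),
    ])
    def test_reported_modes(self, n, c, label):
        assert classify_motif(n, c).label == label

    def test_shift_invariance(self):
        base = classify_motif({2, 6}, {13, 16}).label
        for k in (-1, 3, 100):
            shifted = classify_motif({2 + k, 6 + k}, {13 + k, 16 + k}).label
            assert shifted == base

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_motif(set(), set())


class TestSaltBridges:
    def test_scripted_major_bridge(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        script = EnsembleScript(n_frames=50, noise_sigma=0.05, seed=4,
                                bridge_schedule={(21, 114): 0.60})
        traj = build_ensemble(frame, script, pairing, pockets)
        stats = {(s.basic_residue[1], s.acidic_residue[1]): s
                 for s in salt_bridges(traj, pairing)}
        assert stats[(21, 114)].occupancy == pytest.approx(0.60)
        assert stats[(21, 114)].major

    def test_minor_bridge_listed_not_major(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        script = EnsembleScript(n_frames=50, noise_sigma=0.05, seed=5,
                                bridge_schedule={(24, 120): 0.12})
        traj = build_ensemble(frame, script, pairing, pockets)
        stats = {(s.basic_residue[1], s.acidic_residue[1]): s
                 for s in salt_bridges(traj, pairing)}
        assert stats[(24, 120)].occupancy == pytest.approx(0.12)
        assert not stats[(24, 120)].major

    def test_never_close_absent(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        script = EnsembleScript(n_frames=20, seed=6,
                                bridge_schedule={(21, 114): 0.0})
        traj = build_ensemble(frame, script, pairing, pockets)
        keys = {(s.basic_residue[1], s.acidic_residue[1])
                for s in salt_bridges(traj, pairing)}
        assert (21, 114) not in keys

    def test_pooled_reports_per_run(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        t1 = build_ensemble(frame, EnsembleScript(
            n_frames=10, seed=7, bridge_schedule={(21, 114): 1.0}),
            pairing, pockets)
        t2 = build_ensemble(frame, EnsembleScript(
            n_frames=10, seed=8, bridge_schedule={(21, 114): 0.0}),
            pairing, pockets)
        stats = {(s.basic_residue[1], s.acidic_residue[1]): s
                 for s in pooled_salt_bridges([t1, t2], pairing)}
        s = stats[(21, 114)]
        assert s.occupancy == pytest.approx(0.5)
        assert s.per_run == [pytest.approx(1.0), pytest.approx(0.0)]


class TestContactResidues:
    def test_isolated_residue_empty(self, complex_fixture):
        frame, pairing, _ = complex_fixture
        far = _tip_atom(frame, "B", 7)
        for a in frame.residue_atoms("B", 7):
            a.coords = a.coords + np.array([0.0, 0.0, 500.0])
        assert contact_residues(frame, pairing, ("B", 7), 4.0) == set()

    def test_constructed_pair(self, complex_fixture):
        frame, pairing, _ = complex_fixture
        target = frame.residue_atoms("A", 120)[0]
        tip = _tip_atom(frame, "B", 21)
        tip.coords = target.coords + np.array([3.5, 0.0, 0.0])
        assert 21 in contact_residues(frame, pairing, ("A", 120), 4.0)

    def test_boundary_excluded(self, complex_fixture):
        frame, pairing, _ = complex_fixture
        target = frame.residue_atoms("A", 120)
        tcoords = np.vstack([a.coords for a in target])
        # move the whole peptide residue so its closest atom is at 4.0
        for a in frame.residue_atoms("B", 21):
            a.coords = a.coords + np.array([0.0, 0.0, 900.0])
        tip = _tip_atom(frame, "B", 21)
        tip.coords = tcoords[0] + np.array([-4.0, 0.0, 0.0])
        assert 21 not in contact_residues(frame, pairing, ("A", 120), 4.0)

    def test_symmetric_roles(self, complex_fixture):
        frame, pairing, _ = complex_fixture
        fwd = contact_residues(frame, pairing, ("B", 6), 6.0)
        for cam_seq in fwd:
            assert 6 in contact_residues(frame, pairing, ("A", cam_seq), 6.0)


class TestTrpShielding:
    def test_scripted_fraction(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        script = EnsembleScript(n_frames=10, noise_sigma=0.05, seed=9,
                                shield_schedule={23: 0.9})
        traj = build_ensemble(frame, script, pairing, pockets)
        flags, frac = trp_shielding(traj, pairing)
        assert frac == pytest.approx(0.90)
        assert sum(flags) == 9

    def test_all_frames_shielded(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        script = EnsembleScript(n_frames=6, seed=10,
                                shield_schedule={23: 1.0})
        traj = build_ensemble(frame, script, pairing, pockets)
        assert trp_shielding(traj, pairing)[1] == pytest.approx(1.0)

    def test_empty_shield_set(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        traj = Trajectory([frame])
        assert trp_shielding(traj, pairing, shield_residues=[])[1] == 0.0

    def test_no_trp_raises(self, complex_fixture):
        _, _, pockets = complex_fixture
        frame2, pairing2, pockets2 = build_complex(
            helix_spec=HelixSpec("AAAAKLAAAAKAAAAKLAAAAK"),
            n_anchors=(6,), c_anchors=(17,))
        with pytest.raises(ValueError, match="tryptophan"):
            trp_shielding(Trajectory([frame2]), pairing2)


class TestOrientation:
    def test_parallel_by_construction(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        assert classify_orientation(frame, pairing, pockets) == "parallel"

    def test_reversed_numbering_flips(self, complex_fixture):
        frame, pairing, pockets = complex_fixture
        rev = reverse_chain_numbering(frame, "B")
        assert classify_orientation(rev, pairing, pockets) == "antiparallel"


class TestCalciumAndDihedral:
    def test_four_sites_in_order(self, scaffold):
        ions = calcium_sites(scaffold, "A")
        assert len(ions) == 4
        assert [i.residue_seq for i in ions] == [201, 202, 203, 204]

    def test_dihedral_recovery(self, scaffold):
        assert abs(lobe_dihedral(scaffold, "A")) == pytest.approx(117.5,
                                                                  abs=1e-6)

    def test_missing_ions_raise(self, melittin_helix):
        with pytest.raises(ValueError):
            calcium_sites(melittin_helix, "B")


class TestAnalysisConfig:
    def test_defaults(self):
        cfg = AnalysisConfig()
        assert cfg.anchor_com_cutoff == 2.5
        assert cfg.contact_cutoff == 4.0
        assert cfg.saltbridge_cutoff == 4.0
        assert cfg.minor_occupancy == 0.10
        assert cfg.major_occupancy == 0.50
        assert cfg.shield_occupancy_ref == 0.85
        assert cfg.cluster_cutoff_complex == 1.5
        assert cfg.cluster_cutoff_peptide == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            AnalysisConfig(anchor_com_cutoff=-1.0)
        with pytest.raises(ValueError):
            AnalysisConfig(minor_occupancy=1.5)
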