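"""AIR derivation, effective distances, rigid-body docking and assembly."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bmap import docking, synth
from bmap.structures import StructureModel

from conftest import make_model


@pytest.fixture(scope="module")
def truth1():
    return synth.make_bipartite_truth(seed=1)


@pytest.fixture(scope="module")
def airs_a(truth1):
    return docking.derive_airs(
        truth1.interface_static_a, truth1.interface_mobile_a,
        truth1.static, truth1.mobile_a, ceiling=docking.BEAD_AIR_CEILING)


@pytest.fixture(scope="module")
def poses_a(truth1, airs_a):
    return docking.dock(truth1.static, truth1.mobile_a, airs_a, n_trials=48,
                        seed=11, clash_distance=docking.BEAD_CLASH_DISTANCE)


class TestDeriveAirs:
    def test_isolated_called_residue_has_empty_passive_shell(self):
        m = make_model([
            ("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 2, "ALA", "CA", "C", (20.0, 0.0, 0.0)),
        ])
        airs = docking.derive_airs([1], [1], m, m)
        assert airs.passive_static == []

    def test_constructed_neighbor_shell(self):
        m = make_model([
            ("A", 231, "ALA", "CA", "C", (0.0, 5.0, 0.0)),
            ("A", 232, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 233, "ALA", "CA", "C", (0.0, -5.0, 0.0)),
            ("A", 300, "ALA", "CA", "C", (30.0, 0.0, 0.0)),
        ])
        airs = docking.derive_airs([232], [232], m, m, neighbor_radius=6.5)
        assert airs.passive_static == [231, 233]

    def test_empty_call_list_rejected(self, truth1):
        with pytest.raises(ValueError):
            docking.derive_airs([], [1001], truth1.static, truth1.mobile_a)

    def test_active_passive_disjoint(self, airs_a):
        assert not set(airs_a.active_static) & set(airs_a.passive_static)
        assert not set(airs_a.active_mobile) & set(airs_a.passive_mobile)


class TestEffectiveDistance:
    def test_single_pair_is_plain_distance(self):
        assert docking.air_effective_distance(
            np.array([[0.0, 0.0, 0.0]]), np.array([[2.0, 0.0, 0.0]])
        ) == pytest.approx(2.0)

    def test_two_equal_pairs_closed_form(self):
        d = 3.0
        got = docking.air_effective_distance(
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[d, 0.0, 0.0], [-d, 0.0, 0.0]]))
        assert got == pytest.approx(d * 2 ** (-1 / 6), rel=1e-12)

    def test_distant_pair_is_negligible(self):
        near = docking.air_effective_distance(
            np.array([[0.0, 0.0, 0.0]]), np.array([[2.0, 0.0, 0.0]]))
        both = docking.air_effective_distance(
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[2.0, 0.0, 0.0], [50.0, 0.0, 0.0]]))
        assert abs(both - near) < 1e-3

    def test_monotone_in_partner_distance(self):
        a = np.array([[0.0, 0.0, 0.0]])
        d1 = docking.air_effective_distance(a, np.array([[3.0, 0, 0], [0, 4.0, 0]]))
        d2 = docking.air_effective_distance(a, np.array([[3.5, 0, 0], [0, 4.5, 0]]))
        assert d2 > d1

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            docking.air_effective_distance(np.empty((0, 3)), np.array([[1.0, 0, 0]]))


class TestDock:
    def test_truth_pose_scores_zero(self, truth1, airs_a):
        prob = docking._DockingProblem(
            truth1.static, truth1.mobile_a, airs_a, [], None,
            clash_distance=docking.BEAD_CLASH_DISTANCE)
        retained = np.ones(prob.n_restraints, dtype=bool)
        ea, es, ec, _ = prob.energies(np.eye(3), np.zeros(3), retained)
        assert ea == pytest.approx(0.0, abs=1e-9)
        assert es == 0.0
        assert ec == 0

    def test_exclusion_count_is_ceil_of_fraction(self):
        airs = docking.AirRestraintSet(list(range(20)), [], list(range(1000, 1020)), [],
                                       exclusion_fraction=0.10)
        assert airs.n_restraints == 40
        assert airs.exclusion_count() == 4  # ceil(0.1 * 40)
        airs31 = docking.AirRestraintSet(list(range(16)), [], list(range(1000, 1015)), [],
                                         exclusion_fraction=0.10)
        assert airs31.exclusion_count() == math.ceil(0.1 * 31)

    def test_each_trial_excludes_exactly_that_many(self, truth1, airs_a, poses_a):
        n_excl = min(airs_a.exclusion_count(), airs_a.n_restraints - 1)
        for pose in poses_a:
            assert len(pose.excluded) == n_excl

    def test_top_pose_recovers_interface(self, truth1, poses_a):
        irmsd = docking.interface_rmsd(poses_a[0], truth1.mobile_a,
                                       truth1.mobile_a, truth1.static)
        assert irmsd < 2.0

    def test_scrambled_airs_destroy_recovery(self, truth1):
        # actives moved to the opposite (non-interface) faces
        far_static = sorted(set(truth1.static.res_numbers.astype(int)))[-10:]
        far_mobile = sorted(set(truth1.mobile_a.res_numbers.astype(int)))[-10:]
        scrambled = docking.derive_airs(far_static, far_mobile,
                                        truth1.static, truth1.mobile_a,
                                        ceiling=docking.BEAD_AIR_CEILING)
        poses = docking.dock(truth1.static, truth1.mobile_a, scrambled,
                             n_trials=10, seed=5,
                             clash_distance=docking.BEAD_CLASH_DISTANCE)
        irmsd = docking.interface_rmsd(poses[0], truth1.mobile_a,
                                       truth1.mobile_a, truth1.static)
        assert irmsd > 8.0

    def test_deterministic_for_fixed_seed(self, truth1, airs_a):
        a = docking.dock(truth1.static, truth1.mobile_a, airs_a, n_trials=3, seed=2,
                         clash_distance=docking.BEAD_CLASH_DISTANCE)
        b = docking.dock(truth1.static, truth1.mobile_a, airs_a, n_trials=3, seed=2,
                         clash_distance=docking.BEAD_CLASH_DISTANCE)
        for pa, pb in zip(a, b):
            assert np.allclose(pa.rotation, pb.rotation)
            assert np.allclose(pa.translation, pb.translation)
            assert pa.score == pb.score

    def test_energy_invariant_under_global_transform(self, truth1, airs_a):
        prob = docking._DockingProblem(
            truth1.static, truth1.mobile_a, airs_a, [], None,
            clash_distance=docking.BEAD_CLASH_DISTANCE)
        retained = np.ones(prob.n_restraints, dtype=bool)
        R_pose = Rotation.from_rotvec([0.2, -0.1, 0.4]).as_matrix()
        t_pose = np.array([3.0, -1.0, 2.0])
        ref = prob.energies(R_pose, t_pose, retained)

        G = Rotation.from_rotvec([0.7, 0.3, -0.5]).as_matrix()
        g = np.array([11.0, -4.0, 6.0])
        static2 = truth1.static.transformed(G, g)
        mobile2 = truth1.mobile_a.transformed(G, g)
        prob2 = docking._DockingProblem(
            static2, mobile2, airs_a, [], None,
            clash_distance=docking.BEAD_CLASH_DISTANCE)
        # conjugated pose: x -> G(R x + t) + g expressed in the new frame
        R2 = G @ R_pose @ G.T
        t2 = G @ t_pose + g - R2 @ g
        got = prob2.energies(R2, t2, retained)
        assert got[0] == pytest.approx(ref[0], abs=1e-8)
        assert got[2] == ref[2]

    def test_unguided_docking_refused(self, truth1):
        empty = docking.AirRestraintSet([], [], [], [])
        with pytest.raises(ValueError):
            docking.dock(truth1.static, truth1.mobile_a, empty, n_trials=1, seed=0)


class TestSaltBridgeScreen:
    def test_truth_bridges_top_the_table(self, truth1, poses_a):
        table = docking.screen_salt_bridges(poses_a, truth1.static, truth1.mobile_a,
                                            top_k=5)
        assert len(table) >= 1
        top_pairs = set(zip(table["basic_res"], table["acidic_res"]))
        assert set(truth1.salt_bridges) & top_pairs

    def test_no_charged_contacts_gives_empty_table(self, truth1, poses_a):
        # mobile B carries no marker atoms
        table = docking.screen_salt_bridges(poses_a[:1], truth1.static,
                                            truth1.mobile_b, top_k=1)
        assert len(table) == 0

    def test_candidate_restriction_filters_output(self, truth1, poses_a):
        wanted = ([truth1.salt_bridges[0][0]], [truth1.salt_bridges[0][1]])
        table = docking.screen_salt_bridges(poses_a, truth1.static, truth1.mobile_a,
                                            top_k=5, candidates=wanted)
        assert set(table["basic_res"]) <= set(wanted[0])
        assert set(table["acidic_res"]) <= set(wanted[1])

    def test_reproducible_for_fixed_poses(self, truth1, poses_a):
        a = docking.screen_salt_bridges(poses_a, truth1.static, truth1.mobile_a, top_k=5)
        b = docking.screen_salt_bridges(poses_a, truth1.static, truth1.mobile_a, top_k=5)
        assert a.equals(b)


class TestAssembly:
    def test_truth_poses_assemble_validly(self, truth1):
        ref = truth1.reference_pose()
        asm = docking.assemble_complex(truth1.static, truth1.mobile_a, ref,
                                       truth1.mobile_b, ref, linkers=[truth1.linker])
        assert asm.valid
        assert asm.inter_body_clashes == 0

    def test_zero_length_linker_with_separated_anchors_invalid(self, truth1):
        ref = truth1.reference_pose()
        short = docking.LinkerSpec("mobile_a", 1036, "mobile_b", 2001, 0)
        asm = docking.assemble_complex(truth1.static, truth1.mobile_a, ref,
                                       truth1.mobile_b, ref, linkers=[short])
        assert not asm.valid

    def test_long_vs_short_linker_at_hundred_angstroms(self, truth1):
        # anchors forced 100 A apart: 36 residues reach (136.8 A),
        # 22 residues do not (83.6 A)
        ref = truth1.reference_pose()
        moved = docking.DockingPose(np.eye(3), np.array([100.0, 0.0, 0.0]),
                                    0.0, 0.0, 0.0, 0, 0, 0)
        anchor_a = truth1.mobile_a.atom_coord(1036, "CA")
        anchor_b = truth1.mobile_b.atom_coord(2001, "CA") + [100.0, 0.0, 0.0]
        span = float(np.linalg.norm(anchor_a - anchor_b))
        long_l = docking.LinkerSpec("mobile_a", 1036, "mobile_b", 2001, 36)
        short_l = docking.LinkerSpec("mobile_a", 1036, "mobile_b", 2001, 22)
        asm = docking.assemble_complex(truth1.static, truth1.mobile_a, ref,
                                       truth1.mobile_b, moved,
                                       linkers=[long_l, short_l],
                                       clash_ceiling=10**9)
        verdicts = {v["n_residues"]: v for v in asm.linker_verdicts}
        assert verdicts[36]["max_reach_A"] == pytest.approx(136.8)
        assert verdicts[22]["max_reach_A"] == pytest.approx(83.6)
        if span <= 136.8:
            assert verdicts[36]["feasible"]
        if span > 83.6:
            assert not verdicts[22]["feasible"]
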