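"""Structure I/O, superposition, precision, geometry scans, restraint counts."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from bmap import structures as st
from bmap.synth import make_lobe

from conftest import make_model


def _toy_ensemble(n_models=3, displace=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = make_lobe(20, 1, shape=(3, 3, 3), jitter=0.5, rng=rng)
    models = []
    for i in range(n_models):
        coords = base.coords + (displace * i if displace else 0.0)
        models.append(st.StructureModel(base.chains, base.res_numbers, base.res_names,
                                        base.atom_names, base.elements, coords, i + 1))
    return st.StructureEnsemble(models, source="toy")


class TestEnsembleIO:
    def test_round_trip_preserves_models_and_coordinates(self, tmp_path):
        ens = _toy_ensemble(3, displace=1.0)
        path = tmp_path / "toy.pdb"
        st.write_ensemble(ens, path)
        back = st.read_ensemble(path)
        assert len(back) == 3
        for a, b in zip(ens, back):
            assert np.allclose(a.coords, b.coords, atol=1e-3)
            assert list(a.atom_names) == list(b.atom_names)

    def test_single_model_file_gives_ensemble_of_one(self, tmp_path):
        ens = _toy_ensemble(1)
        path = tmp_path / "single.pdb"
        st.write_ensemble(ens, path)
        assert len(st.read_ensemble(path)) == 1

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            st.read_ensemble("no_such_file.pdb")

    def test_inconsistent_rosters_rejected_with_model_ids(self):
        ens = _toy_ensemble(2)
        m2 = ens.models[1]
        bad = st.StructureModel(m2.chains[:-1], m2.res_numbers[:-1], m2.res_names[:-1],
                                m2.atom_names[:-1], m2.elements[:-1], m2.coords[:-1], 2)
        with pytest.raises(ValueError, match="2"):
            st.StructureEnsemble([ens.models[0], bad])


class TestSuperpose:
    def test_self_superposition_is_identity(self):
        m = _toy_ensemble(1).models[0]
        R, t, rmsd = st.superpose(m, m, atom_names=None)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    def test_known_rotation_recovered_as_inverse(self):
        m = _toy_ensemble(1).models[0]
        Rot = Rotation.from_quat([0.3, -0.2, 0.5, 0.79]).as_matrix()
        # orthonormalize the quaternion-derived matrix is exact already
        moved = m.transformed(Rot, np.array([1.0, -2.0, 3.0]))
        R, t, rmsd = st.superpose(moved, m, atom_names=None)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(R, Rot.T, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_grid_oracle_on_toy_pair(self):
        # 4-atom pair with hand displacement, planar rotation only: scan
        # angles exhaustively as an independent oracle
        ref = np.array([[0, 0, 0], [3, 0, 0], [3, 3, 0], [0, 3, 0.5]], float)
        mob = ref + np.array([0.4, -0.2, 0.3])
        mob[2] += [0.3, 0.1, 0.0]
        best = np.inf
        for ang in np.linspace(-0.2, 0.2, 4001):
            c, s = np.cos(ang), np.sin(ang)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            a = (mob - mob.mean(0)) @ R.T
            b = ref - ref.mean(0)
            best = min(best, np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
        _, _, rmsd = st.kabsch(mob, ref)
        # Kabsch searches all of SO(3), so it can only do better
        assert rmsd <= best + 1e-6

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            st.kabsch(line, line + 1.0)

    def test_idempotent_after_applying_transform(self):
        m = _toy_ensemble(1).models[0]
        Rot = Rotation.from_rotvec([0.4, 0.1, -0.3]).as_matrix()
        moved = m.transformed(Rot, np.array([5.0, 0.0, -2.0]))
        R, t, _ = st.superpose(moved, m, atom_names=None)
        fitted = moved.transformed(R, t)
        R2, t2, rmsd2 = st.superpose(fitted, m, atom_names=None)
        assert rmsd2 < 1e-8
        assert np.allclose(R2, np.eye(3), atol=1e-8)


class TestEnsemblePrecision:
    def test_identical_models_give_zero(self):
        ens = _toy_ensemble(4, displace=0.0)
        assert st.ensemble_precision(ens, range(1, 21), atom_names=None) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_matches_hand_formula(self):
        # two models identical except one atom displaced by d along x;
        # fitting on the other atoms leaves the transform at identity,
        # so precision over N atoms is exactly (d/2) * sqrt(1/N)
        n, d = 16, 0.8
        rng = np.random.default_rng(3)
        base = rng.normal(size=(n, 3)) * 5
        coords2 = base.copy()
        coords2[0, 0] += d
        mk = lambda xyz, i: st.StructureModel(
            np.full(n, "A"), np.arange(1, n + 1), np.full(n, "ALA"),
            np.full(n, "CA"), np.full(n, "C"), xyz, i)
        ens = st.StructureEnsemble([mk(base, 1), mk(coords2, 2)])
        got = st.ensemble_precision(ens, range(1, n + 1), atom_names=None,
                                    fit_residues=range(2, n + 1))
        expected = (d / 2) * np.sqrt(1.0 / n)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_global_rigid_transform(self):
        ens = _toy_ensemble(3, displace=0.5, seed=5)
        ref = st.ensemble_precision(ens, range(1, 21), atom_names=None)
        Rot = Rotation.from_rotvec([1.0, -0.5, 0.2]).as_matrix()
        moved = st.StructureEnsemble(
            [m.transformed(Rot, np.array([10.0, -3.0, 7.0])) for m in ens.models])
        assert st.ensemble_precision(moved, range(1, 21), atom_names=None) == pytest.approx(ref, abs=1e-6)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            st.ensemble_precision(_toy_ensemble(1), range(1, 21), atom_names=None)


class TestContacts:
    def test_disulfide_pair_detected(self):
        m = make_model([
            ("A", 1, "CYS", "SG", "S", (0.0, 0.0, 0.0)),
            ("A", 8, "CYS", "SG", "S", (2.04, 0.0, 0.0)),
        ])
        hits = st.scan_contacts(m, "disulfide")
        assert len(hits) == 1
        assert hits[0].distance == pytest.approx(2.04)
        assert {hits[0].residue_i[1], hits[0].residue_j[1]} == {1, 8}

    def test_greedy_pairing_uses_each_sg_once(self):
        # three SG in a row: only the closest pair bonds
        m = make_model([
            ("A", 1, "CYS", "SG", "S", (0.0, 0.0, 0.0)),
            ("A", 5, "CYS", "SG", "S", (2.0, 0.0, 0.0)),
            ("A", 9, "CYS", "SG", "S", (4.2, 0.0, 0.0)),
        ])
        hits = st.scan_contacts(m, "disulfide")
        assert len(hits) == 1
        assert {hits[0].residue_i[1], hits[0].residue_j[1]} == {1, 5}

    def test_salt_bridge_arg_glu(self):
        m = make_model([
            ("A", 10, "ARG", "NH1", "N", (0.0, 0.0, 0.0)),
            ("A", 40, "GLU", "OE1", "O", (3.5, 0.0, 0.0)),
        ])
        hits = st.scan_contacts(m, "salt-bridge")
        assert len(hits) == 1
        assert hits[0].residue_i[2] == "ARG" and hits[0].residue_j[2] == "GLU"
        assert hits[0].distance == pytest.approx(3.5)

    def test_one_hit_per_residue_pair_at_minimal_distance(self):
        m = make_model([
            ("A", 10, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("A", 40, "ASP", "OD1", "O", (3.9, 0.0, 0.0)),
            ("A", 40, "ASP", "OD2", "O", (3.1, 0.0, 0.0)),
        ])
        hits = st.scan_contacts(m, "salt-bridge")
        assert len(hits) == 1
        assert hits[0].atom_j == "OD2"
        assert hits[0].distance == pytest.approx(3.1)

    def test_unknown_kind_and_bad_cutoff_rejected(self):
        m = make_model([("A", 1, "CYS", "SG", "S", (0, 0, 0))])
        with pytest.raises(ValueError):
            st.scan_contacts(m, "hydrophobic")
        with pytest.raises(ValueError):
            st.scan_contacts(m, "disulfide", cutoff=-1)


class TestLinkerSpan:
    def test_coincident_anchors_zero_linker_feasible(self):
        span, reach, ok = st.linker_span_feasible((0, 0, 0), (0, 0, 0), 0)
        assert span == 0 and reach == 0 and ok

    @pytest.mark.parametrize(
        "span,n,expect_reach,expect_ok",
        [
            (140.0, 36, 136.8, False),  # 36 residues cannot span 140 A
            (80.0, 22, 83.6, True),     # the shorter 22-residue linker can span 80 A
            (100.0, 36, 136.8, True),
            (100.0, 22, 83.6, False),
        ],
    )
    def test_reach_arithmetic(self, span, n, expect_reach, expect_ok):
        got_span, reach, ok = st.linker_span_feasible((0, 0, 0), (span, 0, 0), n)
        assert got_span == pytest.approx(span)
        assert reach == pytest.approx(expect_reach)
        assert ok is expect_ok

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            st.linker_span_feasible((0, 0, 0), (1, 0, 0), -1)


class TestRestraintAccounting:
    def test_empty_table_all_zero(self):
        counts = st.summarize_restraints(pd.DataFrame({"category": []}))
        assert counts["total_noe"] == 0 and counts["inter"] == 0

    def test_classification_is_pure_function_of_separation(self):
        assert st.classify_noe(5, 5) == "intra"
        assert st.classify_noe(5, 6) == "sequential"
        assert st.classify_noe(5, 9) == "short"
        assert st.classify_noe(5, 10) == "long"

    def test_random_table_matches_independent_recount(self):
        rng = np.random.default_rng(11)
        res_i = rng.integers(1, 60, 100)
        res_j = rng.integers(1, 60, 100)
        cats = [st.classify_noe(i, j) for i, j in zip(res_i, res_j)]
        table = pd.DataFrame({"res_i": res_i, "res_j": res_j, "upper": 5.0, "category": cats})
        counts = st.summarize_restraints(table)
        # brute-force recount, independent of the summarizer
        brute = {c: 0 for c in st.ALL_CATEGORIES}
        for i, j in zip(res_i, res_j):
            sep = abs(int(i) - int(j))
            key = ("intra" if sep == 0 else "sequential" if sep == 1
                   else "short" if sep < 5 else "long")
            brute[key] += 1
        for cat in ("intra", "sequential", "short", "long"):
            assert counts[cat] == brute[cat]
        assert counts["inter"] == counts["sequential"] + counts["short"] + counts["long"]
        assert counts["unambiguous"] == counts["intra"] + counts["inter"]
        assert counts["total_noe"] == counts["unambiguous"] + counts["ambiguous"]

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            st.summarize_restraints(pd.DataFrame({"category": ["mystery"]}))
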