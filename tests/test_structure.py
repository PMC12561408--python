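"""Structure parsing, superposition, SASA/SAP and confidence metrics."""

import math

import numpy as np
import pytest

from _oracles import quaternion_rmsd

from pepfunnel.structure import (AtomRecord, EfficacyThresholds, PAEMatrix,
                                 StructScore, StructureModel, ca_rmsd,
                                 derive_thresholds, efficacy_gate,
                                 ingest_affinity, interface_pae, kabsch,
                                 mean_plddt, read_pae_json, read_pdb, sap,
                                 score_complex, shrake_rupley, tm_d0,
                                 tm_score, write_pae_json, write_pdb)
from pepfunnel.synth import build_ideal_helix, perturb_structure


def single_atom_model(element="C", xyz=(0.0, 0.0, 0.0)):
    m = StructureModel()
    m.add_atom(AtomRecord(1, element, "ALA", "A", 1, np.array(xyz),
                          element=element))
    return m


class TestPdbIO:
    def test_round_trip_coordinates_and_plddt(self, tmp_path, helix_model):
        path = tmp_path / "h.pdb"
        write_pdb(helix_model, path)
        back = read_pdb(path)
        orig = list(helix_model.iter_atoms())
        parsed = list(back.iter_atoms())
        assert len(parsed) == len(orig)
        for a, b in zip(orig, parsed):
            assert np.allclose(a.xyz, b.xyz, atol=5e-4)
        assert mean_plddt(back, "A") == 100.0

    def test_ca_bfactor_becomes_residue_plddt(self, tmp_path):
        path = tmp_path / "x.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00 80.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000"
            "  1.00 91.20           C\n"
        )
        model = read_pdb(path)
        assert model.chains["A"].residues[1].plddt == pytest.approx(91.20)

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  CA  ALA A   1     1.0 2.0\n")
        with pytest.raises(ValueError, match=":1:"):
            read_pdb(path)

    def test_non_primary_altloc_dropped(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000"
            "  0.50 90.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000"
            "  0.50 90.00           C\n"
        )
        model = read_pdb(path)
        assert len(model.chains["A"].residues[1].atoms) == 1

    def test_empty_model_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing\n")
        with pytest.raises(ValueError, match="no ATOM"):
            read_pdb(path)


class TestPaeIO:
    def test_index_map_follows_chain_lengths(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text('{"predicted_aligned_error": '
                        '[[0,1,2,3],[1,0,2,2],[2,2,0,1],[3,2,1,0]]}')
        pae = read_pae_json(path, {"A": 2, "B": 2})
        assert list(pae.chain_rows("A")) == [0, 1]
        assert list(pae.chain_rows("B")) == [2, 3]

    def test_list_wrapped_dialect(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text('[{"pae": [[0,1],[1,0]]}]')
        assert read_pae_json(path, {"A": 1, "B": 1}).matrix.shape == (2, 2)

    def test_non_square_rejected(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text('{"predicted_aligned_error": '
                        '[[0,1,2,3],[1,0,2,2],[2,2,0,1]]}')
        with pytest.raises(ValueError, match="square"):
            read_pae_json(path, {"A": 2, "B": 2})

    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(5)
        m = np.abs(rng.normal(5, 2, size=(6, 6)))
        pae = PAEMatrix(m, tuple(("A", i + 1) for i in range(6)))
        path = tmp_path / "pae.json"
        write_pae_json(pae, path)
        back = read_pae_json(path, {"A": 6})
        assert np.array_equal(back.matrix, pae.matrix)


class TestKabsch:
    def test_identical_point_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch(pts, pts)[2] == pytest.approx(0.0, abs=1e-12)

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0],
                        [0.0, 0.0, 1.0]])  # 90 deg about z
        moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
        assert kabsch(pts, moved)[2] == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        r, _, _ = kabsch(a, b)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            assert kabsch(a, b)[2] == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCaRmsd:
    def test_self_rmsd_zero(self, helix_model):
        assert ca_rmsd(helix_model, helix_model) == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_single_displaced_ca_matches_oracle(self, helix_model):
        moved = perturb_structure(helix_model, 0.0)
        first = next(iter(moved.chains["A"].residues.values()))
        first.atom("CA").xyz = first.atom("CA").xyz + np.array([1.0, 0, 0])
        ref_ca = np.array(list(helix_model.ca_coords("A").values()))
        mod_ca = np.array(list(moved.ca_coords("A").values()))
        assert ca_rmsd(moved, helix_model) == pytest.approx(
            quaternion_rmsd(ref_ca, mod_ca), abs=1e-9)

    def test_invariant_to_global_rotation(self, helix_model):
        rng = np.random.default_rng(9)
        moved = perturb_structure(helix_model, 0.2, seed=4)
        base = ca_rmsd(moved, helix_model)
        theta = rng.uniform(0, 2 * math.pi)
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        for atom in moved.iter_atoms():
            atom.xyz = rot @ atom.xyz + np.array([3.0, -1.0, 2.0])
        assert ca_rmsd(moved, helix_model) == pytest.approx(base, abs=1e-9)


class TestTmScore:
    def test_identity_scores_one(self, helix_model):
        assert tm_score(helix_model, helix_model) == pytest.approx(1.0)

    def test_d0_for_31_residues(self):
        assert tm_d0(31) == pytest.approx(1.3246, abs=1e-4)

    def test_all_pairs_at_d0_give_half(self):
        # radial expansion of a tetrahedral point cloud: the optimal
        # rotation is the identity, every pair sits at exactly d0
        base = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                         [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        rho = math.sqrt(3.0)
        d0 = tm_d0(4)  # clamped to 0.5 for a 4-residue reference
        scale = 1.0 + d0 / rho

        ref = StructureModel()
        mod = StructureModel()
        for i, p in enumerate(base):
            ref.add_atom(AtomRecord(i + 1, "CA", "ALA", "A", i + 1, p,
                                    element="C"))
            mod.add_atom(AtomRecord(i + 1, "CA", "ALA", "A", i + 1,
                                    p * scale, element="C"))
        assert tm_score(ref, mod) == pytest.approx(0.5, abs=1e-9)

    def test_score_in_unit_interval_and_decreasing_with_noise(self,
                                                              helix_model):
        prev = 1.0
        for sigma in (0.2, 0.8, 2.0):
            score = tm_score(helix_model,
                             perturb_structure(helix_model, sigma, seed=8))
            assert 0.0 < score <= 1.0
            assert score < prev
            prev = score


class TestShrakeRupley:
    def test_isolated_carbon_matches_sphere_area(self):
        area = shrake_rupley(single_atom_model())[0]
        assert area == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2,
                                     rel=0.02)

    def test_far_apart_atoms_unoccluded(self):
        m = StructureModel()
        m.add_atom(AtomRecord(1, "C", "ALA", "A", 1, np.zeros(3),
                              element="C"))
        m.add_atom(AtomRecord(2, "C", "ALA", "A", 2,
                              np.array([50.0, 0, 0]), element="C"))
        areas = shrake_rupley(m)
        iso = shrake_rupley(single_atom_model())[0]
        assert areas[0] == pytest.approx(iso)
        assert areas[1] == pytest.approx(iso)

    def test_caged_atom_fully_buried(self):
        m = StructureModel()
        m.add_atom(AtomRecord(1, "C", "ALA", "A", 1, np.zeros(3),
                              element="C"))
        serial = 2
        # dense shell of atoms just outside the central sphere
        for theta in np.linspace(0, math.pi, 10):
            for phi in np.linspace(0, 2 * math.pi, 20, endpoint=False):
                xyz = 2.2 * np.array([
                    math.sin(theta) * math.cos(phi),
                    math.sin(theta) * math.sin(phi), math.cos(theta)])
                m.add_atom(AtomRecord(serial, "C", "ALA", "A", serial, xyz,
                                      element="C"))
                serial += 1
        assert shrake_rupley(m)[0] == 0.0

    def test_total_area_nonincreasing_as_atoms_approach(self):
        totals = []
        for sep in np.linspace(8.0, 1.0, 15):
            m = StructureModel()
            m.add_atom(AtomRecord(1, "C", "ALA", "A", 1, np.zeros(3),
                                  element="C"))
            m.add_atom(AtomRecord(2, "C", "ALA", "A", 2,
                                  np.array([sep, 0, 0]), element="C"))
            totals.append(sum(shrake_rupley(m)))
        assert all(a >= b - 1e-6 for a, b in zip(totals, totals[1:]))

    def test_quadrature_convergence_on_helix(self, helix_model):
        coarse = shrake_rupley(helix_model, n_points=256)
        fine = shrake_rupley(helix_model, n_points=960)
        scale = 4 * math.pi * (1.70 + 1.4) ** 2
        for c, f in zip(coarse, fine):
            # per-atom difference under 3% of the atomic sphere area
            assert abs(c - f) <= 0.03 * scale

    def test_minimum_point_count_enforced(self, helix_model):
        with pytest.raises(ValueError, match="64"):
            shrake_rupley(helix_model, n_points=32)


class TestSap:
    def test_no_side_chain_atoms_no_sap(self):
        # poly-Gly has no side-chain heavy atoms at all
        from conftest import make_record
        model = build_ideal_helix(make_record("G" * 10))
        per_res, aggregate = sap(model)
        assert aggregate == 0.0
        assert all(v == 0.0 for v in per_res.values())

    def test_exposed_ala_side_chain_bounded_by_hydrophobicity(self):
        from conftest import make_record
        from pepfunnel.residues import SAP_HYDROPHOBICITY
        model = build_ideal_helix(make_record("A"))
        per_res, aggregate = sap(model)
        value = per_res[("A", 7)]
        areas = shrake_rupley(model)
        cb_idx = [i for i, a in enumerate(model.iter_atoms())
                  if a.name == "CB"][0]
        expected = areas[cb_idx] / 67.0 * SAP_HYDROPHOBICITY["A"]
        assert value == pytest.approx(expected)
        assert 0 < value <= SAP_HYDROPHOBICITY["A"] * 1.5

    def test_occlusion_lowers_residue_sap(self):
        # burying the side chain lowers that residue's SAP (monotone in
        # exposure); the occluder is a backbone-named atom so it adds no
        # hydrophobic contribution of its own
        from conftest import make_record
        model = build_ideal_helix(make_record("A"))
        free = sap(model)[0][("A", 7)]
        cb = [a for a in model.iter_atoms() if a.name == "CB"][0]
        occluded = build_ideal_helix(make_record("A"))
        occluded.add_atom(AtomRecord(99, "C", "GLY", "B", 1,
                                     cb.xyz + np.array([1.8, 0, 0]),
                                     element="C"))
        assert sap(occluded)[0][("A", 7)] < free


class TestConfidence:
    def test_mean_plddt_examples(self):
        m = StructureModel()
        for i, b in enumerate((80.0, 100.0)):
            m.add_atom(AtomRecord(i + 1, "CA", "ALA", "A", i + 1,
                                  np.array([float(i) * 3.8, 0, 0]),
                                  bfactor=b, element="C"))
        assert mean_plddt(m, "A") == pytest.approx(90.0)

    def test_missing_chain_rejected(self, helix_model):
        with pytest.raises(KeyError):
            mean_plddt(helix_model, "Z")

    def test_intra_chain_entries_excluded(self):
        index = tuple(("A", i + 1) for i in range(2)) + \
            tuple(("B", i + 1) for i in range(2))
        m = np.full((4, 4), 30.0)
        m[0:2, 2:4] = 5.0
        m[2:4, 0:2] = 5.0
        assert interface_pae(PAEMatrix(m, index), "A", "B") == 5.0

    def test_asymmetric_blocks_average_evenly(self):
        index = tuple(("A", i + 1) for i in range(2)) + \
            tuple(("B", i + 1) for i in range(3))
        m = np.zeros((5, 5))
        m[0:2, 2:5] = 4.0  # 6 entries
        m[2:5, 0:2] = 8.0  # 6 entries
        assert interface_pae(PAEMatrix(m, index), "A", "B") == \
            pytest.approx(6.0)

    def test_symmetric_matrix_equals_single_block_mean(self):
        rng = np.random.default_rng(12)
        block = np.abs(rng.normal(6, 1, size=(3, 4)))
        m = np.zeros((7, 7))
        m[0:3, 3:7] = block
        m[3:7, 0:3] = block.T
        index = tuple(("A", i + 1) for i in range(3)) + \
            tuple(("B", i + 1) for i in range(4))
        assert interface_pae(PAEMatrix(m, index), "A", "B") == \
            pytest.approx(block.mean())

    def test_affine_shift_of_inter_blocks(self):
        rng = np.random.default_rng(13)
        m = np.abs(rng.normal(5, 1, size=(6, 6)))
        index = tuple(("A", i + 1) for i in range(3)) + \
            tuple(("B", i + 1) for i in range(3))
        base = interface_pae(PAEMatrix(m, index), "A", "B")
        shifted = interface_pae(PAEMatrix(m + 2.5, index), "A", "B")
        assert shifted == pytest.approx(base + 2.5)


class TestThresholdsAndGate:
    REF = StructScore(tm=1.0, ca_rmsd=0.0, mean_plddt=95.0,
                      interface_pae=5.0, sap_aggregate=4.0)

    def test_slack_arithmetic(self):
        thr = derive_thresholds(self.REF, 0.1)
        assert thr.min_tm == pytest.approx(0.9)
        assert thr.max_ca_rmsd == pytest.approx(0.55)  # floored at 0.5
        assert thr.min_mean_plddt == pytest.approx(85.5)
        assert thr.max_interface_pae == pytest.approx(5.5)

    def test_zero_slack_equals_reference_with_rmsd_floor(self):
        thr = derive_thresholds(self.REF, 0.0)
        assert thr.min_tm == 1.0
        assert thr.max_ca_rmsd == 0.5
        assert thr.max_interface_pae == 5.0

    def test_thresholds_monotone_in_slack(self):
        t1 = derive_thresholds(self.REF, 0.05)
        t2 = derive_thresholds(self.REF, 0.2)
        assert t2.min_tm < t1.min_tm
        assert t2.max_interface_pae > t1.max_interface_pae

    def test_reference_passes_its_own_slackened_gate(self):
        thr = derive_thresholds(self.REF, 0.1)
        assert efficacy_gate(self.REF, thr).passed

    def test_single_violation_single_reason(self):
        thr = derive_thresholds(self.REF, 0.1)
        bad = StructScore(tm=0.95, ca_rmsd=0.3, mean_plddt=90.0,
                          interface_pae=9.0, sap_aggregate=4.0)
        res = efficacy_gate(bad, thr)
        assert not res.passed
        assert len(res.reasons) == 1
        assert res.reasons[0][0] == "interface_pae_max"

    def test_missing_required_score_rejected(self):
        thr = EfficacyThresholds(max_affinity=-20.0)
        with pytest.raises(ValueError, match="affinity"):
            efficacy_gate(StructScore(tm=1.0), thr)


class TestScoreComplex:
    def test_reference_scored_against_itself(self, complex_model):
        score = score_complex(complex_model, complex_model)
        assert score.tm == pytest.approx(1.0)
        assert score.ca_rmsd == pytest.approx(0.0, abs=1e-9)
        assert score.mean_plddt == 100.0
        assert score.sap_aggregate > 0


class TestAffinityIngest:
    def test_three_rows(self, tmp_path):
        path = tmp_path / "aff.tsv"
        path.write_text("id\taffinity\nD01\t-45.2\nD02\t-38.1\nD03\t-51\n")
        assert ingest_affinity(path) == {"D01": -45.2, "D02": -38.1,
                                         "D03": -51.0}

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "aff.tsv"
        path.write_text("id\taffinity\nD01\t-45.2\nD01\t-38.1\n")
        with pytest.raises(ValueError, match="duplicate"):
            ingest_affinity(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "aff.tsv"
        path.write_text("id\taffinity\nD01\tstrong\n")
        with pytest.raises(ValueError, match="non-numeric"):
            ingest_affinity(path)

    def test_header_only_gives_empty_map(self, tmp_path):
        path = tmp_path / "aff.tsv"
        path.write_text("id\taffinity\n")
        assert ingest_affinity(path) == {}
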