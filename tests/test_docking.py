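"""Pocket parsing, coordinate extraction, distances, positive calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moanet.docking import (DockingPose, PocketSpec, classify_pose,
                            extract_pocket_coords, min_distance,
                            parse_pocket_table, read_pose_table,
                            summarize_candidates, write_pocket_table)
from moanet.errors import InputError, ValidationError
from moanet.synthetic import generate_pose_table, write_mini_pdb


def pocket_csv(tmp_path, rows):
    p = tmp_path / "pockets.csv"
    p.write_text("candidate,uniprot,pdb_id,chain,residues,pocket_type\n"
                 + "".join(",".join(r) + "\n" for r in rows))
    return p


class TestPocketTable:
    def test_bh4_domain_row_has_21_positions(self, tmp_path):
        residues = ";".join(str(i) for i in range(10, 31))
        p = pocket_csv(tmp_path, [("BCL2", "P10415", "2XA0", "A", residues,
                                   "BH4 domain (entire)")])
        specs = parse_pocket_table(p)
        assert len(specs[0].residue_positions) == 21
        assert specs[0].residue_positions == tuple(range(10, 31))

    def test_individual_histidines_row(self, tmp_path):
        p = pocket_csv(tmp_path, [("BCL2", "P10415", "2XA0", "A",
                                   "3;20;94;184;186",
                                   "Individual histidines")])
        assert parse_pocket_table(p)[0].residue_positions == (3, 20, 94,
                                                              184, 186)

    def test_bh3_domain_row_has_15_positions(self, tmp_path):
        residues = ";".join(str(i) for i in range(59, 74))
        p = pocket_csv(tmp_path, [("BAX", "Q07812", "2K7W", "A", residues,
                                   "BH3 domain (entire)")])
        assert len(parse_pocket_table(p)[0].residue_positions) == 15

    def test_non_integer_token_reported(self, tmp_path):
        p = pocket_csv(tmp_path, [("BCL2", "P10415", "2XA0", "A",
                                   "10;eleven;12", "BH4")])
        with pytest.raises(ValidationError, match="residues"):
            parse_pocket_table(p)

    def test_round_trip_bit_identical(self, tmp_path):
        p = pocket_csv(tmp_path, [
            ("BCL2", "P10415", "2XA0", "A", "3;20;94;184;186", "histidines"),
            ("BAX", "Q07812", "2K7W", "A", "59;60;61", "BH3 part"),
        ])
        specs = parse_pocket_table(p)
        out1 = tmp_path / "o1.csv"
        out2 = tmp_path / "o2.csv"
        write_pocket_table(out1, specs)
        write_pocket_table(out2, parse_pocket_table(out1))
        assert out1.read_text() == out2.read_text()

    def test_bad_pdb_id_rejected(self):
        with pytest.raises(ValidationError):
            PocketSpec("X", "P1", "TOOLONG", "A", (1,))


class TestPocketCoords:
    def test_selects_only_listed_residues(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        expected = write_mini_pdb(pdb, n_residues=3)
        spec = PocketSpec("X", "P00000", "1ABC", "A", (1, 2))
        coords, missing = extract_pocket_coords(pdb, spec)
        assert missing == []
        want = np.array(expected[1] + expected[2])
        assert coords.shape == want.shape  # hydrogens excluded
        assert np.allclose(np.sort(coords, axis=0), np.sort(want, axis=0))

    def test_absent_residue_reported_missing(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        write_mini_pdb(pdb, n_residues=2)
        spec = PocketSpec("X", "P00000", "1ABC", "A", (1, 99))
        coords, missing = extract_pocket_coords(pdb, spec)
        assert missing == [99]
        assert len(coords) == 3

    def test_highest_occupancy_altloc_wins(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        expected = write_mini_pdb(pdb, n_residues=1)
        spec = PocketSpec("X", "P00000", "1ABC", "A", (1,))
        coords, _ = extract_pocket_coords(pdb, spec)
        # the 0.30-occupancy CA conformer sits 5 A away and must be absent
        ca = np.array(expected[1][1])
        assert any(np.allclose(c, ca) for c in coords)
        assert not any(np.allclose(c, ca + [5, 0, 0]) for c in coords)

    def test_no_residues_resolved_raises(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        write_mini_pdb(pdb, n_residues=2)
        spec = PocketSpec("X", "P00000", "1ABC", "A", (50, 60))
        with pytest.raises(InputError):
            extract_pocket_coords(pdb, spec)

    def test_missing_chain_raises(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        write_mini_pdb(pdb, n_residues=1)
        spec = PocketSpec("X", "P00000", "1ABC", "B", (1,))
        with pytest.raises(InputError, match="chain"):
            extract_pocket_coords(pdb, spec)


class TestMinDistance:
    def test_three_four_five(self):
        assert min_distance([[0, 0, 0]], [[3, 4, 0]]) == pytest.approx(5.0)

    def test_coincident_points(self):
        assert min_distance([[1, 1, 1]], [[1, 1, 1]]) == 0.0

    def test_matches_brute_force_on_clouds(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(50, 3)), rng.normal(size=(50, 3))
        brute = min(np.linalg.norm(x - y) for x in a for y in b)
        assert min_distance(a, b) == pytest.approx(brute, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            min_distance([], [[0, 0, 0]])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10**6))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(int(rng.integers(1, 8)), 3))
        b = rng.normal(size=(int(rng.integers(1, 8)), 3))
        d = min_distance(a, b)
        assert d >= 0
        assert d == pytest.approx(min_distance(b, a))


class TestClassifyPose:
    @pytest.mark.parametrize("energy,dist,expected", [
        (-7.2, 3.1, True),
        (-5.9, 3.1, False),
        (-7.2, 6.0, False),
        (-6.0, 5.0, False),   # strict boundaries fail
        (-6.0, 3.0, False),
        (-6.1, 5.0, False),
        (-6.0001, 4.9999, True),
    ])
    def test_strict_thresholds(self, energy, dist, expected):
        pose = DockingPose("lig", "p", energy, dist)
        assert classify_pose(pose) is expected

    def test_missing_distance_rejected(self):
        with pytest.raises(ValidationError):
            classify_pose(DockingPose("lig", "p", -7.0, None))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-12, 0), st.floats(0, 10),
           st.floats(0, 3), st.floats(0, 3))
    def test_monotone_in_both_axes(self, energy, dist, de, dd):
        """Lowering energy or shrinking distance never loses a positive."""
        before = classify_pose(DockingPose("l", "p", energy, dist))
        after = classify_pose(DockingPose("l", "p", energy - de,
                                          max(0.0, dist - dd)))
        assert after or not before


class TestSummarize:
    def test_planted_positives_recovered_and_all_validated(self):
        poses, pockets, gt = generate_pose_table(seed=6)
        positives = [p.ligand_id for p in poses if classify_pose(p)]
        assert positives == gt["positives"]
        reports = summarize_candidates(poses, pockets)
        assert [r.candidate for r in reports] == gt["candidates"]
        assert all(r.validated for r in reports)

    def test_only_negative_poses_not_validated(self):
        poses, pockets, _ = generate_pose_table(seed=6, frac_positive=0.0)
        reports = summarize_candidates(poses, pockets)
        assert not any(r.validated for r in reports)

    def test_best_pose_is_lowest_energy_positive(self):
        pockets = [PocketSpec("C", "P1", "1AAA", "A", (1, 2), "site")]
        label = pockets[0].label
        poses = [DockingPose("a", label, -7.0, 1.0),
                 DockingPose("b", label, -9.0, 1.0),
                 DockingPose("c", label, -11.0, 9.0)]  # distance fails
        rep = summarize_candidates(poses, pockets)[0]
        assert rep.best_pose_per_pocket[label].ligand_id == "b"

    def test_orphan_pocket_reference_raises(self):
        pockets = [PocketSpec("C", "P1", "1AAA", "A", (1,), "site")]
        poses = [DockingPose("a", "nope", -7.0, 1.0)]
        with pytest.raises(InputError):
            summarize_candidates(poses, pockets)

    def test_empty_pose_list_gives_unvalidated_report(self):
        pockets = [PocketSpec("C", "P1", "1AAA", "A", (1,), "site")]
        reports = summarize_candidates([], pockets)
        assert len(reports) == 1 and not reports[0].validated

    def test_pose_table_round_trip(self, tmp_path):
        poses, pockets, _ = generate_pose_table(seed=1, n_poses=10)
        import pandas as pd
        import dataclasses
        p = tmp_path / "poses.csv"
        pd.DataFrame([dataclasses.asdict(x) for x in poses]).to_csv(
            p, index=False)
        again = read_pose_table(p)
        assert [a.ligand_id for a in again] == [a.ligand_id for a in poses]
        for a, b in zip(again, poses):
            assert a.binding_energy == pytest.approx(b.binding_energy)
            assert a.min_distance == pytest.approx(b.min_distance)
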