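import numpy as np
import pytest

import inbredkit as ik
from inbredkit.pedigree import (Pedigree, PedigreeError, PedigreeRecord as R,
                                load_pedigree, write_pedigree)

from oracles import random_pedigree


class TestLoading:
    def test_minimal_trio(self, tmp_path):
        f = tmp_path / "ped.csv"
        f.write_text("id,sire,dam\nA,0,0\nB,0,0\nC,A,B\n")
        ped = load_pedigree(f)
        assert len(ped) == 3
        assert set(ped.founders) == {"A", "B"}

    def test_unlisted_parent_promoted_to_founder(self, tmp_path):
        f = tmp_path / "ped.csv"
        f.write_text("id,sire,dam\nA,0,0\nB,0,0\nC,X,B\n")
        ped = load_pedigree(f)
        assert len(ped) == 4
        assert ped.is_founder("X")
        assert ped.record("X").sex == "male"

    def test_cycle_is_an_error(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree.from_records([R("B"), R("C", "A", "B"), R("A", "C", None)])

    def test_duplicate_id_is_an_error(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            Pedigree.from_records([R("A"), R("A")])

    def test_self_parent_is_an_error(self):
        with pytest.raises(PedigreeError, match="own parent"):
            R("A", "A", None)

    def test_bad_row_reports_line_number(self, tmp_path):
        f = tmp_path / "ped.csv"
        f.write_text("id,sire,dam,birth_year\nA,0,0,1990\nB,0,0,notayear\n")
        with pytest.raises(PedigreeError, match="line 3"):
            load_pedigree(f)

    def test_tab_separated_no_header(self, tmp_path):
        f = tmp_path / "ped.tsv"
        f.write_text("A\t0\t0\nB\t0\t0\nC\tA\tB\n")
        ped = load_pedigree(f)
        assert ped.parents("C") == ("A", "B")

    def test_roundtrip(self, tmp_path, full_sib_pedigree):
        out = tmp_path / "out.csv"
        write_pedigree(full_sib_pedigree, out)
        again = load_pedigree(out)
        assert again.ids == full_sib_pedigree.ids
        assert again.parents("X") == ("C", "D")


class TestDepthMetrics:
    def test_equivalent_generations(self, trio):
        assert trio.equivalent_generations("A") == 0.0
        assert trio.equivalent_generations("C") == 1.0
        # both parents known, all four grandparents known founders -> 2.0
        ped = Pedigree.from_records([
            R("G1"), R("G2"), R("G3"), R("G4"),
            R("S", "G1", "G2"), R("D", "G3", "G4"), R("X", "S", "D"),
        ])
        assert ped.equivalent_generations("X") == pytest.approx(2.0)

    def test_generation_counts(self, trio):
        assert trio.generation_counts("A") == (0, 0)
        # parents known, one maternal grandsire known, nothing else
        ped = Pedigree.from_records([
            R("GS"), R("S"), R("D", "GS", None), R("X", "S", "D"),
        ])
        assert ped.generation_counts("X") == (1, 2)

    def test_three_complete_generations(self):
        recs = [R(f"G{k}") for k in range(8)]
        recs += [R("P0", "G0", "G1"), R("P1", "G2", "G3"),
                 R("P2", "G4", "G5"), R("P3", "G6", "G7")]
        recs += [R("S", "P0", "P1"), R("D", "P2", "P3"), R("X", "S", "D")]
        ped = Pedigree.from_records(recs)
        assert ped.generation_counts("X") == (3, 3)
        assert ped.equivalent_generations("X") == pytest.approx(3.0)

    def test_completeness(self, trio):
        assert np.allclose(trio.completeness("A", 3), [0, 0, 0])
        ped = Pedigree.from_records([
            R("G1"), R("G2"), R("S", "G1", "G2"), R("D"), R("X", "S", "D"),
        ])
        # parents known, 2 of 4 grandparents known
        assert np.allclose(ped.completeness("X", 2), [1.0, 0.5])

    def test_completeness_one_up_to_full_generations(self, rng):
        for _ in range(30):
            ped = random_pedigree(rng)
            for i in ped.ids:
                full, mx = ped.generation_counts(i)
                eq = ped.equivalent_generations(i)
                assert full <= mx
                assert eq <= mx
                if full:
                    comp = ped.completeness(i, full)
                    assert np.allclose(comp, 1.0)


class TestTruncation:
    def test_truncation_beyond_depth_is_identity(self, full_sib_pedigree):
        sub = full_sib_pedigree.truncate_to_depth("X", 10)
        assert set(sub.ids) == set(full_sib_pedigree.ids)
        assert sub.parents("X") == ("C", "D")

    def test_depth_one_makes_parents_founders(self, full_sib_pedigree):
        sub = full_sib_pedigree.truncate_to_depth("X", 1)
        assert set(sub.ids) == {"C", "D", "X"}
        assert sub.is_founder("C") and sub.is_founder("D")

    def test_chain_cut_at_two(self):
        ped = Pedigree.from_records([
            R("W"), R("Z"), R("A", "W", "Z"), R("B", "A", None), R("C", "B", None),
        ])
        sub = ped.truncate_to_depth("C", 2)
        assert set(sub.ids) == {"A", "B", "C"}
        assert sub.is_founder("A")

    def test_truncation_shrinks_depth_metrics(self, rng):
        # full generations cannot exceed the cut (the shortest path to any
        # depth-g ancestor is forced open); equivalent generations cannot
        # grow.  A strict eq <= g bound only holds when no ancestor is
        # reachable at several depths, as in a chain pedigree.
        for _ in range(20):
            ped = random_pedigree(rng)
            for i in ped.ids[-3:]:
                g = int(rng.integers(1, 5))
                sub = ped.truncate_to_depth(i, g)
                assert sub.generation_counts(i)[0] <= g
                assert sub.equivalent_generations(i) <= ped.equivalent_generations(i) + 1e-12

    def test_truncated_chain_equivalent_generations_bounded(self):
        recs = [R("A0")]
        for t in range(1, 7):
            recs.append(R(f"A{t}", f"A{t-1}", None))
        ped = Pedigree.from_records(recs)
        for g in (1, 2, 3):
            sub = ped.truncate_to_depth("A6", g)
            assert sub.equivalent_generations("A6") <= g


class TestCommonAncestors:
    def test_unrelated_founder_parents(self, trio):
        assert trio.common_ancestors("C") == 0

    def test_full_sib_offspring_shares_two_grandparents(self, full_sib_pedigree):
        assert full_sib_pedigree.common_ancestors("X") == 2

    def test_parent_offspring_mating(self):
        ped = Pedigree.from_records([
            R("S"), R("M"), R("D", "S", "M"), R("X", "S", "D"),
        ])
        assert ped.common_ancestors("X") == 1

    def test_missing_parent_convention(self):
        ped = Pedigree.from_records([R("S"), R("X", "S", None)])
        assert ped.common_ancestors("X") == 0


def test_generational_intervals():
    ped = Pedigree.from_records([
        R("A", birth_year=1953), R("B", birth_year=1960), R("C", "A", "B",
                                                            birth_year=1969),
        R("D"),
    ])
    bins = ped.generational_intervals(10)
    assert bins["A"] == 1950 and bins["B"] == 1960 and bins["C"] == 1960
    assert np.isnan(bins["D"])


def test_topological_order_invariant(rng):
    for _ in range(25):
        ped = random_pedigree(rng)
        for i in range(len(ped)):
            assert ped.sire_pos[i] < i and ped.dam_pos[i] < i
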