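import numpy as np
import pandas as pd
import pytest

import inbredkit as ik
from inbredkit.pedcoef import (GeneDropConfig, ancestor_contributions,
                               ballou_recursive, classical_F,
                               effective_ancestors, effective_founders,
                               founder_contributions, gene_drop,
                               kalinowski_decomposition, F_at_depth,
                               relationship_matrix)
from inbredkit.pedigree import Pedigree, PedigreeRecord as R

from oracles import enumerate_gene_drop, random_pedigree, wright_F


class TestClassicalF:
    def test_textbook_values(self, trio, full_sib_pedigree, half_sib_pedigree,
                             cousin_pedigree):
        assert classical_F(trio)["C"] == 0.0
        assert classical_F(full_sib_pedigree)["X"] == pytest.approx(0.25)
        assert classical_F(half_sib_pedigree)["X"] == pytest.approx(0.125)
        assert classical_F(cousin_pedigree)["X"] == pytest.approx(0.0625)

    def test_full_sib_line_recurrence(self, full_sib_line):
        # F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4
        F = classical_F(full_sib_line)
        expected = [0.0, 0.25, 0.375, 0.5]
        got = [F[f"A{t}"] for t in range(1, 5)]
        assert np.allclose(got, expected)

    def test_matches_wright_path_counting(self, rng):
        for _ in range(60):
            ped = random_pedigree(rng)
            tab = classical_F(ped)
            oracle = wright_F(ped)
            for i in ped.ids:
                assert tab[i] == pytest.approx(oracle[i], abs=1e-12)

    def test_relationship_matrix_diagonal(self, full_sib_pedigree):
        A = relationship_matrix(full_sib_pedigree)
        assert np.allclose(np.diag(A), [1, 1, 1, 1, 1.25])
        assert np.allclose(A, A.T)


class TestFAtDepth:
    def test_loop_inside_horizon(self, full_sib_pedigree):
        assert F_at_depth(full_sib_pedigree, 3)["X"] == pytest.approx(0.25)

    def test_loop_beyond_horizon_vanishes(self):
        # the only inbreeding loop closes at depth 5: parents are related
        # solely through a shared founder pair four meioses up each side
        recs = [R("P"), R("Q"), R("a1", "P", "Q"), R("b1", "P", "Q")]
        for t in range(2, 5):
            recs += [R(f"ma{t}"), R(f"mb{t}"),
                     R(f"a{t}", f"a{t-1}", f"ma{t}"),
                     R(f"b{t}", f"b{t-1}", f"mb{t}")]
        recs.append(R("X", "a4", "b4"))
        ped = Pedigree.from_records(recs)
        F = classical_F(ped)["X"]
        assert F == pytest.approx(2 * 0.5 ** 9)
        assert F_at_depth(ped, 3)["X"] == 0.0
        deep = ped.generation_counts("X")[1]
        assert F_at_depth(ped, deep)["X"] == pytest.approx(F)

    def test_monotone_and_converges_to_F(self, rng):
        for _ in range(15):
            ped = random_pedigree(rng)
            F = classical_F(ped)
            prev = pd.Series(0.0, index=ped.ids)
            for g in (1, 2, 3, 6, 12):
                cur = F_at_depth(ped, g)
                assert (cur >= prev - 1e-12).all()
                prev = cur
            assert np.allclose(prev, F)


class TestBallou:
    def test_zero_cases(self, trio, full_sib_pedigree):
        assert ballou_recursive(trio).eq(0).all()
        # X itself is inbred but its ancestors are not
        assert ballou_recursive(full_sib_pedigree)["X"] == 0.0

    def test_one_step_recursion(self):
        # two unrelated parents, each with F = 1/4 and Fa = 0
        recs = []
        for fam in ("L", "R"):
            recs += [R(f"{fam}A"), R(f"{fam}B"),
                     R(f"{fam}C", f"{fam}A", f"{fam}B"),
                     R(f"{fam}D", f"{fam}A", f"{fam}B"),
                     R(f"{fam}X", f"{fam}C", f"{fam}D")]
        recs.append(R("Z", "LX", "RX"))
        ped = Pedigree.from_records(recs)
        fa = ballou_recursive(ped)
        assert fa["Z"] == pytest.approx(0.25)
        exact = enumerate_gene_drop(ped)
        assert fa["Z"] == pytest.approx(exact["Z"]["Fa_Bal"], abs=1e-12)

    def test_matches_enumeration_on_disjoint_loops(self, full_sib_pedigree):
        exact = enumerate_gene_drop(full_sib_pedigree)
        fa = ballou_recursive(full_sib_pedigree)
        for i in full_sib_pedigree.ids:
            assert fa[i] == pytest.approx(exact[i]["Fa_Bal"], abs=1e-12)


class TestGeneDrop:
    CFG = GeneDropConfig(n_replicates=40_000, seed=99)

    def test_founders_all_zero(self, trio):
        res = gene_drop(trio, self.CFG)
        for s in (res.F, res.Fa_Bal, res.Fa_Kal, res.Fnew_Kal, res.AHC):
            assert s["A"] == 0.0 and s["B"] == 0.0

    def test_full_sib_estimates_and_identities(self, full_sib_pedigree):
        res = gene_drop(full_sib_pedigree, self.CFG)
        se = np.sqrt(0.25 * 0.75 / self.CFG.n_replicates)
        assert abs(res.F["X"] - 0.25) <= 3 * se
        assert res.Fa_Kal["X"] == 0.0
        assert res.Fnew_Kal["X"] == res.F["X"]
        fij = res.F_ij.set_index(["id", "founder"])["value"]
        assert fij["X", "A"] + fij["X", "B"] == pytest.approx(res.F["X"])
        assert abs(fij["X", "A"] - 0.125) <= 4 * se

    def test_exact_identities_on_random_pedigrees(self, rng):
        cfg = GeneDropConfig(n_replicates=5000, seed=5)
        for _ in range(5):
            ped = random_pedigree(rng)
            res = gene_drop(ped, cfg)
            assert np.allclose(res.Fa_Kal + res.Fnew_Kal, res.F, atol=1e-12)
            fij_tot = res.F_ij.groupby("id")["value"].sum().reindex(ped.ids,
                                                                    fill_value=0.0)
            assert np.allclose(fij_tot, res.F, atol=1e-12)
            assert (res.AHC >= res.Fa_Bal - 1e-15).all()
            assert (res.Fa_Bal >= res.Fa_Kal - 1e-15).all()

    def test_against_exhaustive_enumeration(self, full_sib_line):
        exact = enumerate_gene_drop(full_sib_line)
        cfg = GeneDropConfig(n_replicates=60_000, seed=31)
        res = gene_drop(full_sib_line, cfg)
        for i in full_sib_line.ids:
            for attr, key in (("F", "F"), ("Fa_Bal", "Fa_Bal"),
                              ("Fa_Kal", "Fa_Kal"), ("AHC", "AHC")):
                e = exact[i][key]
                tol = 4 * np.sqrt(max(e * (1 - e), 0.02) / cfg.n_replicates)
                assert abs(getattr(res, attr)[i] - e) <= tol, (i, attr)
        # ancestral IBD events accumulate: AHC exceeds F down the line
        assert exact["A3"]["AHC"] > exact["A3"]["F"]

    def test_monte_carlo_F_close_to_tabular(self, rng):
        cfg = GeneDropConfig(n_replicates=20_000, seed=1)
        for _ in range(4):
            ped = random_pedigree(rng)
            F = classical_F(ped)
            res = gene_drop(ped, cfg)
            for i in ped.ids:
                se = np.sqrt(max(F[i] * (1 - F[i]), 1e-4) / cfg.n_replicates)
                assert abs(res.F[i] - F[i]) <= 4 * se

    def test_seed_reproducibility(self, full_sib_pedigree):
        cfg = GeneDropConfig(n_replicates=2000, seed=77)
        a = gene_drop(full_sib_pedigree, cfg)
        b = gene_drop(full_sib_pedigree, cfg)
        assert a.F.equals(b.F) and a.AHC.equals(b.AHC)
        assert a.F_ij.equals(b.F_ij)


class TestKalinowski:
    def test_non_inbred_is_zero(self, trio):
        fa, fnew = kalinowski_decomposition(trio, GeneDropConfig(1000, seed=2))
        assert fa.eq(0).all() and fnew.eq(0).all()

    def test_stacked_loops_have_ancestral_component(self, full_sib_line):
        exact = enumerate_gene_drop(full_sib_line)
        assert exact["A2"]["Fa_Kal"] == 0.0  # parents not inbred yet... A2's parents A1,B1 have F=0
        assert exact["A3"]["Fa_Kal"] > 0.0   # grandparents inbred


class TestPartialInbreeding:
    def test_parent_offspring_concentrates_on_sire_founders(self):
        ped = Pedigree.from_records([
            R("S"), R("M"), R("D", "S", "M"), R("X", "S", "D"),
        ])
        exact = enumerate_gene_drop(ped)
        assert exact["X"]["F"] == pytest.approx(0.25)
        assert exact["X"]["F_ij"]["S"] == pytest.approx(0.25)
        assert exact["X"]["F_ij"]["M"] == 0.0
        res = ik.partial_inbreeding(ped, GeneDropConfig(n_replicates=30_000, seed=4))
        vals = res.set_index(["id", "founder"])["value"]
        assert ("X", "M") not in vals.index or vals["X", "M"] == 0.0
        assert abs(vals["X", "S"] - 0.25) < 0.01


class TestGeneOrigin:
    def test_equal_founder_contributions(self, rng):
        # N founders, one offspring each pair -> balanced reference
        recs = [R(f"F{k}") for k in range(6)]
        recs += [R(f"X{k}", f"F{2*k}", f"F{2*k+1}") for k in range(3)]
        ped = Pedigree.from_records(recs)
        ref = [f"X{k}" for k in range(3)]
        assert effective_founders(ped, ref) == pytest.approx(6.0)
        assert effective_ancestors(ped, ref) == pytest.approx(6.0)

    def test_closed_form_unbalanced(self):
        ped = Pedigree.from_records([
            R("A"), R("B"), R("C", "A", "B"), R("D", "A", "C"),
        ])
        # contributions to D: A = 0.75, B = 0.25
        q = founder_contributions(ped, ["D"])
        assert q["A"] == pytest.approx(0.75) and q["B"] == pytest.approx(0.25)
        assert effective_founders(ped, ["D"]) == pytest.approx(1.6)

    def test_reference_equals_founders(self, trio):
        assert effective_founders(trio, ["A", "B"]) == pytest.approx(2.0)

    def test_bottleneck_sire_dominates(self):
        recs = [R("P"), R("Q"), R("S", "P", "Q")] + [R(f"D{k}") for k in range(6)]
        recs += [R(f"X{k}", "S", f"D{k}") for k in range(6)]
        ped = Pedigree.from_records(recs)
        ref = [f"X{k}" for k in range(6)]
        p = ancestor_contributions(ped, ref)
        assert p.iloc[0] >= 0.5 - 1e-12
        assert p.index[0] == "S"
        assert effective_ancestors(ped, ref) < effective_founders(ped, ref)

    def test_fa_never_exceeds_fe(self, rng):
        for _ in range(25):
            ped = random_pedigree(rng)
            ref = ped.ids[-3:]
            fe = effective_founders(ped, ref)
            fa = effective_ancestors(ped, ref)
            assert fa <= fe + 1e-9
            assert fe <= len(founder_contributions(ped, ref)) + 1e-9

    def test_single_ancestor_funnel(self):
        recs = [R("A")] + [R(f"X{k}", "A", None) for k in range(5)]
        ped = Pedigree.from_records(recs)
        p = ancestor_contributions(ped, [f"X{k}" for k in range(5)])
        assert p["A"] == pytest.approx(0.5)  # the other half is unknown dams
        assert p.index[0] == "A" and p.sum() == pytest.approx(1.0)
        fa = effective_ancestors(ped, [f"X{k}" for k in range(5)])
        # A explains half, each unknown dam slot a tenth
        assert fa == pytest.approx(1 / (0.25 + 5 * 0.01))
        assert fa == pytest.approx(effective_founders(ped, [f"X{k}" for k in range(5)]))

    def test_empty_reference_rejected(self, trio):
        with pytest.raises(ValueError):
            effective_founders(trio, [])
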