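"""Pedigree parsing, kinship/dominance recursions, households, classification."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedvar.genedrop import GeneDropper
from pedvar.pedigree import (
    IndividualRecord,
    PedigreeError,
    PedigreeGraph,
    classify_pair,
    dominance_coefficient,
    household_groups,
    household_matrix,
    kinship,
    load_pedigree,
    relationship_matrices,
    write_pedigree,
)


class TestLoading:
    def test_nuclear_family_construction(self):
        csv = io.StringIO(
            "family_id,individual_id,father_id,mother_id,sex,mz_group,birth_year\n"
            "1,f,0,0,male,0,1950\n"
            "1,m,0,0,female,0,1952\n"
            "1,c1,f,m,male,0,1980\n"
            "1,c2,f,m,female,0,1982\n"
        )
        peds = load_pedigree(csv)
        ped = peds["1"]
        assert len(ped) == 4
        assert set(ped.founders) == {"f", "m"}

    def test_single_parent_gets_placeholder_founder(self, caplog):
        ped = PedigreeGraph(
            [
                IndividualRecord("f", "1", sex="male"),
                IndividualRecord("c", "1", father_id="f", mother_id=None, sex="male"),
            ]
        )
        fa, mo = ped.parents("c")
        assert fa == "f" and mo is not None and mo in ped
        assert ped.members[mo].is_founder

    def test_cycle_rejected_with_members_named(self):
        recs = [
            IndividualRecord("a", "1", "c", "b", "male"),
            IndividualRecord("b", "1", sex="female"),
            IndividualRecord("c", "1", "a", "b", "male"),
        ]
        with pytest.raises(PedigreeError, match="cycle"):
            PedigreeGraph(recs)

    def test_duplicate_id_rejected(self):
        recs = [
            IndividualRecord("a", "1", sex="male"),
            IndividualRecord("a", "1", sex="female"),
        ]
        with pytest.raises(PedigreeError, match="duplicate"):
            PedigreeGraph(recs)

    def test_mz_group_with_differing_parents_rejected(self):
        recs = [
            IndividualRecord("f", "1", sex="male"),
            IndividualRecord("m", "1", sex="female"),
            IndividualRecord("m2", "1", sex="female"),
            IndividualRecord("t1", "1", "f", "m", "male", mz_group="g"),
            IndividualRecord("t2", "1", "f", "m2", "male", mz_group="g"),
        ]
        with pytest.raises(PedigreeError, match="mz_group"):
            PedigreeGraph(recs)

    def test_csv_round_trip(self, tmp_path, nuclear_mz):
        path = tmp_path / "ped.csv"
        write_pedigree({"fam": nuclear_mz}, path)
        back = load_pedigree(path)["fam"]
        assert set(back.members) == set(nuclear_mz.members)
        assert back.members["t1"].mz_group == "g"
        assert back.members["t1"].birth_year == 1980


class TestCoefficients:
    """The nine relative classes and their printed (additive, dominance)
    sharing values, reproduced exactly by the recursions."""

    def test_mz_pair(self, nuclear_mz):
        assert 2 * kinship(nuclear_mz, "t1", "t2") == 1.0
        assert dominance_coefficient(nuclear_mz, "t1", "t2") == 1.0

    def test_full_sibs_and_dz(self, nuclear_mz):
        assert 2 * kinship(nuclear_mz, "t1", "s1") == 0.5
        assert dominance_coefficient(nuclear_mz, "t1", "s1") == 0.25

    def test_parent_offspring(self, nuclear_mz):
        assert 2 * kinship(nuclear_mz, "f", "s1") == 0.5
        assert dominance_coefficient(nuclear_mz, "f", "s1") == 0.0

    def test_spouse(self, nuclear_mz):
        assert kinship(nuclear_mz, "f", "m") == 0.0
        assert dominance_coefficient(nuclear_mz, "f", "m") == 0.0

    def test_grandparental(self, three_generation):
        assert 2 * kinship(three_generation, "gf", "c1") == 0.25
        assert dominance_coefficient(three_generation, "gf", "c1") == 0.0

    def test_avuncular(self, three_generation):
        assert 2 * kinship(three_generation, "u1", "c2") == 0.25
        assert dominance_coefficient(three_generation, "u1", "c2") == 0.0

    def test_first_cousin(self, three_generation):
        assert 2 * kinship(three_generation, "c1", "c2") == 0.125
        assert dominance_coefficient(three_generation, "c1", "c2") == 0.0

    def test_half_sibs(self, three_generation):
        assert 2 * kinship(three_generation, "c2", "c3") == 0.25
        assert dominance_coefficient(three_generation, "c2", "c3") == 0.0

    def test_double_first_cousin(self, double_first_cousins):
        assert 2 * kinship(double_first_cousins, "x", "y") == 0.25
        assert dominance_coefficient(double_first_cousins, "x", "y") == 0.0625

    def test_first_cousin_mz_parents(self, mz_parent_cousins):
        assert 2 * kinship(mz_parent_cousins, "c1", "c2") == 0.25
        assert dominance_coefficient(mz_parent_cousins, "c1", "c2") == 0.0

    def test_founder_self_kinship(self, nuclear_mz):
        assert kinship(nuclear_mz, "f", "f") == 0.5

    def test_inbreeding_warns_on_dominance(self):
        # cousin marriage: child of first cousins is inbred
        recs = [
            IndividualRecord(i, "1", sex=s)
            for i, s in [("gf", "male"), ("gm", "female"), ("w", "female"),
                         ("h", "male"), ("o", "female")]
        ]
        recs += [
            IndividualRecord("p1", "1", "gf", "gm", "male"),
            IndividualRecord("p2", "1", "gf", "gm", "female"),
            IndividualRecord("c1", "1", "p1", "w", "male"),
            IndividualRecord("c2", "1", "h", "p2", "female"),
            IndividualRecord("kid", "1", "c1", "c2", "male"),
            IndividualRecord("kid2", "1", "c1", "c2", "female"),
        ]
        ped = PedigreeGraph(recs)
        assert kinship(ped, "kid", "kid") > 0.5
        with pytest.warns(UserWarning, match="non-inbreeding"):
            dominance_coefficient(ped, "kid", "kid2")


class TestHouseholds:
    def _fam(self, twin_birth=1984):
        return PedigreeGraph(
            [
                IndividualRecord("f", "1", sex="male"),
                IndividualRecord("m", "1", sex="female"),
                IndividualRecord("t1", "1", "f", "m", "female", twin_birth),
                IndividualRecord("t2", "1", "f", "m", "female", twin_birth),
            ]
        )

    def test_minor_twins_join_parent_household(self):
        ped = self._fam()
        H = household_matrix(ped, {"t1": 16, "t2": 16}, ids=["f", "m", "t1", "t2"])
        assert (H == 1).all()

    def test_adult_twins_are_singletons(self):
        ped = self._fam()
        H = household_matrix(ped, {"t1": 30, "t2": 30}, ids=["f", "m", "t1", "t2"])
        expected = np.eye(4)
        expected[0, 1] = expected[1, 0] = 1  # spouse pair
        assert (H == expected).all()

    def test_own_spouse_group_beats_parental(self):
        recs = [
            IndividualRecord("f", "1", sex="male"),
            IndividualRecord("m", "1", sex="female"),
            IndividualRecord("t1", "1", "f", "m", "female", 1984),
            IndividualRecord("sp", "1", sex="male", spouse_of="t1"),
        ]
        ped = PedigreeGraph(recs)
        groups = {frozenset(g) for g in household_groups(ped, {"t1": 17})}
        assert frozenset({"t1", "sp"}) in groups
        assert frozenset({"f", "m"}) in groups

    def test_missing_age_treated_as_adult(self):
        ped = self._fam()
        H = household_matrix(ped, {}, ids=["f", "m", "t1", "t2"])
        assert H[0, 2] == 0 and H[2, 3] == 0


class TestRelationshipMatrices:
    def test_symmetry_and_diagonals(self, three_generation):
        mats = relationship_matrices(three_generation)
        for M in (mats.additive, mats.dominance, mats.household):
            assert (M == M.T).all()
        assert np.allclose(np.diag(mats.additive), 1.0)
        assert np.allclose(np.diag(mats.dominance), 1.0)
        assert np.allclose(np.diag(mats.household), 1.0)

    def test_additive_matrix_psd(self, double_first_cousins, three_generation):
        for ped in (double_first_cousins, three_generation):
            eig = np.linalg.eigvalsh(relationship_matrices(ped).additive)
            assert eig.min() >= -1e-8

    def test_gene_dropping_agrees_with_recursion(self, three_generation,
                                                 mz_parent_cousins):
        """Monte-Carlo IBD sharing from dropped alleles matches the recursive
        coefficients within 3 MC standard errors on every pair."""
        for ped in (three_generation, mz_parent_cousins):
            gd = GeneDropper(ped, 60_000, np.random.default_rng(12))
            ids = list(ped.order)
            for a in range(len(ids)):
                for b in range(a, len(ids)):
                    i, j = ids[a], ids[b]
                    res = gd.pair(i, j)
                    exact_add = 2 * kinship(ped, i, j)
                    exact_dom = (
                        1.0 if i == j else dominance_coefficient(ped, i, j)
                    )
                    tol_a = 3 * res.additive_se + 1e-12
                    tol_d = 3 * res.dominance_se + 1e-12
                    assert abs(res.additive - exact_add) <= tol_a, (i, j)
                    assert abs(res.dominance - exact_dom) <= tol_d, (i, j)

    def test_gene_dropping_on_large_random_pedigree(self):
        """On a 200-member random mating pedigree, empirical allele sharing
        from 200,000 drops matches 2*phi for a sample of pairs."""
        rng = np.random.default_rng(99)
        recs = [
            IndividualRecord(f"F{k}", "big", sex="male" if k % 2 else "female")
            for k in range(40)
        ]
        males = [r.individual_id for r in recs if r.sex == "male"]
        females = [r.individual_id for r in recs if r.sex == "female"]
        for k in range(160):
            iid = f"N{k}"
            fa = males[rng.integers(len(males))]
            mo = females[rng.integers(len(females))]
            sex = "male" if rng.random() < 0.5 else "female"
            recs.append(IndividualRecord(iid, "big", fa, mo, sex))
            (males if sex == "male" else females).append(iid)
        ped = PedigreeGraph(recs)
        gd = GeneDropper(ped, 200_000, rng)
        ids = list(ped.members)
        for _ in range(15):
            i, j = ids[rng.integers(len(ids))], ids[rng.integers(len(ids))]
            if i == j:
                continue
            res = gd.pair(i, j)
            exact = 2 * kinship(ped, i, j)
            assert abs(res.additive - exact) <= 3 * res.additive_se + 1e-12


class TestClassification:
    def test_priority_labels(self, nuclear_mz, three_generation):
        assert classify_pair(nuclear_mz, "t1", "t2") == "MZ"
        assert classify_pair(nuclear_mz, "t1", "s1") == "sib"
        assert classify_pair(nuclear_mz, "f", "t1") == "father-daughter"
        assert classify_pair(nuclear_mz, "m", "s1") == "mother-son"
        assert classify_pair(nuclear_mz, "f", "m") == "spouse"
        assert classify_pair(three_generation, "c2", "c3") == "half-sib"
        assert classify_pair(three_generation, "gf", "c1") == "grandparental"
        assert classify_pair(three_generation, "u1", "c2") == "avuncular"
        assert classify_pair(three_generation, "c1", "c2") == "first-cousin"

    def test_dz_twins_need_shared_birth_year(self):
        ped = PedigreeGraph(
            [
                IndividualRecord("f", "1", sex="male"),
                IndividualRecord("m", "1", sex="female"),
                IndividualRecord("a", "1", "f", "m", "male", 1980),
                IndividualRecord("b", "1", "f", "m", "female", 1980),
                IndividualRecord("c", "1", "f", "m", "female", 1985),
            ]
        )
        assert classify_pair(ped, "a", "b") == "DZ"
        assert classify_pair(ped, "a", "c") == "sib"

    def test_special_cousins(self, double_first_cousins, mz_parent_cousins):
        assert classify_pair(double_first_cousins, "x", "y") == "double-first-cousin"
        assert (
            classify_pair(mz_parent_cousins, "c1", "c2") == "first-cousin-MZ-parents"
        )

    def test_spouse_inferred_from_shared_offspring(self, three_generation):
        assert classify_pair(three_generation, "u1", "w1") == "spouse"


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_random_sib_pedigree_invariants(seed):
    """Random sibship pedigrees: matrices symmetric, additive PSD, sib
    coefficients exact."""
    rng = np.random.default_rng(seed)
    n_sibs = int(rng.integers(2, 6))
    recs = [
        IndividualRecord("f", "1", sex="male"),
        IndividualRecord("m", "1", sex="female"),
    ] + [
        IndividualRecord(f"s{k}", "1", "f", "m",
                         "male" if rng.random() < 0.5 else "female", 1980 + k)
        for k in range(n_sibs)
    ]
    ped = PedigreeGraph(recs)
    mats = relationship_matrices(ped)
    assert (mats.additive == mats.additive.T).all()
    assert np.linalg.eigvalsh(mats.additive).min() >= -1e-8
    i = mats.ids.index("s0")
    j = mats.ids.index("s1")
    assert mats.additive[i, j] == 0.5
    assert mats.dominance[i, j] == 0.25
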