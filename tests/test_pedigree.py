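"""Pedigree container, I/O, filters, depth statistics and cohorts."""

import io

import numpy as np
import pytest

import pedkin as pk
from pedkin.pedigree import _ecg_all

from conftest import make_random_pedigree


CSV = """Indiv,Sire,Dam,Sex,Breed,Born
s,,,M,THA,2000
d,,,F,THA,2000
c,s,d,M,THA,2002
"""


class TestLoading:
    def test_basic_load_topological(self):
        ped = pk.load_pedigree(io.StringIO(CSV))
        assert len(ped) == 3
        assert ped.ids[-1] == "c"
        assert ped["c"].sire == "s" and ped["c"].dam == "d"

    def test_child_before_parents_is_sorted(self):
        shuffled = "Indiv,Sire,Dam,Sex,Breed,Born\nc,s,d,M,THA,2002\ns,,,M,THA,2000\nd,,,F,THA,2000\n"
        ped = pk.load_pedigree(io.StringIO(shuffled))
        order = {pid: i for i, pid in enumerate(ped.ids)}
        assert order["s"] < order["c"] and order["d"] < order["c"]

    def test_semicolon_dialect_and_roundtrip(self, tmp_path):
        ped = pk.load_pedigree(io.StringIO(CSV.replace(",", ";")))
        out = tmp_path / "ped.csv"
        pk.write_pedigree(ped, out)
        again = pk.load_pedigree(out)
        assert again.ids == ped.ids
        assert [r.breed for r in again.records] == [r.breed for r in ped.records]

    def test_undefined_parent_materialises_as_unknown_founder(self):
        text = CSV + "k,X,d,F,THA,2004\n"
        ped = pk.load_pedigree(io.StringIO(text))
        assert len(ped) == 5  # 4 rows + auto-created X
        assert ped["X"].breed == pk.UNKNOWN
        assert ped["X"].sex == "male"  # inferred from the sire slot

    def test_duplicate_id_rejected(self):
        text = CSV + "s,,,M,THA,2000\n"
        with pytest.raises(pk.PedigreeValidationError, match="duplicate"):
            pk.load_pedigree(io.StringIO(text))

    def test_sex_conflict_rejected(self):
        text = CSV + "k,d,s,M,THA,2004\n"  # s used as dam, d as sire
        with pytest.raises(pk.PedigreeValidationError, match="sex conflict"):
            pk.load_pedigree(io.StringIO(text))

    def test_cycle_rejected(self):
        recs = [
            pk.PedigreeRecord("a", "b", None, sex="male"),
            pk.PedigreeRecord("b", "a", None, sex="male"),
        ]
        with pytest.raises(pk.PedigreeValidationError, match="cycle"):
            pk.Pedigree.from_records(recs)

    def test_self_parent_rejected(self):
        with pytest.raises(pk.PedigreeValidationError):
            pk.PedigreeRecord("a", "a", None)

    def test_row_order_never_changes_statistics(self):
        rng = np.random.default_rng(7)
        ped = make_random_pedigree(rng, 30)
        frame = ped.to_frame().sample(frac=1.0, random_state=3)
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        ped2 = pk.load_pedigree(io.StringIO(buf.getvalue()))
        pop = pk.Population(tuple(sorted(ped.ids)))
        k1 = pk.kinship_matrix(ped, pop).f
        k2 = pk.kinship_matrix(ped2, pop).f
        np.testing.assert_array_equal(k1, k2)


class TestBreedFilters:
    def test_last_native_reassigns_late_founder(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("a", sex="male", breed="THA", birth_year=2010),
            pk.PedigreeRecord("b", sex="female", breed="THA", birth_year=2000),
        ])
        out = pk.apply_last_native(ped, "THA", 2005)
        assert out["a"].breed == pk.UNKNOWN
        assert out["b"].breed == "THA"

    def test_last_native_leaves_non_founders(self, trio):
        out = pk.apply_last_native(trio, "THA", 1990)
        assert out["c"].breed == "THA"  # has both parents, untouched

    def test_last_native_idempotent(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("a", sex="male", breed="THA", birth_year=2010),
        ])
        once = pk.apply_last_native(ped, "THA", 2005)
        twice = pk.apply_last_native(once, "THA", 2005)
        assert [r.breed for r in once.records] == [r.breed for r in twice.records]

    def test_offspring_breed_corrected_when_parents_agree(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("s", sex="male", breed="OSH", birth_year=2000),
            pk.PedigreeRecord("d", sex="female", breed="OSH", birth_year=2000),
            pk.PedigreeRecord("k", "s", "d", sex="male", breed="SIA", birth_year=2002),
        ])
        out = pk.correct_offspring_breed(ped)
        assert out["k"].breed == "OSH"

    def test_offspring_breed_kept_when_parents_differ(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("s", sex="male", breed="THA", birth_year=2000),
            pk.PedigreeRecord("d", sex="female", breed="SIA", birth_year=2000),
            pk.PedigreeRecord("k", "s", "d", sex="male", breed="THA", birth_year=2002),
        ])
        out = pk.correct_offspring_breed(ped)
        assert out["k"].breed == "THA"

    def test_breed_correction_cascades(self):
        # k1 gets corrected SIA->OSH; k2 (child of k1 and another OSH) must be
        # re-evaluated against the *corrected* breed of k1
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("s", sex="male", breed="OSH", birth_year=2000),
            pk.PedigreeRecord("d", sex="female", breed="OSH", birth_year=2000),
            pk.PedigreeRecord("k1", "s", "d", sex="female", breed="SIA", birth_year=2002),
            pk.PedigreeRecord("m", sex="male", breed="OSH", birth_year=2002),
            pk.PedigreeRecord("k2", "m", "k1", sex="male", breed="SIA", birth_year=2004),
        ])
        out = pk.correct_offspring_breed(ped)
        assert out["k1"].breed == "OSH"
        assert out["k2"].breed == "OSH"
        # idempotent
        again = pk.correct_offspring_breed(out)
        assert [r.breed for r in again.records] == [r.breed for r in out.records]


class TestDepthStatistics:
    def test_ecg_founder_zero(self, trio):
        assert pk.equivalent_complete_generations(trio, "s") == 0.0

    def test_ecg_one_known_generation(self, trio):
        assert pk.equivalent_complete_generations(trio, "c") == 1.0

    def test_ecg_two_full_generations(self, fullsib_mating):
        # x: parents (2 * 1/2) + 4 grandparent slots (4 * 1/4) = 2.0
        assert pk.equivalent_complete_generations(fullsib_mating, "x") == 2.0

    def test_completeness_founders_zero(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("a", sex="male"), pk.PedigreeRecord("b", sex="female"),
        ])
        prof = pk.pedigree_completeness(ped, pk.Population(("a", "b")), 3)
        assert prof.per_generation_fraction == (0.0, 0.0, 0.0)

    def test_completeness_complete_two_generations(self, fullsib_mating):
        prof = pk.pedigree_completeness(fullsib_mating, pk.Population(("x",)), 2)
        assert prof.per_generation_fraction == (1.0, 1.0)

    def test_completeness_one_missing_grandparent_slot(self):
        # two members; one member is missing one of its four grandparents
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("g1", sex="male"), pk.PedigreeRecord("g2", sex="female"),
            pk.PedigreeRecord("g3", sex="male"),
            pk.PedigreeRecord("p1", "g1", "g2", sex="male"),
            pk.PedigreeRecord("p2", "g3", None, sex="female"),
            pk.PedigreeRecord("m1", "p1", "p2", sex="male"),
            pk.PedigreeRecord("p3", "g1", "g2", sex="male"),
            pk.PedigreeRecord("p4", "g3", "p2x", sex="female"),
            pk.PedigreeRecord("p2x", sex="female"),
            pk.PedigreeRecord("m2", "p3", "p4", sex="female"),
        ])
        prof = pk.pedigree_completeness(ped, pk.Population(("m1", "m2")), 2)
        assert prof.per_generation_fraction[0] == 1.0
        assert prof.per_generation_fraction[1] == pytest.approx(7 / 8)

    def test_ecg_equals_summed_completeness_fractions(self):
        # cross-check of the two implementations on random pedigrees
        rng = np.random.default_rng(11)
        for _ in range(5):
            ped = make_random_pedigree(rng, 35)
            ecgs = _ecg_all(ped)
            for pid in list(ped.ids)[-5:]:
                prof = pk.pedigree_completeness(ped, pk.Population((pid,)), 40)
                assert sum(prof.per_generation_fraction) == pytest.approx(
                    ecgs[ped.index_of(pid)], abs=1e-9
                )

    def test_completeness_non_increasing_for_truncated_pedigrees(self):
        # complete for 2 generations, nothing known deeper
        recs = [pk.PedigreeRecord(f"g{i}", sex="male" if i % 2 == 0 else "female")
                for i in range(4)]
        recs += [
            pk.PedigreeRecord("p1", "g0", "g1", sex="male"),
            pk.PedigreeRecord("p2", "g2", "g3", sex="female"),
            pk.PedigreeRecord("x", "p1", "p2", sex="male"),
        ]
        ped = pk.Pedigree.from_records(recs)
        prof = pk.pedigree_completeness(ped, pk.Population(("x",)), 4)
        fr = prof.per_generation_fraction
        assert fr == (1.0, 1.0, 0.0, 0.0)
        assert all(b <= a for a, b in zip(fr, fr[1:]))

    def test_avk_complete_unrelated(self, fullsib_mating):
        # x within 2 generations: 2 parents + 2 distinct grandparents = 4 of 6
        assert pk.ancestor_loss_coefficient(fullsib_mating, "x", 2) == pytest.approx(4 / 6)

    def test_avk_founder_zero(self, trio):
        assert pk.ancestor_loss_coefficient(trio, "s", 4) == 0.0

    def test_avk_no_repeats_is_one(self):
        recs = [pk.PedigreeRecord(f"g{i}", sex="male" if i % 2 == 0 else "female")
                for i in range(4)]
        recs += [
            pk.PedigreeRecord("p1", "g0", "g1", sex="male"),
            pk.PedigreeRecord("p2", "g2", "g3", sex="female"),
            pk.PedigreeRecord("x", "p1", "p2", sex="male"),
        ]
        ped = pk.Pedigree.from_records(recs)
        assert pk.ancestor_loss_coefficient(ped, "x", 2) == 1.0


class TestCohorts:
    def test_breeding_cohort_unique_parents(self):
        recs = [
            pk.PedigreeRecord("s1", sex="male", breed="THA", birth_year=2010),
            pk.PedigreeRecord("d1", sex="female", breed="THA", birth_year=2010),
            pk.PedigreeRecord("d2", sex="female", breed="THA", birth_year=2010),
            pk.PedigreeRecord("k1", "s1", "d1", sex="male", breed="THA", birth_year=2016),
            pk.PedigreeRecord("k2", "s1", "d1", sex="male", breed="THA", birth_year=2017),
            pk.PedigreeRecord("k3", "s1", "d2", sex="female", breed="THA", birth_year=2017),
        ]
        ped = pk.Pedigree.from_records(recs)
        pop = pk.breeding_cohort(ped, "THA", (2016, 2017))
        assert sorted(pop) == ["d1", "d2", "s1"]

    def test_breeding_cohort_includes_outcross_parent(self):
        recs = [
            pk.PedigreeRecord("s1", sex="male", breed="SIA", birth_year=2010),
            pk.PedigreeRecord("d1", sex="female", breed="THA", birth_year=2010),
            pk.PedigreeRecord("k1", "s1", "d1", sex="male", breed="THA", birth_year=2016),
        ]
        ped = pk.Pedigree.from_records(recs)
        pop = pk.breeding_cohort(ped, "THA", (2016, 2017))
        assert "s1" in pop.member_ids

    def test_breeding_cohort_empty_window_raises(self, trio):
        with pytest.raises(pk.EmptyPopulationError):
            pk.breeding_cohort(trio, "THA", (1990, 1991))

    def test_ecg_filter_strictly_less_than(self, fullsib_mating):
        pop = pk.Population(("x", "b"))
        out = pk.filter_min_ecg(fullsib_mating, pop, min_ecg=2.0)
        # x has ecg exactly 2.0 -> retained; b has ecg 1.0 -> removed
        assert tuple(out) == ("x",)

    def test_ecg_filter_zero_threshold_is_identity(self, fullsib_mating):
        pop = pk.Population(("x", "b"))
        assert tuple(pk.filter_min_ecg(fullsib_mating, pop, 0.0)) == tuple(pop)

    def test_ecg_filter_all_removed_raises(self, trio):
        with pytest.raises(pk.EmptyPopulationError):
            pk.filter_min_ecg(trio, pk.Population(("s", "d")), 3.0)

    def test_unknown_parentage_all_founders(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("a", sex="male"), pk.PedigreeRecord("b", sex="female"),
        ])
        assert pk.unknown_parentage_fraction(ped) == 1.0

    def test_unknown_parentage_trio(self, trio):
        assert pk.unknown_parentage_fraction(trio) == pytest.approx(4 / 6)

    def test_demographic_counts(self):
        recs = [
            pk.PedigreeRecord("s1", sex="male", breed="THA", birth_year=2010),
            pk.PedigreeRecord("d1", sex="female", breed="THA", birth_year=2010),
            pk.PedigreeRecord("d2", sex="female", breed="THA", birth_year=2010),
            pk.PedigreeRecord("k1", "s1", "d1", sex="male", breed="THA", birth_year=2016),
            pk.PedigreeRecord("k2", "s1", "d2", sex="male", breed="THA", birth_year=2016),
        ]
        ped = pk.Pedigree.from_records(recs)
        df = pk.demographic_counts(ped, "THA", (2015, 2016))
        assert df.loc[2015, "kittens"] == 0
        assert df.loc[2015, "breeding_individuals"] == 0
        assert df.loc[2016, "kittens"] == 2
        assert df.loc[2016, "breeding_individuals"] == 3  # shared sire counted once
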