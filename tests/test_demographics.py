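"""Birth-year imputation, affiliation rules, and cohort statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pedcraft as pc
from pedcraft import demographics as demo
from pedcraft.demographics import (
    DEFAULT_AFFILIATION_RULES,
    AffiliationRule,
    cohort_table,
    couple_kinship_stats,
    estimate_birth_years,
    generation_gap,
    load_rules,
    predict_affiliation,
)
from pedcraft.kinship import KinshipContext

from .conftest import random_pedigree
from .test_kinship import first_cousin_pedigree


class TestGenerationGap:
    def test_two_pairs_mean_and_median(self):
        persons = [
            pc.Person(1, birth_year=1700),
            pc.Person(2, birth_year=1720),
            pc.Person(3, birth_year=1710),
            pc.Person(4, birth_year=1740),
        ]
        links = [pc.ParentLink(1, 2), pc.ParentLink(3, 4)]
        ped = pc.build_pedigree(persons, links)
        mean, median, n = generation_gap(ped)
        assert (mean, median, n) == (25, 25, 2)

    def test_oldest_child_is_minimum_year(self):
        persons = [
            pc.Person(1, birth_year=1760),
            pc.Person(2, birth_year=1790),
            pc.Person(3, birth_year=1785),
        ]
        links = [pc.ParentLink(1, 2), pc.ParentLink(1, 3)]
        ped = pc.build_pedigree(persons, links)
        mean, _, n = generation_gap(ped)
        assert (mean, n) == (25, 1)

    def test_no_qualifying_pairs_signals_empty(self):
        ped = pc.build_pedigree([pc.Person(1), pc.Person(2)], [pc.ParentLink(1, 2)])
        assert generation_gap(ped) == (None, None, 0)

    def test_founders_only_vs_all_pairs(self, fig1_pedigree):
        persons = {
            1: 1700, 2: 1702, 3: 1725, 4: 1726, 5: 1755,
        }
        ped = pc.build_pedigree(
            [pc.Person(pid, birth_year=y) for pid, y in persons.items()],
            fig1_pedigree.links,
        )
        _, _, n_founders = generation_gap(ped, founders_only=True)
        _, _, n_all = generation_gap(ped, founders_only=False)
        assert n_founders == 3  # founders 1, 2, 4
        assert n_all == 4  # plus non-founder parent 3

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        ped = random_pedigree(seed, missing_birth_year_rate=0.2)
        gaps = []
        for f in ped.founder_pids():
            fy = ped.persons[f].birth_year
            if fy is None:
                continue
            ys = [
                ped.persons[c].birth_year
                for c in ped.children_of(f)
                if ped.persons[c].birth_year is not None
            ]
            if ys:
                gaps.append(min(ys) - fy)
        mean, median, n = generation_gap(ped)
        assert n == len(gaps)
        if gaps:
            assert mean == pytest.approx(sum(gaps) / len(gaps))
            assert median == pytest.approx(float(np.median(gaps)))


class TestEstimateBirthYears:
    def test_stehly_chain_estimates_1695(self, stehly_pedigree):
        updated = estimate_birth_years(stehly_pedigree, G=25)
        by_name = {p.name: p for p in updated.values()}
        assert by_name["Stehly founder"].birth_year == 1695
        assert by_name["Henry Stehly"].birth_year == 1720
        assert by_name["Magdalena Stehly"].birth_year == 1745
        assert all(
            by_name[n].birth_year_estimated
            for n in ("Stehly founder", "Henry Stehly", "Magdalena Stehly")
        )

    def test_known_years_never_overwritten(self, stehly_pedigree):
        updated = estimate_birth_years(stehly_pedigree)
        catherine = next(p for p in updated.values() if p.name == "Catherine Sieber")
        assert catherine.birth_year == 1770
        assert not catherine.birth_year_estimated

    def test_min_includes_estimated_children(self):
        # parent's children: known 1800 and estimated 1790 (via grandchild 1815)
        persons = [
            pc.Person(1),
            pc.Person(2, birth_year=1800),
            pc.Person(3),
            pc.Person(4, birth_year=1815),
        ]
        links = [pc.ParentLink(1, 2), pc.ParentLink(1, 3), pc.ParentLink(3, 4)]
        ped = pc.build_pedigree(persons, links)
        updated = estimate_birth_years(ped, G=25)
        assert updated[3].birth_year == 1790
        assert updated[1].birth_year == 1765

    def test_person_without_estimable_child_stays_unknown(self, stehly_pedigree):
        updated = estimate_birth_years(stehly_pedigree)
        sib = next(p for p in updated.values() if p.name == "Stehly sibling A")
        assert sib.birth_year is None

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_interval_and_orders_parents_before_children(self, seed):
        ped = random_pedigree(seed, missing_birth_year_rate=0.4)
        small = estimate_birth_years(ped, G=20)
        large = estimate_birth_years(ped, G=30)
        for pid in ped.persons:
            a, b = small[pid], large[pid]
            if a.birth_year_estimated:
                assert b.birth_year <= a.birth_year
        for lk in ped.links:
            p, c = large[lk.parent_pid], large[lk.child_pid]
            if p.birth_year_estimated and c.birth_year is not None:
                assert p.birth_year <= c.birth_year - 30


def _family_for_affiliation():
    """Person 10 with parents 1,2; spouse 11 with parents 3,4; child 12."""
    persons = {
        1: pc.Person(1, pc.Sex.MALE),
        2: pc.Person(2, pc.Sex.FEMALE),
        3: pc.Person(3, pc.Sex.MALE),
        4: pc.Person(4, pc.Sex.FEMALE),
        10: pc.Person(10, pc.Sex.MALE, birth_year=1960),
        11: pc.Person(11, pc.Sex.FEMALE, birth_year=1962),
        12: pc.Person(12, pc.Sex.MALE, birth_year=1990),
    }
    links = [
        pc.ParentLink(1, 10),
        pc.ParentLink(2, 10),
        pc.ParentLink(3, 11),
        pc.ParentLink(4, 11),
        pc.ParentLink(10, 12),
        pc.ParentLink(11, 12),
    ]
    return persons, pc.build_pedigree(persons.values(), links)


class TestPredictAffiliation:
    def flag(self, persons, pid):
        import dataclasses

        out = dict(persons)
        out[pid] = dataclasses.replace(out[pid], affiliation=pc.Affiliation.FLAGGED)
        return out

    def test_spouse_flag_propagates_in_earliest_cohort(self):
        persons, ped = _family_for_affiliation()
        persons = self.flag(persons, 11)
        assert predict_affiliation(persons, ped, DEFAULT_AFFILIATION_RULES, 10)

    def test_spouses_parents_only_counts_in_middle_cohort(self):
        import dataclasses

        persons, ped = _family_for_affiliation()
        persons[10] = dataclasses.replace(persons[10], birth_year=1980)
        persons = self.flag(persons, 3)  # spouse's father
        assert predict_affiliation(persons, ped, DEFAULT_AFFILIATION_RULES, 10)
        # the earliest-cohort relative set does not reach spouses' parents
        persons[10] = dataclasses.replace(persons[10], birth_year=1960)
        assert not predict_affiliation(persons, ped, DEFAULT_AFFILIATION_RULES, 10)

    def test_grandparents_count_only_in_latest_cohort(self):
        persons, ped = _family_for_affiliation()
        persons = self.flag(persons, 1)  # child 12's grandfather
        assert predict_affiliation(persons, ped, DEFAULT_AFFILIATION_RULES, 12)

    def test_no_flags_predicts_false(self):
        persons, ped = _family_for_affiliation()
        assert not predict_affiliation(persons, ped, DEFAULT_AFFILIATION_RULES, 10)

    def test_monotone_in_flag_set(self):
        persons, ped = _family_for_affiliation()
        flagged = persons
        for pid in (11, 2, 1):
            flagged = self.flag(flagged, pid)
            for target in (10, 12):
                before = predict_affiliation(
                    persons, ped, DEFAULT_AFFILIATION_RULES, target
                )
                after = predict_affiliation(
                    flagged, ped, DEFAULT_AFFILIATION_RULES, target
                )
                assert after >= before

    def test_uncovered_year_raises_configuration_error(self):
        persons, ped = _family_for_affiliation()
        rules = (AffiliationRule((1900, 1950), frozenset({"self"})),)
        with pytest.raises(pc.ConfigurationError):
            predict_affiliation(persons, ped, rules, 10)

    def test_rules_yaml_round_trip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(
            "- {range: [null, 1971], relatives: [self, parents, spouses]}\n"
            "- {range: [1972, 1986], relatives: [self, parents, spouses, spouses_parents]}\n"
            "- {range: [1987, null], relatives: [self, parents, grandparents, spouses]}\n"
        )
        assert load_rules(path) == DEFAULT_AFFILIATION_RULES

    def test_unknown_relative_set_rejected(self):
        with pytest.raises(pc.ConfigurationError):
            AffiliationRule((None, None), frozenset({"cousins"}))


class TestCoupleKinship:
    def test_founder_marriages_only(self):
        persons = [
            pc.Person(1, birth_year=1700),
            pc.Person(2, birth_year=1701),
            pc.Person(3),
        ]
        links = [pc.ParentLink(1, 3), pc.ParentLink(2, 3)]
        ctx = KinshipContext(pc.build_pedigree(persons, links))
        rows, frac = couple_kinship_stats(ctx, [(1650, 1750)])
        assert frac == 0.0
        assert rows[0].n_couples == 1
        assert rows[0].mean == 0.0

    def test_first_cousin_couple_among_four(self):
        ped = first_cousin_pedigree()
        # add three unrelated founder couples with a child each
        persons = list(ped.persons.values())
        links = list(ped.links)
        pid = 10
        for _ in range(3):
            a, b, c = pid, pid + 1, pid + 2
            persons += [pc.Person(a), pc.Person(b), pc.Person(c)]
            links += [pc.ParentLink(a, c), pc.ParentLink(b, c)]
            pid += 3
        big = pc.renumber(pc.build_pedigree(persons, links)).pedigree
        ctx = KinshipContext(big)
        # couples: (1,2), (3,5), (4,6), (7,8) + three founder couples = 7
        _, frac = couple_kinship_stats(ctx, [])
        consang = [c for c in big.couples() if ctx.kinship(*c) > 0]
        assert len(consang) == 1
        assert ctx.kinship(*consang[0]) == 0.0625
        assert frac == pytest.approx(1 / 7)

    def test_empty_bin_row(self):
        persons = [pc.Person(1, birth_year=1900), pc.Person(2, birth_year=1901), pc.Person(3)]
        links = [pc.ParentLink(1, 3), pc.ParentLink(2, 3)]
        ctx = KinshipContext(pc.build_pedigree(persons, links))
        rows, _ = couple_kinship_stats(ctx, [(1700, 1800)])
        assert rows[0].n_couples == 0
        assert rows[0].mean is None

    def test_quartiles_match_numpy_percentiles(self):
        ped = random_pedigree(3, n_generations=5, founding_couples=4)
        ctx = KinshipContext(ped)
        rows, _ = couple_kinship_stats(ctx, [(1600, 2100)])
        vals = [
            ctx.kinship(*c)
            for c in ped.couples()
            if any(ped.persons[p].birth_year is not None for p in c)
        ]
        assert rows[0].n_couples == len(vals)
        assert rows[0].q25 == pytest.approx(np.percentile(vals, 25))
        assert rows[0].median == pytest.approx(np.percentile(vals, 50))
        assert rows[0].q75 == pytest.approx(np.percentile(vals, 75))
        assert rows[0].q25 <= rows[0].median <= rows[0].q75

    def test_overlapping_bins_rejected(self):
        ped = random_pedigree(1)
        ctx = KinshipContext(ped)
        with pytest.raises(pc.ConfigurationError):
            couple_kinship_stats(ctx, [(1700, 1800), (1750, 1850)])


class TestCohortTable:
    def test_counts_by_bin_and_sex(self):
        persons = [
            pc.Person(1, pc.Sex.FEMALE, birth_year=1935),
            pc.Person(2, pc.Sex.FEMALE, birth_year=1935),
            pc.Person(3, pc.Sex.MALE, birth_year=1990),
        ]
        bins = [(1930, 1940), (1981, 1990)]
        df = cohort_table(persons, bins)
        assert df.loc["1930-1940", "female"] == 2
        assert df.loc["1981-1990", "male"] == 1
        assert df.loc["total", "sum"] == 3

    def test_empty_person_list_all_zero(self):
        df = cohort_table([], [(1900, 1950)])
        assert (df.values == 0).all()

    def test_totals_equal_cell_sums(self):
        ped = random_pedigree(11, missing_birth_year_rate=0.3)
        bins = [(1690, 1740), (1741, 1790), (1791, 1840)]
        df = cohort_table(ped.persons, bins)
        body = df.iloc[:-1][["female", "male", "unknown"]]
        assert df.loc["total", "sum"] == body.values.sum()
        assert (df["sum"].iloc[:-1] == body.sum(axis=1)).all()
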