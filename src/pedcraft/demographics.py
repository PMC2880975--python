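"""Birth-year imputation, affiliation prediction, and cohort statistics.

Birth-year imputation uses a calibrated parent-child generation interval:
a person lacking a birth year but having at least one child with a known or
estimated year receives (oldest such child's year - G). The interval G is
calibrated from founder/oldest-child pairs with known years; 25 years is
the default. Affiliation (e.g. church-membership) prediction follows
birth-cohort rules: depending on the cohort, the flag is looked up on the
individual, their parents, grandparents, spouses, or spouses' parents —
whichever relative carries it makes the prediction positive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from statistics import median as _median
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ArgumentError, ConfigurationError, UnknownPidError
from .kinship import KinshipContext
from .model import Affiliation, Pedigree, Person, Sex

RELATIVE_SETS = {"self", "parents", "grandparents", "spouses", "spouses_parents"}


# -- generation interval ---------------------------------------------------


def generation_gap(
    ped: Pedigree, founders_only: bool = True
) -> tuple[Optional[float], Optional[float], int]:
    """Mean/median birth-year gap between parents and their oldest child.

    For each qualifying parent (founders only by default) with a known birth
    year, the oldest child is the minimum *known* birth year among the
    children; the gap is (child year - parent year). Returns
    (mean, median, n_pairs); (None, None, 0) when no pair qualifies.
    """
    gaps: list[int] = []
    for pid, person in sorted(ped.persons.items()):
        if founders_only and not ped.is_founder(pid):
            continue
        if person.birth_year is None:
            continue
        child_years = [
            ped.persons[c].birth_year
            for c in ped.children_of(pid)
            if ped.persons[c].birth_year is not None
        ]
        if not child_years:
            continue
        gaps.append(min(child_years) - person.birth_year)
    if not gaps:
        return None, None, 0
    return sum(gaps) / len(gaps), float(_median(gaps)), len(gaps)


def estimate_birth_years(ped: Pedigree, G: int = 25) -> dict[int, Person]:
    """Impute missing birth years bottom-up with a G-year generation interval.

    Children are resolved before parents (reverse ancestor-first order); a
    person lacking a year whose children include at least one known or
    already-estimated year receives (min over those years) - G and the
    ``birth_year_estimated`` flag. Known years are never overwritten.
    Returns a new pid -> Person mapping; the input pedigree is untouched.
    """
    updated = {pid: p for pid, p in ped.persons.items()}
    for pid in reversed(ped.topological_pids()):
        person = updated[pid]
        if person.birth_year is not None:
            continue
        child_years = [
            updated[c].birth_year
            for c in ped.children_of(pid)
            if updated[c].birth_year is not None
        ]
        if child_years:
            updated[pid] = dataclasses.replace(
                person, birth_year=min(child_years) - G, birth_year_estimated=True
            )
    return updated


# -- affiliation rules -----------------------------------------------------


@dataclass(frozen=True)
class AffiliationRule:
    """One birth-cohort rule: which relatives' records to inspect.

    ``birth_year_range`` is a closed interval; ``None`` bounds are open-ended.
    ``relative_sets`` is drawn from {self, parents, grandparents, spouses,
    spouses_parents}.
    """

    birth_year_range: tuple[Optional[int], Optional[int]]
    relative_sets: frozenset[str]

    def __post_init__(self) -> None:
        unknown = set(self.relative_sets) - RELATIVE_SETS
        if unknown:
            raise ConfigurationError(f"unknown relative sets {sorted(unknown)}")
        lo, hi = self.birth_year_range
        if lo is not None and hi is not None and lo > hi:
            raise ConfigurationError(f"inverted rule range ({lo}, {hi})")

    def covers(self, year: int) -> bool:
        lo, hi = self.birth_year_range
        return (lo is None or year >= lo) and (hi is None or year <= hi)


#: Default cohort rules: individuals born through 1971 are checked against
#: self, parents and spouses; 1972-1986 adds spouses' parents; 1987 onward
#: swaps spouses' parents for grandparents (recent records carry the flag on
#: the older generations).
DEFAULT_AFFILIATION_RULES: tuple[AffiliationRule, ...] = (
    AffiliationRule((None, 1971), frozenset({"self", "parents", "spouses"})),
    AffiliationRule(
        (1972, 1986), frozenset({"self", "parents", "spouses", "spouses_parents"})
    ),
    AffiliationRule(
        (1987, None), frozenset({"self", "parents", "grandparents", "spouses"})
    ),
)


def load_rules(path_or_buf) -> tuple[AffiliationRule, ...]:
    """Load affiliation rules from YAML: a list of {range: [lo, hi], relatives: [...]}."""
    if hasattr(path_or_buf, "read"):
        raw = yaml.safe_load(path_or_buf)
    else:
        with open(path_or_buf) as fh:
            raw = yaml.safe_load(fh)
    rules = []
    for entry in raw:
        lo, hi = entry["range"]
        rules.append(AffiliationRule((lo, hi), frozenset(entry["relatives"])))
    return tuple(rules)


def _rule_for_year(
    rules: Sequence[AffiliationRule], year: Optional[int]
) -> AffiliationRule:
    if year is None:
        # unknown birth year: fall back to the earliest-cohort rule
        open_low = [r for r in rules if r.birth_year_range[0] is None]
        if open_low:
            return open_low[0]
        return min(rules, key=lambda r: r.birth_year_range[0])
    for rule in rules:
        if rule.covers(year):
            return rule
    raise ConfigurationError(f"no affiliation rule covers birth year {year}")


def predict_affiliation(
    persons: Mapping[int, Person],
    ped: Pedigree,
    rules: Sequence[AffiliationRule],
    pid: int,
) -> bool:
    """True iff any relative selected by the cohort rule carries the flag."""
    if pid not in persons:
        raise UnknownPidError(pid)
    rule = _rule_for_year(rules, persons[pid].birth_year)

    relatives: set[int] = set()
    if "self" in rule.relative_sets:
        relatives.add(pid)
    if "parents" in rule.relative_sets:
        relatives.update(ped.parents_of(pid))
    if "grandparents" in rule.relative_sets:
        for p in ped.parents_of(pid):
            relatives.update(ped.parents_of(p))
    spouses = ped.mates_of(pid)
    if "spouses" in rule.relative_sets:
        relatives.update(spouses)
    if "spouses_parents" in rule.relative_sets:
        for s in spouses:
            relatives.update(ped.parents_of(s))

    return any(
        persons[r].affiliation is Affiliation.FLAGGED
        for r in relatives
        if r in persons
    )


# -- couple kinship / cohort tables ---------------------------------------


@dataclass
class CoupleKinshipRow:
    cohort: tuple[int, int]
    n_couples: int
    mean: Optional[float]
    q25: Optional[float]
    median: Optional[float]
    q75: Optional[float]


def _check_bins(bins: Sequence[tuple[int, int]]) -> None:
    for lo, hi in bins:
        if lo > hi:
            raise ConfigurationError(f"inverted bin ({lo}, {hi})")
    for i, (lo, hi) in enumerate(bins):
        for lo2, hi2 in bins[i + 1 :]:
            if lo <= hi2 and lo2 <= hi:
                raise ConfigurationError(
                    f"overlapping bins ({lo}, {hi}) and ({lo2}, {hi2})"
                )


def couple_kinship_stats(
    ctx: KinshipContext,
    cohort_bins: Sequence[tuple[int, int]],
    persons: Optional[Mapping[int, Person]] = None,
    index_spouse: str = "earlier",
) -> tuple[list[CoupleKinshipRow], float]:
    """Kinship statistics of couples (pairs with >=1 common child) by cohort.

    A couple's cohort is indexed by the earlier-born spouse's known or
    estimated birth year by default (``index_spouse`` in {"earlier",
    "later"}); couples with no usable year fall outside every bin but still
    count toward the overall consanguineous fraction — the fraction of
    couples with kinship > 0. Quartiles use linear interpolation.
    """
    _check_bins(cohort_bins)
    if index_spouse not in ("earlier", "later"):
        raise ArgumentError(f"index_spouse must be 'earlier' or 'later', got {index_spouse!r}")
    persons = persons if persons is not None else ctx.pedigree.persons

    couples = sorted(ctx.pedigree.couples())
    phi = {c: float(ctx.kinship(*c)) for c in couples}
    pick = min if index_spouse == "earlier" else max

    def couple_year(a: int, b: int) -> Optional[int]:
        years = [
            persons[p].birth_year
            for p in (a, b)
            if p in persons and persons[p].birth_year is not None
        ]
        return pick(years) if years else None

    rows = []
    for lo, hi in cohort_bins:
        vals = [
            phi[c]
            for c in couples
            if (y := couple_year(*c)) is not None and lo <= y <= hi
        ]
        if vals:
            arr = np.asarray(vals)
            rows.append(
                CoupleKinshipRow(
                    (lo, hi),
                    len(vals),
                    float(arr.mean()),
                    float(np.percentile(arr, 25)),
                    float(np.percentile(arr, 50)),
                    float(np.percentile(arr, 75)),
                )
            )
        else:
            rows.append(CoupleKinshipRow((lo, hi), 0, None, None, None, None))

    consang = (
        sum(1 for v in phi.values() if v > 0) / len(couples) if couples else 0.0
    )
    return rows, consang


def cohort_table(
    persons: Mapping[int, Person] | Iterable[Person],
    bins: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Birth-year-bin x sex count table with row and column sums.

    Persons with unknown birth year or outside every bin are not counted.
    """
    _check_bins(bins)
    if isinstance(persons, Mapping):
        persons = persons.values()
    index = [f"{lo}-{hi}" for lo, hi in sorted(bins)]
    cols = ["female", "male", "unknown", "sum"]
    df = pd.DataFrame(0, index=index + ["total"], columns=cols)
    for p in persons:
        if p.birth_year is None:
            continue
        for lo, hi in bins:
            if lo <= p.birth_year <= hi:
                sexcol = {
                    Sex.FEMALE: "female",
                    Sex.MALE: "male",
                    Sex.UNKNOWN: "unknown",
                }[p.sex]
                df.loc[f"{lo}-{hi}", sexcol] += 1
                break
    df["sum"] = df[["female", "male", "unknown"]].sum(axis=1)
    df.loc["total"] = df.iloc[:-1].sum(axis=0)
    return df
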