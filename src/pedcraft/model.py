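"""Domain types and pedigree construction.

A pedigree is a validated DAG of parent->child links over person records.
Persons carry integer program ids (pids); 0 is reserved as the LINKAGE
missing-parent sentinel and is never a valid pid.
"""

from __future__ import annotations

import dataclasses
import heapq
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

from .errors import CycleError, DataError, UnknownPidError


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @property
    def linkage_code(self) -> int:
        return {Sex.MALE: 1, Sex.FEMALE: 2, Sex.UNKNOWN: 0}[self]

    @classmethod
    def from_linkage_code(cls, code: int) -> "Sex":
        try:
            return {1: cls.MALE, 2: cls.FEMALE, 0: cls.UNKNOWN}[code]
        except KeyError:
            raise DataError(f"invalid LINKAGE sex code {code}") from None

    @property
    def opposite(self) -> "Sex":
        if self is Sex.MALE:
            return Sex.FEMALE
        if self is Sex.FEMALE:
            return Sex.MALE
        return Sex.UNKNOWN


class Affiliation(str, Enum):
    FLAGGED = "flagged"
    UNFLAGGED = "unflagged"
    UNKNOWN = "unknown"


@dataclass
class Person:
    """One genealogy record.

    ``birth_year_estimated`` marks a year filled in by the generation-interval
    imputation rather than recorded in the source.
    """

    pid: int
    sex: Sex = Sex.UNKNOWN
    birth_year: Optional[int] = None
    death_year: Optional[int] = None
    birth_year_estimated: bool = False
    affiliation: Affiliation = Affiliation.UNKNOWN
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.pid, int) or self.pid <= 0:
            raise DataError(f"pid must be a positive integer, got {self.pid!r}")
        if isinstance(self.sex, str) and not isinstance(self.sex, Sex):
            self.sex = Sex(self.sex)
        if isinstance(self.affiliation, str) and not isinstance(self.affiliation, Affiliation):
            self.affiliation = Affiliation(self.affiliation)
        if (
            self.birth_year is not None
            and self.death_year is not None
            and self.death_year < self.birth_year
        ):
            raise DataError(
                f"person {self.pid}: death year {self.death_year} precedes "
                f"birth year {self.birth_year}"
            )
        if self.birth_year_estimated and self.birth_year is None:
            raise DataError(f"person {self.pid}: estimated flag set without a birth year")


@dataclass(frozen=True)
class ParentLink:
    """Directed parent->child edge; adoptive links carry biological=False."""

    parent_pid: int
    child_pid: int
    biological: bool = True

    def __post_init__(self) -> None:
        if self.parent_pid == self.child_pid:
            raise DataError(f"person {self.parent_pid} linked as its own parent")


class Pedigree:
    """A validated pedigree: persons plus biological parent->child links.

    Derived indexes (parents-of, children-of, mates-of) are built once at
    construction. Mates are pairs sharing at least one common child. Use
    :func:`build_pedigree` rather than the constructor to get full validation
    of adoptive-link exclusion.
    """

    def __init__(
        self,
        persons: Iterable[Person],
        links: Iterable[ParentLink],
        meta: Optional[dict] = None,
    ):
        self.persons: dict[int, Person] = {}
        for p in persons:
            if p.pid in self.persons:
                raise DataError(f"duplicate pid {p.pid}")
            self.persons[p.pid] = p

        self.links: tuple[ParentLink, ...] = tuple(links)
        self.meta: dict = dict(meta or {})

        self._parents: dict[int, tuple[int, ...]] = {pid: () for pid in self.persons}
        self._children: dict[int, set[int]] = {pid: set() for pid in self.persons}
        seen_pairs: set[tuple[int, int]] = set()
        for lk in self.links:
            for pid in (lk.parent_pid, lk.child_pid):
                if pid not in self.persons:
                    raise UnknownPidError(pid)
            pair = (lk.parent_pid, lk.child_pid)
            if pair in seen_pairs:
                raise DataError(f"duplicate link {lk.parent_pid}->{lk.child_pid}")
            seen_pairs.add(pair)
            self._parents[lk.child_pid] = tuple(
                sorted(self._parents[lk.child_pid] + (lk.parent_pid,))
            )
            self._children[lk.parent_pid].add(lk.child_pid)

        for pid, par in self._parents.items():
            if len(par) > 2:
                raise DataError(f"person {pid} has {len(par)} recorded parents")

        self._check_acyclic()

        # mates: pairs of persons sharing >=1 common child
        self._mates: dict[int, set[int]] = {pid: set() for pid in self.persons}
        for pid, par in self._parents.items():
            if len(par) == 2:
                a, b = par
                self._mates[a].add(b)
                self._mates[b].add(a)

    # -- indexes -----------------------------------------------------------

    def parents_of(self, pid: int) -> tuple[int, ...]:
        try:
            return self._parents[pid]
        except KeyError:
            raise UnknownPidError(pid) from None

    def children_of(self, pid: int) -> frozenset[int]:
        try:
            return frozenset(self._children[pid])
        except KeyError:
            raise UnknownPidError(pid) from None

    def mates_of(self, pid: int) -> frozenset[int]:
        try:
            return frozenset(self._mates[pid])
        except KeyError:
            raise UnknownPidError(pid) from None

    def couples(self) -> set[tuple[int, int]]:
        """All mate pairs as sorted (pid, pid) tuples."""
        out: set[tuple[int, int]] = set()
        for pid, mates in self._mates.items():
            for m in mates:
                out.add((min(pid, m), max(pid, m)))
        return out

    def __contains__(self, pid: int) -> bool:
        return pid in self.persons

    def __len__(self) -> int:
        return len(self.persons)

    def graph(self) -> nx.DiGraph:
        """The parent->child digraph (fresh copy)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.persons)
        g.add_edges_from((lk.parent_pid, lk.child_pid) for lk in self.links)
        return g

    def is_founder(self, pid: int) -> bool:
        return not self.parents_of(pid)

    def founder_pids(self) -> frozenset[int]:
        return frozenset(pid for pid in self.persons if not self._parents[pid])

    def is_renumbered(self) -> bool:
        """True when every parent pid is smaller than its child's pid."""
        return all(lk.parent_pid < lk.child_pid for lk in self.links)

    def topological_pids(self) -> list[int]:
        """Ancestor-first order, ties broken by ascending pid."""
        return _kahn_order(self._parents, self._children, key=lambda pid: pid)

    def subset_on(self, pids: Iterable[int]) -> "Pedigree":
        """Induced sub-pedigree on ``pids`` (links with both endpoints kept)."""
        keep = set(pids)
        for pid in keep:
            if pid not in self.persons:
                raise UnknownPidError(pid)
        persons = [self.persons[p] for p in sorted(keep)]
        links = [
            lk for lk in self.links if lk.parent_pid in keep and lk.child_pid in keep
        ]
        return Pedigree(persons, links)

    # -- internals ---------------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.persons)
        g.add_edges_from((lk.parent_pid, lk.child_pid) for lk in self.links)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(cycle[0][0])


def _kahn_order(parents, children, key) -> list[int]:
    indeg = {pid: len(par) for pid, par in parents.items()}
    ready = [(key(pid), pid) for pid, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        _, pid = heapq.heappop(ready)
        order.append(pid)
        for c in children[pid]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (key(c), c))
    if len(order) != len(parents):
        stuck = next(pid for pid, d in indeg.items() if d > 0)
        raise CycleError(stuck)
    return order


def build_pedigree(
    persons: Iterable[Person],
    links: Iterable[ParentLink],
    exclude_adoptive: bool = True,
) -> Pedigree:
    """Construct and validate a pedigree from the two-table representation.

    Adoptive (non-biological) links are dropped from the analysis pedigree by
    default; they remain in the caller's tables. All structural invariants
    (acyclicity, <=2 parents, distinct parents, known pids) are enforced.
    """
    links = list(links)
    if exclude_adoptive:
        links = [lk for lk in links if lk.biological]
    return Pedigree(persons, links)


@dataclass
class RenumberResult:
    """Outcome of ancestor-first renumbering.

    ``old_to_new`` maps each original pid to its new pid (a bijection on the
    original persons); ``added_placeholders`` holds the new pids of spouse
    placeholders created so every person has zero or two parents.
    """

    pedigree: Pedigree
    old_to_new: dict[int, int]
    added_placeholders: frozenset[int]

    @property
    def new_to_old(self) -> dict[int, int]:
        return {v: k for k, v in self.old_to_new.items()}


def renumber(ped: Pedigree) -> RenumberResult:
    """Renumber a pedigree so parents always have smaller ids than children.

    Every person with exactly one recorded parent gains a placeholder second
    parent (one per such child), mated to the known parent, with sex opposite
    to the known parent's when that is known. New ids are assigned by a stable
    Kahn topological sort with ties broken by ascending original pid;
    placeholders sort after all original persons among simultaneously ready
    nodes.
    """
    persons = dict(ped.persons)
    parents = {pid: list(ped.parents_of(pid)) for pid in persons}
    links = [(lk.parent_pid, lk.child_pid) for lk in ped.links]

    next_tmp = max(persons, default=0) + 1
    placeholder_tmp: set[int] = set()
    for child in sorted(persons):
        par = ped.parents_of(child)
        if len(par) == 1:
            known = persons[par[0]]
            ph = Person(pid=next_tmp, sex=known.sex.opposite)
            persons[ph.pid] = ph
            placeholder_tmp.add(ph.pid)
            parents[child].append(ph.pid)
            parents[ph.pid] = []
            links.append((ph.pid, child))
            next_tmp += 1

    children: dict[int, set[int]] = {pid: set() for pid in persons}
    for p, c in links:
        children[p].add(c)
    parent_map = {pid: tuple(v) for pid, v in parents.items()}

    order = _kahn_order(
        parent_map, children, key=lambda pid: (pid in placeholder_tmp, pid)
    )
    tmp_to_new = {pid: i + 1 for i, pid in enumerate(order)}

    new_persons = [
        dataclasses.replace(persons[pid], pid=tmp_to_new[pid]) for pid in order
    ]
    new_links = [ParentLink(tmp_to_new[p], tmp_to_new[c]) for p, c in links]
    new_ped = Pedigree(new_persons, new_links)

    old_to_new = {pid: tmp_to_new[pid] for pid in ped.persons}
    added = frozenset(tmp_to_new[pid] for pid in placeholder_tmp)
    return RenumberResult(pedigree=new_ped, old_to_new=old_to_new, added_placeholders=added)
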