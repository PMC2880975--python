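"""Graph queries over pedigrees: closures, founders, filters, subset and asp.

These mirror the classic genealogy-database query catalog: ancestry/descent
closures, founder identification, descendant counting, living/age filters,
the maximal common-ancestor ``subset`` query and the all-shortest-paths
``asp`` pedigree extraction used to connect a set of sampled individuals.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from .errors import ArgumentError, ContractError, UnknownPidError
from .model import Pedigree, Person

Ancestor = Union[int, tuple[int, int]]


def _check_ids(ped: Pedigree, ids: Iterable[int]) -> set[int]:
    ids = set(ids)
    for pid in ids:
        if pid not in ped:
            raise UnknownPidError(pid)
    return ids


def ancestors(ped: Pedigree, ids: Iterable[int]) -> Pedigree:
    """Induced sub-pedigree on ``ids`` plus all of their ancestors."""
    seeds = _check_ids(ped, ids)
    g = ped.graph()
    closure = set(seeds)
    for pid in seeds:
        closure |= nx.ancestors(g, pid)
    return ped.subset_on(closure)


def ancestor_pids(ped: Pedigree, pid: int) -> set[int]:
    """Strict ancestors of one individual (excluding the individual)."""
    if pid not in ped:
        raise UnknownPidError(pid)
    return nx.ancestors(ped.graph(), pid)


def descendants(ped: Pedigree, pid: int) -> set[int]:
    """All persons reachable from ``pid`` by parent->child edges (pid excluded)."""
    if pid not in ped:
        raise UnknownPidError(pid)
    return nx.descendants(ped.graph(), pid)


def founders(ped: Pedigree) -> set[int]:
    """Persons with zero parents in this pedigree."""
    return set(ped.founder_pids())


def founder_descendant(ped: Pedigree, pid: int) -> set[int]:
    """Founders among the ancestor closure of ``pid`` (a founder returns itself)."""
    if pid not in ped:
        raise UnknownPidError(pid)
    closure = ancestor_pids(ped, pid) | {pid}
    return {p for p in closure if ped.is_founder(p)}


def count_descendant(pairs: Iterable[tuple[int, int]]) -> dict[int, int]:
    """Count distinct descendants per ancestor from (ancestor, descendant) pairs."""
    seen: dict[int, set[int]] = {}
    for anc, desc in pairs:
        seen.setdefault(anc, set()).add(desc)
    return {anc: len(d) for anc, d in sorted(seen.items())}


def living(
    persons: Union[Mapping[int, Person], Iterable[Person]],
    birth_window: Optional[tuple[int, int]] = None,
) -> set[int]:
    """Presumed-living filter: no recorded death year.

    With ``birth_window=(lo, hi)`` (closed interval) a person must also have a
    known birth year inside the window; unknown birth years are excluded.
    """
    if isinstance(persons, Mapping):
        persons = persons.values()
    if birth_window is not None:
        lo, hi = birth_window
        if lo > hi:
            raise ArgumentError(f"inverted birth window ({lo}, {hi})")
    out = set()
    for p in persons:
        if p.death_year is not None:
            continue
        if birth_window is not None:
            if p.birth_year is None or not (lo <= p.birth_year <= hi):
                continue
        out.add(p.pid)
    return out


def _candidate_coverage(ped: Pedigree, members: tuple[int, ...], ids: set[int]) -> set[int]:
    g = ped.graph()
    desc: set[int] = set(members)
    for m in members:
        desc |= nx.descendants(g, m)
    return ids & desc


def subset(ped: Pedigree, ids: Iterable[int]) -> tuple[Ancestor, set[int]]:
    """Find the ancestor (person or married couple) covering the most of ``ids``.

    A couple — two persons sharing at least one child — is treated as a unit
    whose descendants are the union over its members. Returns the winning
    ancestor and the maximal covered member set. Ties prefer couples over
    single ancestors, then the smallest pid (pair).
    """
    ids = _check_ids(ped, ids)
    if not ids:
        raise ArgumentError("subset requires at least one individual")

    g = ped.graph()
    desc_cache: dict[int, set[int]] = {}

    def desc_of(pid: int) -> set[int]:
        if pid not in desc_cache:
            desc_cache[pid] = nx.descendants(g, pid)
        return desc_cache[pid]

    best: Optional[tuple] = None  # (coverage, is_couple, sort_key, ancestor, members)
    for a, b in sorted(ped.couples()):
        members = ids & (desc_of(a) | desc_of(b) | {a, b})
        key = (len(members), 1, (-a, -b))
        if best is None or key > best[0]:
            best = (key, (a, b), members)
    for pid in sorted(ped.persons):
        members = ids & (desc_of(pid) | {pid})
        key = (len(members), 0, (-pid,))
        if best is None or key > best[0]:
            best = (key, pid, members)
    assert best is not None
    return best[1], best[2]


def _bfs_down(ped: Pedigree, sources: Sequence[int]) -> dict[int, int]:
    """Shortest parent->child distances from any source."""
    dist = {s: 0 for s in sources}
    q = deque(sources)
    while q:
        v = q.popleft()
        for c in ped.children_of(v):
            if c not in dist:
                dist[c] = dist[v] + 1
                q.append(c)
    return dist


def _bfs_up(ped: Pedigree, target: int) -> dict[int, int]:
    """Shortest parent->child distances from each vertex down to target."""
    dist = {target: 0}
    q = deque([target])
    while q:
        v = q.popleft()
        for p in ped.parents_of(v):
            if p not in dist:
                dist[p] = dist[v] + 1
                q.append(p)
    return dist


def asp(ped: Pedigree, ids: Iterable[int], ancestor: Ancestor) -> Pedigree:
    """All-shortest-paths pedigree connecting sampled ``ids`` to an ancestor.

    For each sampled individual s, d(s) is the length in parent->child edges
    of the shortest directed path from the ancestor (from either member when
    the ancestor is a couple) to s. The output contains every vertex on some
    length-d(s) path for some s, then is completed with mates so that every
    included person has zero or two parents. Persons added only by spouse
    completion are recorded in ``result.meta['completion_added']``.
    """
    ids = _check_ids(ped, ids)
    members = ancestor if isinstance(ancestor, tuple) else (ancestor,)
    _check_ids(ped, members)

    down = _bfs_down(ped, members)
    keep: set[int] = set(members)
    for s in sorted(ids):
        if s not in down:
            raise ContractError(f"individual {s} is not a descendant of {ancestor}")
        up = _bfs_up(ped, s)
        d = down[s]
        keep |= {v for v in up if v in down and down[v] + up[v] == d}

    # complete with mates: a path vertex with exactly one parent on a path
    # gains its other parent, who enters as a founder of the output
    added: set[int] = set()
    for pid in sorted(keep):
        par = ped.parents_of(pid)
        present = [p for p in par if p in keep]
        if len(present) == 1:
            added.add(next(p for p in par if p not in keep))
    keep |= added

    sub = ped.subset_on(keep)
    persons = list(sub.persons.values())
    links = [lk for lk in sub.links if lk.child_pid not in added]
    return Pedigree(persons, links, meta={"completion_added": frozenset(added)})


def person_info(
    persons: Union[Mapping[int, Person], Iterable[Person]], pid: int
) -> Person:
    """Echo one person's full record."""
    if not isinstance(persons, Mapping):
        persons = {p.pid: p for p in persons}
    try:
        return persons[pid]
    except KeyError:
        raise UnknownPidError(pid) from None
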