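"""Recursive founder trimming.

A nuclear family at the top of the pedigree whose parents are both founders
and who have exactly one child (and no children by anyone else) can be
collapsed: the only child carries all genomic information derived from the
two parents, so it replaces them as a *trimmed founder*. Rounds repeat until
no family is eligible; a child made parentless in one round is a candidate
parent in the next.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ParentLink, Pedigree


@dataclass
class TrimResult:
    pedigree: Pedigree
    rounds: int
    replaced: list[list[tuple[int, int, int]]]  # per round: (father, mother, child)
    trimmed_founders: frozenset[int]

    def all_replaced(self) -> list[tuple[int, int, int]]:
        return [t for rnd in self.replaced for t in rnd]


def _eligible_families(ped: Pedigree) -> list[tuple[int, int, int]]:
    """Top-of-pedigree couples with a single child and no other offspring.

    Both parents must be parentless, share exactly one child, and have no
    other child by any mate — a remarried founder's families are ineligible
    because the single child would not carry that parent's other genome paths.
    """
    out = []
    for a, b in sorted(ped.couples()):
        if ped.parents_of(a) or ped.parents_of(b):
            continue
        kids_a, kids_b = ped.children_of(a), ped.children_of(b)
        if len(kids_a) == 1 and kids_a == kids_b:
            (child,) = kids_a
            pa, pb = (a, b) if _father_first(ped, a, b) else (b, a)
            out.append((pa, pb, child))
    return out


def _father_first(ped: Pedigree, a: int, b: int) -> bool:
    from .model import Sex

    sa, sb = ped.persons[a].sex, ped.persons[b].sex
    if sa is Sex.MALE or sb is Sex.FEMALE:
        return True
    if sb is Sex.MALE or sa is Sex.FEMALE:
        return False
    return a < b


def trim_once(ped: Pedigree) -> TrimResult:
    """One simultaneous round of trimming (identity when nothing is eligible)."""
    fams = _eligible_families(ped)
    if not fams:
        return TrimResult(ped, rounds=0, replaced=[], trimmed_founders=ped.founder_pids())
    removed = {p for fa, mo, _ in fams for p in (fa, mo)}
    persons = [p for pid, p in sorted(ped.persons.items()) if pid not in removed]
    links = [
        lk
        for lk in ped.links
        if lk.parent_pid not in removed
    ]
    new_ped = Pedigree(persons, links, meta=dict(ped.meta))
    return TrimResult(
        new_ped, rounds=1, replaced=[fams], trimmed_founders=new_ped.founder_pids()
    )


def trim(ped: Pedigree) -> TrimResult:
    """Trim to the fixed point; ``rounds`` counts the non-identity passes."""
    rounds = 0
    replaced: list[list[tuple[int, int, int]]] = []
    current = ped
    while True:
        step = trim_once(current)
        if step.rounds == 0:
            break
        rounds += 1
        replaced.extend(step.replaced)
        current = step.pedigree
    return TrimResult(
        current,
        rounds=rounds,
        replaced=replaced,
        trimmed_founders=current.founder_pids(),
    )
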