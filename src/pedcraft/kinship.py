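"""Kinship and inbreeding coefficients, and relative founder representation.

The kinship coefficient phi(i, j) is the probability that an allele sampled
at random from i is identical by descent (IBD) to an allele sampled at
random from j at the same locus. It is computed by the classic recursion on
an ancestor-first (renumbered) pedigree:

    phi(f, f) = (1 + F_f) / 2                    for a founder f
    phi(i, i) = (1 + phi(father_i, mother_i)) / 2
    phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2   for id(i) > id(j)

where a founder contributes zero cross-terms and F_f is an optionally
assigned founder inbreeding coefficient. The ancestor-first numbering makes
"recurse on the higher id" well-founded, which is what makes the
renumbering pass pay off for large pedigrees.

The relative founder representation (RFR) of a founder in a descendant is
the expected proportion of the descendant's alleles inherited IBD from that
founder: twice the founder-descendant kinship, evaluated with all founder
inbreeding forced to zero. Founders' own ancestors are outside the
genealogy by definition, so Mendelian-sampling expectations must not be
mixed with the founder's internal IBD — an inbred founder parent would
otherwise out-weigh a non-inbred one.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ArgumentError, ContractError, UnknownPidError
from .model import Pedigree

NORMALIZATION_TOL = 1e-9


class KinshipContext:
    """Memoized kinship calculator bound to one renumbered pedigree.

    Parameters
    ----------
    pedigree:
        A pedigree whose links all satisfy parent pid < child pid (the
        ancestor-first property guaranteed by ``renumber``).
    founder_inbreeding:
        Optional mapping founder pid -> F in [0, 1]. Only founders may carry
        an assigned F; everyone else's inbreeding follows from the pedigree.
    exact:
        Compute with exact rational arithmetic (``fractions.Fraction``)
        instead of floats; useful for verification on small pedigrees.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        founder_inbreeding: Optional[Mapping[int, float]] = None,
        exact: bool = False,
    ):
        if not pedigree.is_renumbered():
            raise ContractError(
                "kinship requires an ancestor-first pedigree (parent pids smaller "
                "than child pids); run renumber() first"
            )
        self.pedigree = pedigree
        self.exact = exact
        self.founder_inbreeding: dict[int, float] = dict(founder_inbreeding or {})
        for pid, f in self.founder_inbreeding.items():
            if pid not in pedigree:
                raise UnknownPidError(pid)
            if not pedigree.is_founder(pid):
                raise ContractError(
                    f"founder inbreeding assigned to non-founder {pid}"
                )
            if not 0 <= f <= 1:
                raise ArgumentError(f"founder inbreeding F={f} outside [0, 1]")
        self._phi: dict[tuple[int, int], float] = {}
        self._zero_ctx: Optional["KinshipContext"] = None

    def _no_inbreeding(self) -> "KinshipContext":
        """Twin context over the same pedigree with all founder F forced to 0."""
        if not self.founder_inbreeding:
            return self
        if self._zero_ctx is None:
            self._zero_ctx = KinshipContext(self.pedigree, exact=self.exact)
        return self._zero_ctx

    def _num(self, x) -> float:
        return Fraction(x) if self.exact else float(x)

    def kinship(self, i: int, j: int) -> float:
        """phi(i, j); symmetric and memoized."""
        for pid in (i, j):
            if pid not in self.pedigree:
                raise UnknownPidError(pid)
        # deep pedigrees recurse one frame per generation of separation
        limit = 4 * len(self.pedigree) + 1000
        if sys.getrecursionlimit() < limit:
            sys.setrecursionlimit(limit)
        return self._kin(i, j)

    def _kin(self, i: int, j: int) -> float:
        if i < j:
            i, j = j, i
        key = (i, j)
        cached = self._phi.get(key)
        if cached is not None:
            return cached
        ped = self.pedigree
        par_i = ped.parents_of(i)
        if i == j:
            if not par_i:
                val = (self._num(1) + self._num(self.founder_inbreeding.get(i, 0))) / 2
            else:
                fa, mo = par_i
                val = (self._num(1) + self._kin(fa, mo)) / 2
        else:
            if not par_i:
                val = self._num(0)
            else:
                fa, mo = par_i
                val = (self._kin(fa, j) + self._kin(mo, j)) / 2
        self._phi[key] = val
        return val

    def inbreeding(self, i: int) -> float:
        """F_i: kinship of i's parents; assigned F (default 0) for founders."""
        if i not in self.pedigree:
            raise UnknownPidError(i)
        par = self.pedigree.parents_of(i)
        if not par:
            return self._num(self.founder_inbreeding.get(i, 0))
        fa, mo = par
        return self.kinship(fa, mo)


def calculate_r(ctx: KinshipContext, founder: int, descendant: int) -> float:
    """RFR of a founder in a descendant: 2 * phi with founder inbreeding zeroed.

    The founder argument must be parentless in the context's pedigree (trimmed
    founders qualify). Returns 0 when the descendant does not descend from
    the founder.
    """
    if founder not in ctx.pedigree:
        raise UnknownPidError(founder)
    if ctx.pedigree.parents_of(founder):
        raise ContractError(
            f"calculate_r requires a parentless founder; {founder} has parents"
        )
    zero = ctx._no_inbreeding()
    return 2 * zero.kinship(founder, descendant)


def average_r(
    ctx: KinshipContext, founder: int, descendants: Iterable[int]
) -> float:
    """Arithmetic mean of calculate_r over a (nonempty) descendant set."""
    descendants = sorted(set(descendants))
    if not descendants:
        raise ArgumentError("average_r requires a nonempty descendant set")
    vals = [calculate_r(ctx, founder, d) for d in descendants]
    return sum(vals) / len(vals)


@dataclass
class RfrTable:
    """Founder x descendant expected-contribution matrix with per-founder means.

    ``table`` is indexed by founder pid (rows) and descendant pid (columns);
    each column sums to 1 (every allele in a descendant traces to exactly one
    founder of its ancestor closure). ``mean_rfr`` therefore sums to 1 over
    founders.
    """

    table: pd.DataFrame
    mean_rfr: pd.Series
    descendants: tuple[int, ...]

    @property
    def founders(self) -> tuple[int, ...]:
        return tuple(self.table.index)


def rfr_table(
    ctx: KinshipContext,
    founders: Optional[Iterable[int]],
    descendants: Iterable[int],
) -> RfrTable:
    """Full RFR table for a founder set over a descendant set.

    ``founders=None`` uses the founders of the ancestor closure of the
    descendants, which is also what the per-descendant normalization check
    requires: if the supplied founder set misses contributing founders, the
    columns cannot sum to 1 and a contract error reports the deficit.
    """
    from . import queries  # local import to avoid a cycle

    descendants = tuple(sorted(set(descendants)))
    if not descendants:
        raise ArgumentError("rfr_table requires a nonempty descendant set")
    if founders is None:
        closure = queries.ancestors(ctx.pedigree, descendants)
        founder_set = sorted(queries.founders(closure))
    else:
        founder_set = sorted(set(founders))

    data = {
        d: [calculate_r(ctx, f, d) for f in founder_set] for d in descendants
    }
    table = pd.DataFrame(data, index=founder_set, dtype=float)
    colsums = table.sum(axis=0)
    bad = colsums[(colsums - 1.0).abs() > NORMALIZATION_TOL]
    if not bad.empty:
        worst = bad.index[0]
        raise ContractError(
            f"founder set incomplete: RFR over supplied founders sums to "
            f"{bad.iloc[0]:.12f} (deficit {1 - bad.iloc[0]:.3e}) for descendant {worst}"
        )
    mean = table.mean(axis=1)
    return RfrTable(table=table, mean_rfr=mean, descendants=descendants)


def cumulative_representation(
    table: RfrTable,
) -> list[tuple[int, float, float]]:
    """Rank founders by descending mean RFR with the running cumulative share.

    Ties are broken by ascending pid. The cumulative share is the running sum
    divided by the total mean RFR, so it is nondecreasing and ends at 1.
    """
    items = sorted(
        table.mean_rfr.items(), key=lambda kv: (-kv[1], kv[0])
    )
    total = sum(v for _, v in items)
    if total == 0:
        raise ArgumentError("cumulative representation undefined: all means are zero")
    out = []
    running = 0.0
    for pid, mean in items:
        running += mean
        out.append((pid, float(mean), float(running / total)))
    return out


def count_for_threshold(
    ranked: Sequence[tuple[int, float, float]], q: float
) -> int:
    """Smallest k such that the top-k cumulative share reaches q (0 < q <= 1)."""
    if not 0 < q <= 1:
        raise ArgumentError(f"threshold q={q} outside (0, 1]")
    for k, (_, _, cum) in enumerate(ranked, start=1):
        if cum >= q - 1e-12:
            return k
    return len(ranked)
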