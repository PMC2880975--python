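"""Gene-dropping: Monte-Carlo segregation of distinct founder alleles.

Each founder is assigned two unique allele labels; every non-founder
inherits one uniformly random allele from each parent, processed in
ancestor-first order so a single pass per replicate suffices. Empirical
founder representation and kinship estimated from many replicates converge
to the analytic single-locus expectations, and the spread across replicates
measures Mendelian-sampling variance — which the analytic coefficients
cannot express (parent-offspring sharing is exactly 1/2 in every replicate,
full-sib sharing varies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, UnknownPidError
from .model import Pedigree


@dataclass
class GeneDropResult:
    """Per-replicate diploid founder-allele labels for every person.

    ``alleles`` has shape (n_reps, n_persons, 2) and holds integer allele
    labels; ``allele_founder[label]`` is the founder pid the label traces to.
    Persons are indexed ancestor-first via ``order`` / ``index_of``.
    """

    n_reps: int
    seed: int
    order: tuple[int, ...]
    alleles: np.ndarray
    allele_founder: np.ndarray

    def __post_init__(self) -> None:
        self.index_of = {pid: i for i, pid in enumerate(self.order)}

    def founder_labels(self, founder: int) -> np.ndarray:
        """The (two) allele labels assigned to one founder."""
        labels = np.flatnonzero(self.allele_founder == founder)
        if labels.size == 0:
            raise UnknownPidError(founder)
        return labels


def gene_drop(ped: Pedigree, n_reps: int, seed: int) -> GeneDropResult:
    """Drop distinct founder alleles through a renumbered pedigree.

    The pedigree must satisfy the ancestor-first property (parent pid <
    child pid) so one ordered sweep propagates alleles. Reproducible: the
    same seed, pedigree and replicate count give identical results.
    """
    if not ped.is_renumbered():
        raise ContractError(
            "gene_drop requires an ancestor-first pedigree; run renumber() first"
        )
    rng = np.random.default_rng(seed)
    order = tuple(sorted(ped.persons))  # renumbered => ancestor-first
    index = {pid: i for i, pid in enumerate(order)}
    n = len(order)

    founders = [pid for pid in order if ped.is_founder(pid)]
    allele_founder = np.repeat(founders, 2).astype(np.int64)
    alleles = np.empty((n_reps, n, 2), dtype=np.int64)

    label = {f: (2 * k, 2 * k + 1) for k, f in enumerate(founders)}
    for pid in order:
        i = index[pid]
        par = ped.parents_of(pid)
        if not par:
            alleles[:, i, 0] = label[pid][0]
            alleles[:, i, 1] = label[pid][1]
        else:
            for slot, parent in enumerate(par):
                j = index[parent]
                pick = rng.integers(0, 2, size=n_reps)
                alleles[:, i, slot] = alleles[np.arange(n_reps), j, pick]
    return GeneDropResult(
        n_reps=n_reps,
        seed=seed,
        order=order,
        alleles=alleles,
        allele_founder=allele_founder,
    )


def empirical_rfr(
    result: GeneDropResult, founder: int, descendant: int
) -> tuple[float, float, float]:
    """Empirical founder representation with its Monte-Carlo error.

    Returns (estimate, mc_standard_error, variance_across_reps) where the
    per-replicate statistic is the fraction of the descendant's two alleles
    labeled from the founder. The variance across replicates is the
    Mendelian-sampling variance of realized sharing.
    """
    if result.n_reps == 0:
        raise ContractError("empirical_rfr on an empty gene-drop result")
    labels = result.founder_labels(founder)
    try:
        di = result.index_of[descendant]
    except KeyError:
        raise UnknownPidError(descendant) from None
    share = np.isin(result.alleles[:, di, :], labels).sum(axis=1) / 2.0
    est = float(share.mean())
    var = float(share.var(ddof=1)) if result.n_reps > 1 else 0.0
    se = float(np.sqrt(var / result.n_reps))
    return est, se, var


def empirical_kinship(
    result: GeneDropResult, i: int, j: int
) -> tuple[float, float]:
    """Empirical kinship: mean fraction of the 4 cross-person allele pairs IBD."""
    if result.n_reps == 0:
        raise ContractError("empirical_kinship on an empty gene-drop result")
    try:
        ii, jj = result.index_of[i], result.index_of[j]
    except KeyError as e:
        raise UnknownPidError(e.args[0]) from None
    a = result.alleles[:, ii, :]  # (reps, 2)
    b = result.alleles[:, jj, :]
    matches = (a[:, :, None] == b[:, None, :]).sum(axis=(1, 2)) / 4.0
    est = float(matches.mean())
    var = float(matches.var(ddof=1)) if result.n_reps > 1 else 0.0
    se = float(np.sqrt(var / result.n_reps))
    return est, se
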