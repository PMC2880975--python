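"""Synthetic closed-founder-population pedigrees, plus tiny worked fixtures.

The generator emulates the demography that shapes founder representation in
a closed population: a founding cohort of married couples, a founder
immigration schedule that declines to zero over generations, large sibships
(zero-truncated Poisson), and within-population mating that avoids close
kin up to a kinship threshold but relaxes when the pool is exhausted — the
mechanism by which consanguinity rises over time in such populations.
Birth years advance ~25 years per generation with small jitter, and
missingness/affiliation flags are injected at configurable rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ArgumentError
from .kinship import KinshipContext
from .model import Affiliation, ParentLink, Pedigree, Person, Sex, build_pedigree

GENERATION_YEARS = 25


@dataclass
class SynthConfig:
    """Parameters of the synthetic closed founder population.

    ``immigration_per_generation`` lists the number of new founders entering
    the mating pool in generations 1, 2, ...; ``None`` uses a halving
    schedule starting from ``founding_couples`` individuals, reaching zero —
    the closed-population regime where essentially no new genetic material
    arrives after the early generations. ``sibship_mean`` is the mean of the
    zero-truncated Poisson sibship-size distribution (large-family default
    of 4). ``mating_kinship_max`` is the kinship ceiling respected while
    pairing (first-cousin level 0.0625 by default), relaxed when no pairing
    is otherwise possible.
    """

    n_generations: int = 5
    founding_couples: int = 10
    immigration_per_generation: Optional[Sequence[int]] = None
    sibship_mean: float = 4.0
    mating_kinship_max: float = 0.0625
    sex_ratio: float = 0.5
    missing_birth_year_rate: float = 0.1
    affiliation_flag_rate: float = 0.1
    start_year: int = 1700
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1 or self.founding_couples < 1:
            raise ArgumentError("need >=1 generation and >=1 founding couple")
        for name in ("sex_ratio", "missing_birth_year_rate", "affiliation_flag_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ArgumentError(f"{name}={v} outside [0, 1]")
        if self.sibship_mean <= 1:
            raise ArgumentError("zero-truncated sibship mean must exceed 1")
        if self.immigration_per_generation is not None:
            if any(k < 0 for k in self.immigration_per_generation):
                raise ArgumentError("immigration counts must be >= 0")

    def immigration(self, generation: int) -> int:
        """New founders entering the pool at ``generation`` (>= 1)."""
        if self.immigration_per_generation is not None:
            sched = self.immigration_per_generation
            return sched[generation - 1] if generation - 1 < len(sched) else 0
        return self.founding_couples >> generation  # halving, declines to 0


def _ztp_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean."""
    return brentq(
        lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-9, max(10.0, 5 * mean)
    )


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    out = np.zeros(size, dtype=int)
    todo = np.arange(size)
    while todo.size:
        draw = rng.poisson(lam, size=todo.size)
        ok = draw > 0
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate(config: SynthConfig) -> tuple[list[Person], list[ParentLink]]:
    """Generate a synthetic pedigree; deterministic for a given config seed.

    Pids are assigned in birth order, so the result is already
    ancestor-first. Returns the two-table representation accepted by
    :func:`~pedcraft.model.build_pedigree`.
    """
    rng = np.random.default_rng(config.seed)
    lam = _ztp_lambda(config.sibship_mean)

    persons: list[Person] = []
    links: list[ParentLink] = []
    next_pid = 1

    def new_person(sex: Sex, generation: int) -> Person:
        nonlocal next_pid
        year: Optional[int] = None
        if rng.random() >= config.missing_birth_year_rate:
            jitter = int(rng.integers(-3, 4))
            year = config.start_year + generation * GENERATION_YEARS + jitter
        affil = (
            Affiliation.FLAGGED
            if rng.random() < config.affiliation_flag_rate
            else Affiliation.UNKNOWN
        )
        p = Person(pid=next_pid, sex=sex, birth_year=year, affiliation=affil)
        next_pid += 1
        persons.append(p)
        return p

    # generation 0: married founder couples
    couples: list[tuple[int, int]] = []
    for _ in range(config.founding_couples):
        m = new_person(Sex.MALE, 0)
        f = new_person(Sex.FEMALE, 0)
        couples.append((m.pid, f.pid))

    for gen in range(1, config.n_generations):
        # children of the previous generation's couples
        sizes = _sample_ztp(rng, lam, len(couples))
        pool_m: list[int] = []
        pool_f: list[int] = []
        for (father, mother), k in zip(couples, sizes):
            for _ in range(int(k)):
                sex = Sex.MALE if rng.random() < config.sex_ratio else Sex.FEMALE
                child = new_person(sex, gen)
                links.append(ParentLink(father, child.pid))
                links.append(ParentLink(mother, child.pid))
                (pool_m if sex is Sex.MALE else pool_f).append(child.pid)

        # immigrant founders join the mating pool, balancing the sexes
        for _ in range(config.immigration(gen)):
            sex = Sex.MALE if len(pool_m) < len(pool_f) else Sex.FEMALE
            imm = new_person(sex, gen)
            (pool_m if sex is Sex.MALE else pool_f).append(imm.pid)

        if gen == config.n_generations - 1:
            break  # bottom generation stays unmarried

        couples = _pair_up(
            pool_m, pool_f, persons, links, config.mating_kinship_max, rng
        )
        if not couples:
            warnings.warn(
                f"generation {gen}: no couples could be formed; lineage ends early"
            )
            break

    return persons, links


def _pair_up(
    males: list[int],
    females: list[int],
    persons: list[Person],
    links: list[ParentLink],
    kin_max: float,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Greedy within-population pairing honoring a kinship ceiling.

    Pairs each male (in random order) with the first compatible female; when
    none is compatible the ceiling is relaxed for that male (closest kin
    avoided but marriage still happens), mirroring rising consanguinity once
    a closed population runs out of unrelated partners.
    """
    ctx = KinshipContext(build_pedigree(persons, links))
    males = list(males)
    females = list(females)
    rng.shuffle(males)
    rng.shuffle(females)
    out: list[tuple[int, int]] = []
    for m in males:
        if not females:
            break
        kins = [float(ctx.kinship(m, f)) for f in females]
        ok = [i for i, k in enumerate(kins) if k <= kin_max]
        if ok:
            idx = ok[0]
        else:
            warnings.warn(
                f"mating pool exhausted below kinship {kin_max}; relaxing for pid {m}"
            )
            idx = int(np.argmin(kins))
        out.append((m, females.pop(idx)))
    return out


# -- exact worked-example fixtures ----------------------------------------


def fixture_figure1() -> tuple[list[Person], list[ParentLink]]:
    """Five-person, two-couple pedigree with three founders.

    A married founder couple (Hans Beuttschi, Margaret Zum Bach) has an only
    son Peter Beuttschi, who marries the female founder Margarete Oswald;
    their only son is Peter Beuttschi Jr. Two recursive trimming rounds
    collapse the three founders down to one trimmed founder.
    """
    persons = [
        Person(1, Sex.MALE, name="Hans Beuttschi"),
        Person(2, Sex.FEMALE, name="Margaret Zum Bach"),
        Person(3, Sex.MALE, name="Peter Beuttschi"),
        Person(4, Sex.FEMALE, name="Margarete Oswald"),
        Person(5, Sex.MALE, name="Peter Beuttschi Jr."),
    ]
    links = [
        ParentLink(1, 3),
        ParentLink(2, 3),
        ParentLink(3, 5),
        ParentLink(4, 5),
    ]
    return persons, links


def fixture_stehly() -> tuple[list[Person], list[ParentLink]]:
    """Four-generation descent chain exercising birth-year imputation.

    Only the bottom individual (Catherine Sieber, b. 1770) has a recorded
    year; each earlier generation must be estimated by subtracting the
    generation interval, chaining through estimated oldest children. Sibling
    branches with unknown years are included so the oldest-child minimum
    rule is exercised rather than trivially satisfied.
    """
    persons = [
        Person(1, Sex.MALE, name="Stehly founder"),
        Person(2, Sex.MALE, name="Henry Stehly"),
        Person(3, Sex.FEMALE, name="Magdalena Stehly"),
        Person(4, Sex.FEMALE, name="Catherine Sieber", birth_year=1770),
        Person(5, Sex.MALE, name="Stehly sibling A"),
        Person(6, Sex.MALE, name="Stehly sibling B"),
        Person(7, Sex.FEMALE, name="Sieber sibling"),
    ]
    links = [
        ParentLink(1, 2),
        ParentLink(1, 5),  # Henry's brother, year unknown
        ParentLink(2, 3),
        ParentLink(2, 6),  # Magdalena's brother, year unknown
        ParentLink(3, 4),
        ParentLink(3, 7),  # Catherine's sister, year unknown
    ]
    return persons, links
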