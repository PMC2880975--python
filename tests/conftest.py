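import warnings

import pytest
from hypothesis import settings

import pedcraft as pc
from pedcraft.synth import SynthConfig, generate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def fig1_pedigree():
    """Five-person two-couple pedigree with three founders (1, 2, 4)."""
    persons, links = pc.fixture_figure1()
    return pc.build_pedigree(persons, links)


@pytest.fixture
def stehly_pedigree():
    persons, links = pc.fixture_stehly()
    return pc.build_pedigree(persons, links)


@pytest.fixture
def trio():
    """Founder couple (1 male, 2 female) with one child (3)."""
    persons = [
        pc.Person(1, pc.Sex.MALE),
        pc.Person(2, pc.Sex.FEMALE),
        pc.Person(3, pc.Sex.MALE),
    ]
    links = [pc.ParentLink(1, 3), pc.ParentLink(2, 3)]
    return pc.build_pedigree(persons, links)


def nuclear(n_children: int) -> pc.Pedigree:
    """Founder couple with n children (pids 3..)."""
    persons = [pc.Person(1, pc.Sex.MALE), pc.Person(2, pc.Sex.FEMALE)]
    links = []
    for k in range(n_children):
        persons.append(pc.Person(3 + k))
        links.append(pc.ParentLink(1, 3 + k))
        links.append(pc.ParentLink(2, 3 + k))
    return pc.build_pedigree(persons, links)


def three_generation() -> pc.Pedigree:
    """Founder grandparents (1,2), their child (3) x founder (4), grandchild (5)."""
    persons, links = pc.fixture_figure1()
    return pc.build_pedigree(persons, links)


def random_pedigree(
    seed: int,
    n_generations: int = 4,
    founding_couples: int = 3,
    sibship_mean: float = 2.5,
    **kw,
) -> pc.Pedigree:
    """Small synthetic pedigree for property tests (already ancestor-first)."""
    cfg = SynthConfig(
        n_generations=n_generations,
        founding_couples=founding_couples,
        sibship_mean=sibship_mean,
        missing_birth_year_rate=kw.pop("missing_birth_year_rate", 0.0),
        seed=seed,
        **kw,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        persons, links = generate(cfg)
    return pc.build_pedigree(persons, links)
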