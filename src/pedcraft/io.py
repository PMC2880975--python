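"""Text I/O: LINKAGE pre-makeped pedigree files and the two-table format.

The two-table representation mirrors a genealogy store: a *person* table and
a parent-child *relationship* table, both tab-separated with headers. Empty
fields mean missing. The LINKAGE skeleton is the 5-column pre-makeped form
``family individual father mother sex`` with 0 as the missing-parent
sentinel and sex coded 1=male, 2=female, 0=unknown.
"""

from __future__ import annotations

from typing import IO, Iterable, Union

import pandas as pd

from .errors import ContractError, PedigreeParseError, UnknownPidError
from .model import Affiliation, ParentLink, Pedigree, Person, Sex, build_pedigree

PERSON_COLUMNS = [
    "pid",
    "sex",
    "birth_year",
    "death_year",
    "affiliation",
    "name",
    "birth_year_estimated",
]
LINK_COLUMNS = ["parent_pid", "child_pid", "biological"]


def _father_mother(ped: Pedigree, pid: int) -> tuple[int, int]:
    par = ped.parents_of(pid)
    if not par:
        return 0, 0
    if len(par) != 2:
        raise ContractError(
            f"person {pid} has exactly one recorded parent; run renumber() to "
            "complete missing spouses before writing LINKAGE output"
        )
    a, b = (ped.persons[p] for p in par)
    if a.sex is Sex.MALE or b.sex is Sex.FEMALE:
        return a.pid, b.pid
    if b.sex is Sex.MALE or a.sex is Sex.FEMALE:
        return b.pid, a.pid
    return a.pid, b.pid  # both unknown: smaller pid in the father slot


def write_linkage(ped: Pedigree, family_id: str = "FAM") -> str:
    """Render a pedigree as LINKAGE pre-makeped text, ancestor-first.

    Requires the zero-or-two-parents property (see :func:`~pedcraft.model.renumber`).
    """
    rows = []
    for pid in ped.topological_pids():
        father, mother = _father_mother(ped, pid)
        sex = ped.persons[pid].sex.linkage_code
        rows.append(f"{family_id} {pid} {father} {mother} {sex}")
    return "\n".join(rows) + ("\n" if rows else "")


def read_linkage(source: Union[str, IO[str], Iterable[str]]) -> Pedigree:
    """Parse LINKAGE pre-makeped text back into a pedigree.

    Rows must carry at least 5 whitespace-delimited columns; extra columns
    (phenotypes, markers) are ignored. Both parents must be present or both
    0 — a half-specified parent pair is rejected.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    elif hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = list(source)

    persons: list[Person] = []
    links: list[ParentLink] = []
    pids: set[int] = set()
    parent_refs: list[tuple[int, int]] = []  # (line_no, pid)
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 5:
            raise PedigreeParseError(f"line {ln}: expected >=5 columns, got {len(cols)}")
        try:
            pid, father, mother, sexcode = (int(c) for c in cols[1:5])
        except ValueError:
            raise PedigreeParseError(f"line {ln}: non-integer field in {cols[1:5]}") from None
        if (father == 0) != (mother == 0):
            raise ContractError(
                f"line {ln}: person {pid} has one parent recorded as 0 and the "
                "other as nonzero; LINKAGE pedigrees require zero or two parents"
            )
        persons.append(Person(pid=pid, sex=Sex.from_linkage_code(sexcode)))
        pids.add(pid)
        if father != 0:
            links.append(ParentLink(father, pid))
            links.append(ParentLink(mother, pid))
            parent_refs.extend([(ln, father), (ln, mother)])

    for ln, ref in parent_refs:
        if ref not in pids:
            raise UnknownPidError(ref)
    return build_pedigree(persons, links)


# -- person / relationship tables -----------------------------------------


def persons_to_frame(persons: Iterable[Person]) -> pd.DataFrame:
    rows = [
        {
            "pid": p.pid,
            "sex": p.sex.value,
            "birth_year": p.birth_year,
            "death_year": p.death_year,
            "affiliation": p.affiliation.value,
            "name": p.name,
            "birth_year_estimated": int(p.birth_year_estimated),
        }
        for p in persons
    ]
    return pd.DataFrame(rows, columns=PERSON_COLUMNS)


def write_person_table(persons: Iterable[Person], path_or_buf) -> None:
    persons_to_frame(persons).to_csv(path_or_buf, sep="\t", index=False, na_rep="")


def read_person_table(path_or_buf) -> list[Person]:
    df = pd.read_csv(path_or_buf, sep="\t", dtype="object", keep_default_na=False)
    missing = {"pid", "sex"} - set(df.columns)
    if missing:
        raise PedigreeParseError(f"person table lacks columns {sorted(missing)}")
    out: list[Person] = []
    for _, row in df.iterrows():
        def opt_int(key):
            v = str(row.get(key, "") or "").strip()
            if v in ("", "nan"):
                return None
            try:
                return int(float(v))
            except ValueError:
                raise PedigreeParseError(f"non-integer {key!r} value {v!r}") from None

        est = str(row.get("birth_year_estimated", "0") or "0").strip()
        out.append(
            Person(
                pid=opt_int("pid"),
                sex=Sex(str(row["sex"]) or "unknown"),
                birth_year=opt_int("birth_year"),
                death_year=opt_int("death_year"),
                birth_year_estimated=est not in ("", "0", "false", "False"),
                affiliation=Affiliation(str(row.get("affiliation", "") or "unknown")),
                name=(str(row["name"]) or None) if "name" in df.columns else None,
            )
        )
    return out


def write_link_table(links: Iterable[ParentLink], path_or_buf) -> None:
    df = pd.DataFrame(
        [
            {"parent_pid": lk.parent_pid, "child_pid": lk.child_pid, "biological": int(lk.biological)}
            for lk in links
        ],
        columns=LINK_COLUMNS,
    )
    df.to_csv(path_or_buf, sep="\t", index=False)


def read_link_table(path_or_buf) -> list[ParentLink]:
    df = pd.read_csv(path_or_buf, sep="\t", dtype="object", keep_default_na=False)
    missing = set(LINK_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise PedigreeParseError(f"relationship table lacks columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        try:
            parent, child = int(row["parent_pid"]), int(row["child_pid"])
        except ValueError:
            raise PedigreeParseError(
                f"non-integer pid in relationship row {dict(row)}"
            ) from None
        bio = str(row.get("biological", "1") or "1").strip() not in ("0", "false", "False")
        out.append(ParentLink(parent, child, biological=bio))
    return out


def read_pair_file(source: Union[str, IO[str], Iterable[str]]) -> list[tuple[int, int]]:
    """Read ancestor-descendant pid pairs: two tab/space-separated columns."""
    if isinstance(source, str):
        lines = source.splitlines()
    elif hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = list(source)
    pairs = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 2:
            raise PedigreeParseError(f"line {ln}: expected 2 columns, got {len(cols)}")
        try:
            pairs.append((int(cols[0]), int(cols[1])))
        except ValueError:
            raise PedigreeParseError(f"line {ln}: non-integer pid in {cols}") from None
    return pairs
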