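"""Pedigree parsing, validation, topological ordering and reference populations.

The on-disk format is a UTF-8 comma-separated file with the header
``id,sire,dam,sex,birth_year,country,tns,ncl``; the empty string denotes a
missing value throughout. Parents referenced but never defined are
auto-created as founders (both parents unknown) with a warning, mirroring how
dangling references occur in real registries.
"""

from __future__ import annotations

import csv
import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

SEXES = ("male", "female", "unknown")
STATUSES = ("affected", "carrier", "normal", "untested")

HEADER = ["id", "sire", "dam", "sex", "birth_year", "country", "tns", "ncl"]


class PedigreeError(ValueError):
    """Raised for fatal pedigree defects (cycles, duplicate ids, self-parentage)."""


@dataclass(frozen=True)
class AnimalRecord:
    """One animal: identity, parentage, sex, birth year and disease-test status."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"
    birth_year: int | None = None
    country: str | None = None
    tns_status: str = "untested"
    ncl_status: str = "untested"
    year_is_placeholder: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("animal id must be non-empty")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"animal {self.id!r} is its own parent")
        if self.sex not in SEXES:
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id!r}")
        for status in (self.tns_status, self.ncl_status):
            if status not in STATUSES:
                raise PedigreeError(f"invalid disease status {status!r} for {self.id!r}")

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Topologically ordered collection of :class:`AnimalRecord`.

    Every parent precedes its offspring in ``records``. Construction validates
    uniqueness of ids, absence of cycles, and (as warnings) sex consistency of
    parents. Parents referenced but not defined are created as implicit
    founders.
    """

    def __init__(self, records: Iterable[AnimalRecord]):
        records = list(records)
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise PedigreeError(f"duplicate animal id {rec.id!r}")
            seen.add(rec.id)
        records = _add_implicit_founders(records, seen)
        self.records: list[AnimalRecord] = _toposort(records)
        self._index: dict[str, int] = {r.id: i for i, r in enumerate(self.records)}
        _check_sex_consistency(self.records)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnimalRecord]:
        return iter(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def __getitem__(self, animal_id: str) -> AnimalRecord:
        return self.records[self._index[animal_id]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return sorted(self.records, key=lambda r: r.id) == sorted(
            other.records, key=lambda r: r.id
        )

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def parents(self, animal_id: str) -> tuple[str | None, str | None]:
        rec = self[animal_id]
        return rec.sire, rec.dam

    def founders(self) -> set[str]:
        """Animals with no known parents."""
        return {r.id for r in self.records if r.is_founder}

    def parent_indices(self) -> tuple[list[int], list[int]]:
        """Sire/dam positions per record in topological order; -1 = unknown."""
        sire_idx, dam_idx = [], []
        for rec in self.records:
            sire_idx.append(self._index[rec.sire] if rec.sire is not None else -1)
            dam_idx.append(self._index[rec.dam] if rec.dam is not None else -1)
        return sire_idx, dam_idx


@dataclass(frozen=True)
class ReferencePopulation:
    """A birth-year cohort plus the closure of all its known ancestors."""

    members: frozenset[str]
    ancestors: frozenset[str]
    year_lo: int | None = None
    year_hi: int | None = None

    @property
    def all_ids(self) -> frozenset[str]:
        return self.members | self.ancestors


def _add_implicit_founders(
    records: list[AnimalRecord], known: set[str]
) -> list[AnimalRecord]:
    implicit: dict[str, str] = {}  # id -> inferred sex
    for rec in records:
        if rec.sire is not None and rec.sire not in known:
            implicit.setdefault(rec.sire, "male")
        if rec.dam is not None and rec.dam not in known:
            implicit.setdefault(rec.dam, "female")
    if implicit:
        warnings.warn(
            f"{len(implicit)} parent id(s) referenced but not defined; "
            "created as implicit founders: "
            + ", ".join(sorted(implicit)[:5])
            + ("..." if len(implicit) > 5 else ""),
            stacklevel=3,
        )
        records = [
            AnimalRecord(id=pid, sex=sex) for pid, sex in sorted(implicit.items())
        ] + records
    return records


def _toposort(records: list[AnimalRecord]) -> list[AnimalRecord]:
    """Kahn's algorithm; stable with respect to input order; cycles are fatal."""
    by_id = {r.id: r for r in records}
    children: dict[str, list[str]] = {r.id: [] for r in records}
    indeg = {r.id: 0 for r in records}
    for rec in records:
        for parent in (rec.sire, rec.dam):
            if parent is not None:
                children[parent].append(rec.id)
                indeg[rec.id] += 1
    order_hint = {r.id: i for i, r in enumerate(records)}
    ready = deque(sorted((r.id for r in records if indeg[r.id] == 0), key=order_hint.get))
    out: list[AnimalRecord] = []
    while ready:
        aid = ready.popleft()
        out.append(by_id[aid])
        for child in children[aid]:
            indeg[child] -= 1
            if indeg[child] == 0:
                ready.append(child)
    if len(out) != len(records):
        stuck = next(aid for aid, d in indeg.items() if d > 0)
        raise PedigreeError(f"parentage cycle detected involving animal {stuck!r}")
    return out


def _check_sex_consistency(records: list[AnimalRecord]) -> None:
    as_sire: set[str] = set()
    as_dam: set[str] = set()
    for rec in records:
        if rec.sire is not None:
            as_sire.add(rec.sire)
        if rec.dam is not None:
            as_dam.add(rec.dam)
    by_id = {r.id: r for r in records}
    both = {a for a in as_sire & as_dam if by_id[a].sex != "unknown"}
    if both:
        warnings.warn(
            f"{len(both)} animal(s) appear both as sire and dam: "
            + ", ".join(sorted(both)[:5]),
            stacklevel=4,
        )
    bad = [a for a in as_sire if by_id[a].sex == "female"] + [
        a for a in as_dam if by_id[a].sex == "male"
    ]
    if bad:
        warnings.warn(
            f"{len(bad)} animal(s) used as a parent inconsistently with recorded sex: "
            + ", ".join(sorted(set(bad))[:5]),
            stacklevel=4,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def parse_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (header ``id,sire,dam,sex,birth_year,country,tns,ncl``).

    Duplicate ids and parentage cycles are fatal; malformed birth years are
    demoted to record-level warnings with the year set missing; duplicate rows
    for the same id raise (first-record-wins resolution would hide registry
    defects the caller should see).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != HEADER:
            raise PedigreeError(
                f"{path}: header must be {','.join(HEADER)!r}, got {reader.fieldnames}"
            )
        records = []
        for lineno, row in enumerate(reader, start=2):
            year: int | None = None
            raw_year = (row["birth_year"] or "").strip()
            if raw_year:
                try:
                    year = int(raw_year)
                except ValueError:
                    warnings.warn(
                        f"{path}:{lineno}: malformed birth_year {raw_year!r} "
                        f"for {row['id']!r}; set missing"
                    )
            records.append(
                AnimalRecord(
                    id=row["id"].strip(),
                    sire=(row["sire"] or "").strip() or None,
                    dam=(row["dam"] or "").strip() or None,
                    sex=(row["sex"] or "").strip() or "unknown",
                    birth_year=year,
                    country=(row["country"] or "").strip() or None,
                    tns_status=(row["tns"] or "").strip() or "untested",
                    ncl_status=(row["ncl"] or "").strip() or "untested",
                )
            )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree in the canonical CSV dialect (round-trips with parse)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEADER)
        for r in ped:
            writer.writerow(
                [
                    r.id,
                    r.sire or "",
                    r.dam or "",
                    r.sex if r.sex != "unknown" else "",
                    r.birth_year if r.birth_year is not None else "",
                    r.country or "",
                    r.tns_status if r.tns_status != "untested" else "",
                    r.ncl_status if r.ncl_status != "untested" else "",
                ]
            )


# ---------------------------------------------------------------------------
# Reference populations and ancestor closures
# ---------------------------------------------------------------------------

def ancestor_closure(ped: Pedigree, ids: Iterable[str]) -> set[str]:
    """All known ancestors of ``ids`` (fixed point of parent lookup, ids excluded).

    Raises ``KeyError`` if any requested id is not in the pedigree.
    """
    ids = set(ids)
    for aid in ids:
        if aid not in ped:
            raise KeyError(f"unknown animal id {aid!r}")
    out: set[str] = set()
    stack = list(ids)
    while stack:
        aid = stack.pop()
        for parent in ped.parents(aid):
            if parent is not None and parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


def select_reference_population(
    ped: Pedigree, year_lo: int, year_hi: int
) -> ReferencePopulation:
    """Cohort of animals born in ``[year_lo, year_hi]`` plus their ancestor closure.

    Animals with missing birth year are never members. Ancestors exclude
    members unless a member is itself an ancestor of another member.
    """
    if year_lo > year_hi:
        raise ValueError("year_lo must not exceed year_hi")
    members = {
        r.id
        for r in ped
        if r.birth_year is not None
        and not r.year_is_placeholder
        and year_lo <= r.birth_year <= year_hi
    }
    if not members:
        warnings.warn(f"no animals born between {year_lo} and {year_hi}")
        return ReferencePopulation(frozenset(), frozenset(), year_lo, year_hi)
    return ReferencePopulation(
        frozenset(members),
        frozenset(ancestor_closure(ped, members)),
        year_lo,
        year_hi,
    )


def assign_placeholder_years(
    ped: Pedigree, year: int = 1950, protect: Iterable[str] | None = None
) -> Pedigree:
    """Fill missing birth years with a placeholder, flagging them as such.

    ``protect`` ids (typically reference-population members) are left
    untouched. Flagged years are excluded from trend and generation-interval
    analyses downstream.
    """
    protect = set(protect or ())
    out = []
    flagged = []
    for rec in ped:
        if rec.birth_year is None and rec.id not in protect:
            out.append(replace(rec, birth_year=year, year_is_placeholder=True))
            flagged.append(rec.id)
        else:
            out.append(rec)
    new = Pedigree(out)
    if flagged:
        # sanity rule: a placeholder must not postdate any offspring's real year
        for rec in new:
            for parent in (rec.sire, rec.dam):
                if (
                    parent is not None
                    and new[parent].year_is_placeholder
                    and rec.birth_year is not None
                    and not rec.year_is_placeholder
                    and rec.birth_year < year
                ):
                    warnings.warn(
                        f"placeholder year {year} postdates offspring "
                        f"{rec.id!r} (born {rec.birth_year})"
                    )
                    break
            else:
                continue
            break
    return new
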