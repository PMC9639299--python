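"""Pedigree ingestion, validation and depth/completeness metrics.

A :class:`Pedigree` is an immutable, topologically ordered collection of
individual -> (sire, dam) records.  All downstream coefficient machinery
(classical inbreeding, gene dropping, gene-origin statistics) assumes the
invariants enforced here: unique ids, acyclic ancestry, every referenced
parent present as a record (unknown parents referenced by id are promoted
to founders), and parents stored before their offspring.

Generation depth is 1-based: parents sit at depth 1, grandparents at
depth 2, and so on.  Founders have depth metrics of zero.
"""

from __future__ import annotations

import csv
import logging
from collections import deque
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens interpreted as "parent unknown" in pedigree files
DEFAULT_MISSING_TOKENS = ("0", "", "NA")

_SEX_CODES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
}


class PedigreeError(ValueError):
    """Raised for structural problems: duplicate ids, cycles, bad rows."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: id, optional parents, optional birth year and sex."""

    id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    birth_year: Optional[int] = None
    sex: str = "unknown"

    def __post_init__(self):
        if not self.id:
            raise PedigreeError("empty individual id")
        if self.sire_id == self.id or self.dam_id == self.id:
            raise PedigreeError(f"individual {self.id!r} listed as its own parent")


@dataclass
class PedigreeDialect:
    """How to parse a delimited pedigree file.

    ``sep=None`` sniffs comma/tab/whitespace; ``header=None`` treats the
    first line as a header when it contains a recognised column name.
    Column order without a header is id, sire, dam[, birth_year[, sex]].
    """

    sep: Optional[str] = None
    header: Optional[bool] = None
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS


class Pedigree:
    """Validated, topologically ordered pedigree.

    Positions (integer indices into :attr:`records`) are the working
    currency of the numeric code; ``sire_pos``/``dam_pos`` hold the parent
    positions with ``-1`` for an unknown parent.
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records: tuple[PedigreeRecord, ...] = tuple(records)
        self._index = {r.id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            raise PedigreeError("duplicate ids in record list")
        n = len(self.records)
        self.sire_pos = np.full(n, -1, dtype=np.int64)
        self.dam_pos = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            for attr, arr in (("sire_id", self.sire_pos), ("dam_id", self.dam_pos)):
                pid = getattr(r, attr)
                if pid is not None:
                    j = self._index.get(pid)
                    if j is None:
                        raise PedigreeError(f"parent {pid!r} of {r.id!r} has no record")
                    if j >= i:
                        raise PedigreeError(
                            f"pedigree not topologically ordered: parent {pid!r} "
                            f"does not precede offspring {r.id!r}"
                        )
                    arr[i] = j

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[PedigreeRecord]) -> "Pedigree":
        """Validate, promote unknown referenced parents to founders, toposort."""
        recs = list(records)
        ids = [r.id for r in recs]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate id {i!r}")
            seen.add(i)
        # promote referenced-but-absent parents to founder records
        promoted = []
        for r in recs:
            for pid, psex in ((r.sire_id, "male"), (r.dam_id, "female")):
                if pid is not None and pid not in seen:
                    promoted.append(PedigreeRecord(id=pid, sex=psex))
                    seen.add(pid)
        recs = promoted + recs
        order = _toposort(recs)
        if promoted:
            logger.info("promoted %d referenced parents to founders", len(promoted))
        ped = cls([recs[i] for i in order])
        logger.info(
            "pedigree loaded: %d records, %d founders, %d promoted parents",
            len(ped), sum(ped.is_founder(r.id) for r in ped.records), len(promoted),
        )
        return ped

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, id: str) -> bool:
        return id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def position(self, id: str) -> int:
        try:
            return self._index[id]
        except KeyError:
            raise KeyError(f"unknown individual {id!r}") from None

    def record(self, id: str) -> PedigreeRecord:
        return self.records[self.position(id)]

    def is_founder(self, id: str) -> bool:
        p = self.position(id)
        return self.sire_pos[p] < 0 and self.dam_pos[p] < 0

    @property
    def founders(self) -> list[str]:
        return [r.id for i, r in enumerate(self.records)
                if self.sire_pos[i] < 0 and self.dam_pos[i] < 0]

    def parents(self, id: str) -> tuple[Optional[str], Optional[str]]:
        r = self.record(id)
        return r.sire_id, r.dam_id

    def ancestors(self, id: str, include_self: bool = False) -> set[str]:
        """All known ancestors of ``id`` (by id), optionally including itself."""
        start = self.position(id)
        seen: set[int] = set()
        stack = [start]
        while stack:
            p = stack.pop()
            for q in (self.sire_pos[p], self.dam_pos[p]):
                if q >= 0 and q not in seen:
                    seen.add(q)
                    stack.append(q)
        out = {self.records[i].id for i in seen}
        if include_self:
            out.add(self.records[start].id)
        return out

    # -- depth metrics -----------------------------------------------------

    def equivalent_generations(self, id: str) -> float:
        """Sum of (1/2)^n over every known ancestor slot of ``id``."""
        return float(self._equivalent_generations_all()[self.position(id)])

    def _equivalent_generations_all(self) -> np.ndarray:
        eq = np.zeros(len(self))
        for i in range(len(self)):
            for p in (self.sire_pos[i], self.dam_pos[i]):
                if p >= 0:
                    eq[i] += 0.5 * (1.0 + eq[p])
        return eq

    def generation_counts(self, id: str) -> tuple[int, int]:
        """(full, maximal) generations traced for ``id``.

        ``full`` is the deepest n with all 2^n ancestor slots known at
        every depth up to n; ``maximal`` is the longest known ancestral
        path.
        """
        pos = self.position(id)
        full = np.zeros(len(self), dtype=np.int64)
        mx = np.zeros(len(self), dtype=np.int64)
        for i in range(len(self)):
            s, d = self.sire_pos[i], self.dam_pos[i]
            if s >= 0 and d >= 0:
                full[i] = 1 + min(full[s], full[d])
            parents = [p for p in (s, d) if p >= 0]
            if parents:
                mx[i] = 1 + max(mx[p] for p in parents)
        return int(full[pos]), int(mx[pos])

    def completeness(self, id: str, max_depth: int) -> np.ndarray:
        """Fraction of known ancestor slots at each depth 1..max_depth."""
        if max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        pos = self.position(id)
        known = np.zeros((len(self), max_depth), dtype=np.float64)
        for i in range(len(self)):
            for p in (self.sire_pos[i], self.dam_pos[i]):
                if p >= 0:
                    known[i, 0] += 1
                    known[i, 1:] += known[p, :-1]
        return known[pos] / (2.0 ** np.arange(1, max_depth + 1))

    # -- ancestry surgery ----------------------------------------------------

    def truncate_to_depth(self, id: str, g: int) -> "Pedigree":
        """Ancestor-restricted pedigree of ``id`` cut at depth ``g``.

        Every ancestor whose minimal generation distance from ``id``
        equals ``g`` becomes a founder (its parents dropped); deeper
        ancestors reachable only through depth-g individuals disappear.
        """
        if g < 1:
            raise ValueError("g must be >= 1")
        start = self.position(id)
        depth = {start: 0}
        q = deque([start])
        while q:
            i = q.popleft()
            if depth[i] >= g:
                continue
            for p in (self.sire_pos[i], self.dam_pos[i]):
                if p >= 0 and (p not in depth or depth[p] > depth[i] + 1):
                    depth[p] = depth[i] + 1
                    q.append(p)
        kept = set(depth)
        new_records = []
        for i in sorted(kept):  # original order is topological
            r = self.records[i]
            if depth[i] >= g:
                r = replace(r, sire_id=None, dam_id=None)
            else:
                sid = r.sire_id if self.sire_pos[i] in kept else None
                did = r.dam_id if self.dam_pos[i] in kept else None
                r = replace(r, sire_id=sid, dam_id=did)
            new_records.append(r)
        return Pedigree(new_records)

    def common_ancestors(self, id: str) -> int:
        """Count of individuals in both the sire-side and dam-side ancestry.

        Each side includes the parent itself.  An individual with a
        missing parent has, by convention, zero common ancestors.
        """
        sire, dam = self.parents(id)
        if sire is None or dam is None:
            return 0
        side_s = self.ancestors(sire, include_self=True)
        side_d = self.ancestors(dam, include_self=True)
        return len(side_s & side_d)

    # -- cohort helpers ------------------------------------------------------

    def generational_intervals(self, width: int = 10) -> pd.Series:
        """Bin individuals by birth year (inclusive lower bound).

        Returns a Series mapping id -> interval start year (NaN when the
        birth year is unknown).  The default 10-year width mirrors the
        studbook convention of one generational interval per decade.
        """
        years = pd.Series(
            [r.birth_year for r in self.records],
            index=self.ids, dtype="float64",
        )
        return (years // width) * width


def _toposort(records: Sequence[PedigreeRecord]) -> list[int]:
    """Kahn topological sort; raises PedigreeError naming a cycle member."""
    index = {r.id: i for i, r in enumerate(records)}
    n = len(records)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i, r in enumerate(records):
        for pid in (r.sire_id, r.dam_id):
            if pid is not None:
                children[index[pid]].append(i)
                indeg[i] += 1
    queue = deque(i for i in range(n) if indeg[i] == 0)
    order = []
    while queue:
        i = queue.popleft()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        on_cycle = min(records[i].id for i in range(n) if indeg[i] > 0)
        raise PedigreeError(f"ancestry cycle detected involving {on_cycle!r}")
    return order


def load_pedigree(path, dialect: Optional[PedigreeDialect] = None) -> Pedigree:
    """Read a delimited pedigree file into a validated :class:`Pedigree`.

    Expected columns: id, sire, dam and optionally birth_year and sex,
    either positional or named in a header line.  Missing-parent tokens
    default to ``{"0", "", "NA"}``.
    """
    dialect = dialect or PedigreeDialect()
    missing = set(dialect.missing_tokens)
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise PedigreeError(f"{path}: empty pedigree file")
    sep = dialect.sep
    if sep is None:
        first = text[0]
        sep = "," if "," in first else ("\t" if "\t" in first else None)

    def split(line: str) -> list[str]:
        if sep is None:
            return line.split()
        return next(csv.reader([line], delimiter=sep))

    known_names = {"id", "animal", "sire", "dam", "birth_year", "year", "sex"}
    rows = [line for line in text if line.strip()]
    fields0 = [f.strip().lower() for f in split(rows[0])]
    has_header = dialect.header
    if has_header is None:
        has_header = bool(known_names & set(fields0))
    colmap: Mapping[str, int]
    if has_header:
        names = fields0
        def find(*cands):
            for c in cands:
                if c in names:
                    return names.index(c)
            return None
        colmap = {
            "id": find("id", "animal"),
            "sire": find("sire", "sire_id"),
            "dam": find("dam", "dam_id"),
            "birth_year": find("birth_year", "year"),
            "sex": find("sex"),
        }
        if colmap["id"] is None or colmap["sire"] is None or colmap["dam"] is None:
            raise PedigreeError(f"{path}: header must name id, sire and dam columns")
        body = rows[1:]
        offset = 2
    else:
        colmap = {"id": 0, "sire": 1, "dam": 2, "birth_year": 3, "sex": 4}
        body = rows
        offset = 1

    records = []
    for lineno, line in enumerate(body, start=offset):
        fields = [f.strip() for f in split(line)]
        try:
            def get(key):
                c = colmap.get(key)
                if c is None or c >= len(fields):
                    return None
                return fields[c]
            id_ = get("id")
            if id_ is None or id_ in missing:
                raise PedigreeError("missing individual id")
            sire = get("sire")
            dam = get("dam")
            sire = None if (sire is None or sire in missing) else sire
            dam = None if (dam is None or dam in missing) else dam
            by_raw = get("birth_year")
            by = None if (by_raw is None or by_raw in missing) else int(by_raw)
            sex_raw = get("sex")
            sex = _SEX_CODES.get((sex_raw or "").lower(), "unknown")
            records.append(PedigreeRecord(id_, sire, dam, by, sex))
        except (PedigreeError, ValueError) as exc:
            raise PedigreeError(f"{path}: line {lineno}: {exc}") from exc
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path, sep: str = ",") -> None:
    """Write a pedigree as delimited text with a header."""
    with open(path, "w") as fh:
        fh.write(sep.join(["id", "sire", "dam", "birth_year", "sex"]) + "\n")
        for r in ped.records:
            fh.write(sep.join([
                r.id,
                r.sire_id or "0",
                r.dam_id or "0",
                "" if r.birth_year is None else str(r.birth_year),
                r.sex,
            ]) + "\n")
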