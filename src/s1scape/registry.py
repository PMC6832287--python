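"""Domain registry: which PDB entry / chain / residue range belongs to which kingdom.

The registry file is plain text, tab-separated, one record per line::

    pdb_id  chain  start  end  kingdom  protein_name  [group]

``#`` starts a comment; blank lines are ignored.  ``group`` is an optional
label marking records that describe the same protein solved in different
organisms or depositions; pairs sharing a group are excluded when identity
extrema are reported.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

KINGDOMS = ("bacteria", "eukaryota", "archaea")

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


class RegistryError(ValueError):
    """Raised for malformed or inconsistent registry input."""


@dataclass(frozen=True)
class DomainRecord:
    """One registry row: a domain slice of a PDB chain."""

    pdb_id: str
    chain_id: str
    start_res: int
    end_res: int
    kingdom: str
    protein_name: str
    same_protein_group: str | None = None

    def __post_init__(self) -> None:
        if not _PDB_ID_RE.match(self.pdb_id):
            raise RegistryError(f"invalid PDB id {self.pdb_id!r}")
        if self.kingdom not in KINGDOMS:
            raise RegistryError(
                f"kingdom must be one of {KINGDOMS}, got {self.kingdom!r}"
            )
        if self.start_res > self.end_res:
            raise RegistryError(
                f"{self.pdb_id}: start_res {self.start_res} > end_res {self.end_res}"
            )
        if len(self.chain_id) != 1:
            raise RegistryError(f"{self.pdb_id}: chain id must be one character")

    @property
    def label(self) -> str:
        """Short unique label used in matrices and trees."""
        return f"{self.pdb_id.lower()}_{self.chain_id}"

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.pdb_id.lower(), self.chain_id, self.start_res, self.end_res)


@dataclass
class Registry:
    """Ordered, validated collection of :class:`DomainRecord`."""

    records: list[DomainRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for rec in self.records:
            if rec.key in seen:
                raise RegistryError(f"duplicate record {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def kingdom_counts(self) -> dict[str, int]:
        counts = Counter(r.kingdom for r in self.records)
        return {k: counts.get(k, 0) for k in KINGDOMS}

    def by_label(self, label: str) -> DomainRecord:
        for rec in self.records:
            if rec.label == label:
                return rec
        raise KeyError(label)

    def group_of(self) -> dict[str, str | None]:
        """Label -> same-protein group (None when ungrouped)."""
        return {r.label: r.same_protein_group for r in self.records}


def _parse_line(line: str, lineno: int) -> DomainRecord:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 6:
        raise RegistryError(
            f"line {lineno}: expected at least 6 fields "
            f"(pdb_id chain start end kingdom protein_name [group]), got {len(fields)}"
        )
    pdb_id, chain, start, end, kingdom = fields[:5]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise RegistryError(f"line {lineno}: non-integer residue range") from exc
    group = None
    if len(fields) >= 7 and fields[6].strip() not in ("", "-", "."):
        group = fields[6].strip()
    try:
        return DomainRecord(
            pdb_id=pdb_id.lower(),
            chain_id=chain,
            start_res=start_i,
            end_res=end_i,
            kingdom=kingdom.lower(),
            protein_name=fields[5],
            same_protein_group=group,
        )
    except RegistryError as exc:
        raise RegistryError(f"line {lineno}: {exc}") from exc


def load_registry(path: str | Path) -> Registry:
    """Load and validate a registry file.

    Raises :class:`RegistryError` naming the offending line for malformed
    input, and for an empty file.
    """
    path = Path(path)
    records: list[DomainRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            records.append(_parse_line(line, lineno))
    if not records:
        raise RegistryError(f"{path}: no records")
    return Registry(records)


def write_registry(reg: Registry, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# pdb_id\tchain\tstart\tend\tkingdom\tprotein_name\tgroup\n")
        for r in reg:
            fh.write(
                "\t".join(
                    [
                        r.pdb_id,
                        r.chain_id,
                        str(r.start_res),
                        str(r.end_res),
                        r.kingdom,
                        r.protein_name,
                        r.same_protein_group or "-",
                    ]
                )
                + "\n"
            )


def kingdom_partition(reg: Registry) -> dict[str, list[DomainRecord]]:
    """Partition records by kingdom; exhaustive and disjoint by construction."""
    parts: dict[str, list[DomainRecord]] = {k: [] for k in KINGDOMS}
    for rec in reg:
        parts[rec.kingdom].append(rec)
    return {k: v for k, v in parts.items() if v}


def default_registry() -> Registry:
    """The bundled 24-entry S1-domain registry (9 bacterial / 10 eukaryotic / 5 archaeal)."""
    ref = resources.files("s1scape").joinpath("data/registry.tsv")
    with resources.as_file(ref) as p:
        return load_registry(p)


def records_from_iterable(rows: Iterable[tuple]) -> Registry:
    """Build a registry from (pdb, chain, start, end, kingdom, name[, group]) tuples."""
    return Registry([DomainRecord(*row) for row in rows])
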