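"""Repeat annotation parsing and family grouping.

Repeat instances come from the RepeatMasker annotation of a genome build,
either as the UCSC genome browser ``rmsk`` table dump (tab-separated,
0-based half-open ``genoStart``/``genoEnd``) or as native RepeatMasker
``.out`` files (whitespace-aligned, 1-based inclusive coordinates, three
header lines).  Internally every interval is 0-based half-open; conversion
happens only at the parse/write boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class AnnotationParseError(ValueError):
    """A malformed annotation row; carries the 1-based line number."""


class FamilyNotFoundError(KeyError):
    """A requested repeat family is absent from the catalog."""


@dataclass(frozen=True)
class RepeatInstance:
    """One annotated genomic copy of a repeat element.

    Coordinates are 0-based half-open (``start`` inclusive, ``end``
    exclusive), matching the UCSC table convention.
    """

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    repclass: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.family:
            raise ValueError("family name must be non-empty")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RepeatCatalog:
    """Ordered collection of repeat instances with a genome-build label."""

    instances: list[RepeatInstance] = field(default_factory=list)
    genome_build: str = ""

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def families(self) -> list[str]:
        """Distinct repName-level family labels in first-seen order."""
        seen: dict[str, None] = {}
        for inst in self.instances:
            seen.setdefault(inst.family, None)
        return list(seen)


# UCSC rmsk table columns (17); we populate the six we model and write
# neutral placeholders for the rest so files round-trip through this dialect.
_RMSK_COLUMNS = [
    "bin", "swScore", "milliDiv", "milliDel", "milliIns", "genoName",
    "genoStart", "genoEnd", "genoLeft", "strand", "repName", "repClass",
    "repFamily", "repStart", "repEnd", "repLeft", "id",
]


def _parse_rmsk_row(fields: Sequence[str], lineno: int) -> RepeatInstance:
    if len(fields) < 17:
        raise AnnotationParseError(
            f"line {lineno}: expected 17 tab-separated rmsk columns, got {len(fields)}"
        )
    try:
        return RepeatInstance(
            chrom=fields[5],
            start=int(fields[6]),
            end=int(fields[7]),
            strand=fields[9],
            family=fields[10],
            repclass=fields[11],
        )
    except (ValueError, IndexError) as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


def _parse_out_row(fields: Sequence[str], lineno: int) -> RepeatInstance:
    # score div del ins query qbegin qend qleft strand repName repClass/Family ...
    if len(fields) < 11:
        raise AnnotationParseError(
            f"line {lineno}: expected >=11 whitespace-separated .out columns, "
            f"got {len(fields)}"
        )
    try:
        begin = int(fields[5])  # 1-based inclusive
        end = int(fields[6])
        strand = "-" if fields[8] == "C" else fields[8]
        cls = fields[10]
        if "/" in cls:
            cls = cls.split("/", 1)[0]
        return RepeatInstance(
            chrom=fields[4],
            start=begin - 1,
            end=end,
            strand=strand,
            family=fields[9],
            repclass=cls,
        )
    except (ValueError, IndexError) as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


def parse_repeat_annotation(
    path: str | Path, dialect: str = "rmsk_table", genome_build: str = ""
) -> RepeatCatalog:
    """Parse a repeat annotation file into a :class:`RepeatCatalog`.

    Parameters
    ----------
    path
        Annotation file.
    dialect
        ``"rmsk_table"`` for the UCSC tab-separated rmsk dump (0-based
        half-open coordinates, ``#``-prefixed header allowed) or
        ``"rm_out"`` for RepeatMasker ``.out`` (1-based inclusive
        coordinates, three header lines, ``C`` for the minus strand).
    genome_build
        Free-text label stored on the catalog.

    Row order is preserved.  Malformed rows raise
    :class:`AnnotationParseError` naming the line number.
    """
    path = Path(path)
    if dialect not in ("rmsk_table", "rm_out"):
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    instances: list[RepeatInstance] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "rm_out":
        # RepeatMasker .out: two header lines + one blank line precede data.
        body = list(enumerate(lines, start=1))[3:]
        for lineno, line in body:
            if not line.strip():
                continue
            instances.append(_parse_out_row(line.split(), lineno))
    else:
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            instances.append(_parse_rmsk_row(line.rstrip("\n").split("\t"), lineno))
    return RepeatCatalog(instances=instances, genome_build=genome_build)


def write_rmsk_table(catalog: RepeatCatalog, path: str | Path) -> None:
    """Write a catalog in the UCSC rmsk table dialect (round-trips exactly)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_RMSK_COLUMNS) + "\n")
        for inst in catalog:
            row = [
                "0", "0", "0", "0", "0",
                inst.chrom, str(inst.start), str(inst.end), "0",
                inst.strand, inst.family, inst.repclass or "Unknown",
                inst.repclass or "Unknown", "0", "0", "0", "0",
            ]
            fh.write("\t".join(row) + "\n")


def group_by_family(
    catalog: RepeatCatalog,
    families: Iterable[str] | None = None,
    level: str = "name",
) -> dict[str, list[RepeatInstance]]:
    """Group catalog instances by repeat family.

    ``level="name"`` groups on repName (the default unit for satellites);
    ``level="class"`` groups on repClass, the coarser unit used for LINE
    and SINE categories.  Within each family, instances are returned in
    genomic order (chrom, start).  Requesting an absent family raises
    :class:`FamilyNotFoundError` rather than returning a silent empty group.
    """
    if level not in ("name", "class"):
        raise ValueError(f"unknown grouping level: {level!r}")
    key = (lambda i: i.family) if level == "name" else (lambda i: i.repclass)
    groups: dict[str, list[RepeatInstance]] = {}
    for inst in catalog:
        groups.setdefault(key(inst), []).append(inst)
    for name in groups:
        groups[name].sort(key=lambda i: (i.chrom, i.start, i.end))
    if families is None:
        return groups
    wanted = list(families)
    missing = [f for f in wanted if f not in groups]
    if missing:
        raise FamilyNotFoundError(
            f"family not found in catalog: {', '.join(missing)}"
        )
    return {f: groups[f] for f in wanted}
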