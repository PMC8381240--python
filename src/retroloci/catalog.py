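"""Retroelement locus catalogs: parsing, validation, and interval export.

A catalog row describes one endogenous retrovirus (ERV) or LINE-1 locus as a
set of gene segments (gag/pol/env for ERVs, ORF1/ORF2 for LINE-1) given as
1-based inclusive chromosomal intervals with an explicit strand, the display
convention used by gEVE-style locus tables.  Internally every coordinate stays
1-based inclusive; BED export shifts to the 0-based half-open convention.

The packaged fixture ``data/table1_loci.tsv`` carries the catalog of mouse
(GRCm38) ERV and LINE-1 loci used throughout the test-suite and examples.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneSegment",
    "RetroelementLocus",
    "CatalogIssue",
    "CatalogError",
    "ERV_ROLES",
    "LINE1_ROLES",
    "parse_locus_table",
    "load_table1_catalog",
    "locus_footprint",
    "export_bed",
    "parse_bed",
    "validate_catalog",
    "lookup",
]

ERV_ROLES = ("gag", "pol", "env")
LINE1_ROLES = ("ORF1", "ORF2")
_ALL_ROLES = ERV_ROLES + LINE1_ROLES

#: Accepted strand glyphs; the unicode minus appears in display-formatted tables.
_STRAND_NORMALIZE = {"+": "+", "-": "-", "−": "-"}

_COORD_RE = re.compile(
    r"^\s*(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)\s*"
    r"\(\s*(?P<strand>[+\-−])\s*\)\s*$"
)


class CatalogError(ValueError):
    """Raised for malformed catalog input (bad coordinate cell, duplicate name)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        norm = _STRAND_NORMALIZE.get(self.strand)
        if norm is None:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "strand", norm)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneSegment:
    """One annotated gene of a locus (gag/pol/env or ORF1/ORF2)."""

    role: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.role not in _ALL_ROLES:
            raise ValueError(f"unknown segment role {self.role!r}")


@dataclass(frozen=True)
class RetroelementLocus:
    """A named ERV or LINE-1 locus.

    Construction enforces the structural invariants that make a locus usable
    at all (at least one segment, a single chromosome and strand).  Role
    uniqueness and class/role compatibility are checked by
    :func:`validate_catalog`, which reports them as :class:`CatalogIssue`
    errors instead of raising, so that defective rows can be surfaced in bulk.
    """

    name: str
    element_class: str
    segments: tuple[GeneSegment, ...]
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.element_class not in ("ERV", "LINE1"):
            raise ValueError(f"element_class must be ERV or LINE1, got {self.element_class!r}")
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "aliases", tuple(self.aliases))
        if not segments:
            raise ValueError(f"locus {self.name!r} has no segments")
        chroms = {s.interval.chrom for s in segments}
        strands = {s.interval.strand for s in segments}
        if len(chroms) > 1:
            raise ValueError(f"locus {self.name!r} spans multiple chromosomes: {sorted(chroms)}")
        if len(strands) > 1:
            raise ValueError(f"locus {self.name!r} mixes strands")

    @property
    def chrom(self) -> str:
        return self.segments[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.segments[0].interval.strand

    def segment(self, role: str) -> GeneSegment | None:
        for seg in self.segments:
            if seg.role == role:
                return seg
        return None


@dataclass(frozen=True)
class CatalogIssue:
    locus_name: str
    severity: str  # "warning" | "error"
    message: str

    def __post_init__(self) -> None:
        if self.severity not in ("warning", "error"):
            raise ValueError(f"severity must be warning or error, got {self.severity!r}")


def _parse_coord_cell(cell: str, *, row_label: str, column: str) -> GenomicInterval:
    m = _COORD_RE.match(cell)
    if m is None:
        raise CatalogError(
            f"row {row_label!r}, column {column!r}: malformed coordinate cell {cell!r} "
            "(expected 'chrom:start-end (strand)')"
        )
    return GenomicInterval(
        chrom=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        strand=m.group("strand"),
    )


def parse_locus_table(table_text: str, dialect: str = "table1-fixture") -> list[RetroelementLocus]:
    """Parse a tab-separated locus table into :class:`RetroelementLocus` records.

    Two dialects are supported:

    ``table1-fixture``
        Wide format, one row per locus.  Header columns: ``name``, ``class``,
        then one column per gene role (``gag``, ``pol``, ``env``, ``ORF1``,
        ``ORF2``) holding ``chrom:start-end (strand)`` or empty, then an
        optional ``aliases`` column (comma-separated).  Trailing empty cells
        may be omitted.

    ``gEVE``
        Long format, one row per gene segment.  Header columns: ``name``,
        ``class``, ``role``, ``chrom``, ``start``, ``end``, ``strand``,
        optional ``aliases`` (repeated per row; the union is kept).

    Raises :class:`CatalogError` on malformed coordinate cells (naming the row
    and column) and on duplicate locus names.
    """
    if dialect == "table1-fixture":
        loci = _parse_wide(table_text)
    elif dialect in ("gEVE", "geve"):
        loci = _parse_long(table_text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    seen: set[str] = set()
    for locus in loci:
        if locus.name in seen:
            raise CatalogError(f"duplicate locus name {locus.name!r}")
        seen.add(locus.name)
    return loci


def _split_rows(table_text: str) -> tuple[list[str], list[list[str]]]:
    reader = csv.reader(io.StringIO(table_text), delimiter="\t")
    rows = [row for row in reader if any(cell.strip() for cell in row)]
    if not rows:
        raise CatalogError("empty table: header row required")
    header = [h.strip() for h in rows[0]]
    return header, rows[1:]


def _parse_wide(table_text: str) -> list[RetroelementLocus]:
    header, rows = _split_rows(table_text)
    try:
        name_i = header.index("name")
        class_i = header.index("class")
    except ValueError as exc:
        raise CatalogError("fixture dialect requires 'name' and 'class' columns") from exc
    role_cols = [(role, header.index(role)) for role in _ALL_ROLES if role in header]
    alias_i = header.index("aliases") if "aliases" in header else None

    loci: list[RetroelementLocus] = []
    for row in rows:
        row = row + [""] * (len(header) - len(row))  # tolerate omitted trailing cells
        name = row[name_i].strip()
        element_class = row[class_i].strip()
        segments = []
        for role, idx in role_cols:
            cell = row[idx].strip()
            if not cell:
                continue
            interval = _parse_coord_cell(cell, row_label=name or f"#{len(loci) + 2}", column=role)
            segments.append(GeneSegment(role=role, interval=interval))
        aliases: tuple[str, ...] = ()
        if alias_i is not None and row[alias_i].strip():
            aliases = tuple(a.strip() for a in row[alias_i].split(",") if a.strip())
        loci.append(
            RetroelementLocus(
                name=name, element_class=element_class, segments=tuple(segments), aliases=aliases
            )
        )
    return loci


def _parse_long(table_text: str) -> list[RetroelementLocus]:
    header, rows = _split_rows(table_text)
    required = ("name", "class", "role", "chrom", "start", "end", "strand")
    try:
        idx = {col: header.index(col) for col in required}
    except ValueError as exc:
        raise CatalogError(f"gEVE dialect requires columns {required}") from exc
    alias_i = header.index("aliases") if "aliases" in header else None

    order: list[str] = []
    by_name: dict[str, dict] = {}
    for n, row in enumerate(rows, start=2):
        row = row + [""] * (len(header) - len(row))
        name = row[idx["name"]].strip()
        try:
            interval = GenomicInterval(
                chrom=row[idx["chrom"]].strip(),
                start=int(row[idx["start"]]),
                end=int(row[idx["end"]]),
                strand=row[idx["strand"]].strip(),
            )
        except ValueError as exc:
            raise CatalogError(f"row {n} ({name!r}): {exc}") from exc
        entry = by_name.setdefault(
            name, {"class": row[idx["class"]].strip(), "segments": [], "aliases": []}
        )
        if name not in order:
            order.append(name)
        entry["segments"].append(GeneSegment(role=row[idx["role"]].strip(), interval=interval))
        if alias_i is not None and row[alias_i].strip():
            for a in row[alias_i].split(","):
                if a.strip() and a.strip() not in entry["aliases"]:
                    entry["aliases"].append(a.strip())
    return [
        RetroelementLocus(
            name=name,
            element_class=by_name[name]["class"],
            segments=tuple(by_name[name]["segments"]),
            aliases=tuple(by_name[name]["aliases"]),
        )
        for name in order
    ]


def load_table1_catalog() -> list[RetroelementLocus]:
    """Load the packaged GRCm38 ERV/LINE-1 locus catalog fixture."""
    text = resources.files("retroloci").joinpath("data/table1_loci.tsv").read_text()
    return parse_locus_table(text, dialect="table1-fixture")


def locus_footprint(locus: RetroelementLocus) -> GenomicInterval:
    """The genomic span from the minimum segment start to the maximum segment end.

    This footprint is the unit of read counting downstream.
    """
    return GenomicInterval(
        chrom=locus.chrom,
        start=min(s.interval.start for s in locus.segments),
        end=max(s.interval.end for s in locus.segments),
        strand=locus.strand,
    )


def export_bed(loci: Iterable[RetroelementLocus]) -> str:
    """Render locus footprints as BED6 text (0-based half-open)."""
    lines = []
    for locus in loci:
        fp = locus_footprint(locus)
        lines.append(f"{fp.chrom}\t{fp.start - 1}\t{fp.end}\t{locus.name}\t0\t{fp.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def parse_bed(bed_text: str) -> dict[str, GenomicInterval]:
    """Read BED6 text back into 1-based inclusive intervals keyed by name."""
    out: dict[str, GenomicInterval] = {}
    for n, line in enumerate(bed_text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise CatalogError(f"BED line {n}: expected 6 columns, got {len(fields)}")
        chrom, start0, end, name, _score, strand = fields[:6]
        out[name] = GenomicInterval(chrom=chrom, start=int(start0) + 1, end=int(end), strand=strand)
    return out


_CLASS_ROLES = {"ERV": set(ERV_ROLES), "LINE1": set(LINE1_ROLES)}

#: Roles whose absence in a locus is only noteworthy, not fatal — the packaged
#: catalog itself contains pol-only ERVs and ORF2-only LINE-1 rows.
_FULL_COMPLEMENT = {"ERV": ("gag", "pol", "env"), "LINE1": ("ORF1", "ORF2")}


def validate_catalog(loci: Sequence[RetroelementLocus]) -> list[CatalogIssue]:
    """Check a catalog and return issues (never raises).

    Errors: duplicate locus names, duplicate roles within a locus, roles
    incompatible with the element class, alias collisions.  Warnings: loci
    missing part of their class's gene complement (partial/pol-only loci).
    """
    issues: list[CatalogIssue] = []
    seen_names: set[str] = set()
    key_owner: dict[str, str] = {}
    for locus in loci:
        if locus.name in seen_names:
            issues.append(CatalogIssue(locus.name, "error", "duplicate locus name"))
        seen_names.add(locus.name)
        for key in (locus.name, *locus.aliases):
            owner = key_owner.get(key)
            if owner is not None and owner != locus.name:
                issues.append(
                    CatalogIssue(
                        locus.name, "error", f"key {key!r} collides with locus {owner!r}"
                    )
                )
            key_owner.setdefault(key, locus.name)

        roles = [s.role for s in locus.segments]
        for role in set(roles):
            if roles.count(role) > 1:
                issues.append(
                    CatalogIssue(locus.name, "error", f"role {role!r} annotated more than once")
                )
        allowed = _CLASS_ROLES.get(locus.element_class, set())
        for role in roles:
            if role not in allowed:
                issues.append(
                    CatalogIssue(
                        locus.name,
                        "error",
                        f"role {role!r} not allowed for class {locus.element_class}",
                    )
                )
        missing = [r for r in _FULL_COMPLEMENT.get(locus.element_class, ()) if r not in roles]
        if missing and not any(i.locus_name == locus.name and i.severity == "error" for i in issues):
            issues.append(
                CatalogIssue(
                    locus.name, "warning", f"partial locus: missing {', '.join(missing)}"
                )
            )
    return issues


def lookup(loci: Sequence[RetroelementLocus], key: str) -> RetroelementLocus:
    """Resolve a locus by primary name or alias; the match must be unique."""
    matches = [l for l in loci if l.name == key or key in l.aliases]
    if not matches:
        raise KeyError(f"no locus named or aliased {key!r}")
    if len(matches) > 1:
        raise KeyError(f"key {key!r} is ambiguous across {[m.name for m in matches]}")
    return matches[0]
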