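"""Read counting per retroelement locus under strict multimapper exclusion.

The counting contract mirrors a stringent-mapping locus-expression workflow:
reads reported at more than ``max_loci`` genomic locations (SAM ``NH`` tag)
are treated as unmapped and removed entirely; surviving reads are assigned to
locus footprints by alignment-block overlap.  Under the default
``best-overlap`` policy a read counts toward the single locus with the
greatest total overlap (ties to the lexicographically smallest locus name);
``any-overlap`` credits every overlapped locus.  Mates sharing a read id are
counted as one fragment.  Counts are raw; :func:`cpm_normalize` is a
reporting aid only.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .catalog import RetroelementLocus, locus_footprint

__all__ = [
    "AlignmentRecord",
    "CountMatrix",
    "SamParseError",
    "read_alignments",
    "filter_multimappers",
    "count_by_locus",
    "build_count_matrix",
    "cpm_normalize",
]

# CIGAR op codes: these consume reference within one gapless-ish block
_REF_BLOCK_OPS = {0, 7, 8, 2}  # M, =, X, D
_REF_SKIP_OP = 3  # N


class SamParseError(ValueError):
    """A SAM record could not be parsed; carries the approximate line number."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment line, reduced to what counting needs.

    ``aligned_blocks`` are 1-based inclusive reference intervals derived from
    the CIGAR: M/=/X/D runs merge into one block, N splits blocks.  ``nh`` is
    the reported number of alignment loci for the read (1 when the tag is
    absent, per SAM semantics).
    """

    read_id: str
    chrom: str | None
    pos: int
    aligned_blocks: tuple[tuple[int, int], ...]
    nh: int
    mapped: bool
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "aligned_blocks", tuple(map(tuple, self.aligned_blocks)))
        if self.nh < 1:
            raise ValueError(f"nh must be >= 1, got {self.nh}")
        prev_end = 0
        for start, end in self.aligned_blocks:
            if start <= prev_end:
                raise ValueError("aligned blocks must be sorted and non-overlapping")
            if end < start:
                raise ValueError(f"block end {end} < start {start}")
            prev_end = end


@dataclass
class CountMatrix:
    """Loci x samples integer counts plus per-sample retained-read totals."""

    counts: pd.DataFrame
    library_size: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.library_size.index):
            raise ValueError("count columns and library_size index disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        over = self.counts.gt(self.library_size, axis=1)
        if over.to_numpy().any():
            raise ValueError("a count exceeds its sample's library size")


def _blocks_from_cigartuples(
    cigartuples: Sequence[tuple[int, int]], reference_start: int
) -> tuple[tuple[int, int], ...]:
    """1-based inclusive reference blocks: M/=/X/D merged, split at N."""
    blocks: list[tuple[int, int]] = []
    cur_start = reference_start  # 0-based
    cur_end = reference_start
    for op, length in cigartuples:
        if op in _REF_BLOCK_OPS:
            cur_end += length
        elif op == _REF_SKIP_OP:
            if cur_end > cur_start:
                blocks.append((cur_start + 1, cur_end))
            cur_start = cur_end + length
            cur_end = cur_start
        # I, S, H, P consume no reference
    if cur_end > cur_start:
        blocks.append((cur_start + 1, cur_end))
    return tuple(blocks)


def read_alignments(source: str | Path) -> list[AlignmentRecord]:
    """Parse SAM (path or literal text) into :class:`AlignmentRecord` objects.

    Supports the mandatory 11 fields, CIGAR ops M/=/X/I/D/N/S/H, and the
    optional ``NH:i`` tag.  Unmapped-flag records yield ``mapped=False``.
    """
    if isinstance(source, str) and "\n" in source:
        with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
            fh.write(source)
            path = Path(fh.name)
        try:
            return _read_sam_file(path, text=source)
        finally:
            path.unlink(missing_ok=True)
    return _read_sam_file(Path(source))


def _read_sam_file(path: Path, text: str | None = None) -> list[AlignmentRecord]:
    if text is None:
        text = path.read_text()
    n_header = sum(1 for line in text.splitlines() if line.startswith("@"))
    records: list[AlignmentRecord] = []
    try:
        samfile = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise SamParseError(f"unreadable SAM header: {exc}") from exc
    with samfile:
        iterator = iter(samfile)
        index = 0
        while True:
            try:
                aln = next(iterator)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise SamParseError(f"malformed SAM record at line {n_header + index + 1}: {exc}") from exc
            index += 1
            nh = int(aln.get_tag("NH")) if aln.has_tag("NH") else 1
            if aln.is_unmapped:
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        chrom=None,
                        pos=0,
                        aligned_blocks=(),
                        nh=max(nh, 1),
                        mapped=False,
                    )
                )
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    pos=aln.reference_start + 1,
                    aligned_blocks=_blocks_from_cigartuples(
                        aln.cigartuples or (), aln.reference_start
                    ),
                    nh=max(nh, 1),
                    mapped=True,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return records


def filter_multimappers(
    records: Iterable[AlignmentRecord], max_loci: int = 2
) -> list[AlignmentRecord]:
    """Drop unmapped records and *all* records of reads with nh > max_loci.

    This is the strict exclusion rule: an over-multimapped read is considered
    unmapped everywhere, not redistributed.
    """
    records = [r for r in records if r.mapped]
    max_nh: dict[str, int] = {}
    for r in records:
        max_nh[r.read_id] = max(max_nh.get(r.read_id, 1), r.nh)
    return [r for r in records if max_nh[r.read_id] <= max_loci]


def _footprint_trees(
    loci: Sequence[RetroelementLocus],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for locus in loci:
        fp = locus_footprint(locus)
        # interval tree is 0-based half-open
        trees.setdefault(fp.chrom, IntervalTree()).addi(
            fp.start - 1, fp.end, (locus.name, fp.strand)
        )
    return trees


def count_by_locus(
    records: Sequence[AlignmentRecord],
    loci: Sequence[RetroelementLocus],
    assignment: str = "best-overlap",
    stranded: bool = False,
) -> tuple[pd.Series, int]:
    """Count fragments per locus footprint; returns (counts, library size).

    ``records`` must already be multimapper-filtered.  A read contributes when
    any aligned block overlaps a footprint by >= 1 bp; overlap is totalled
    over all records sharing the read id (mates/multi-placements).  Library
    size is the number of distinct retained reads.
    """
    if assignment not in ("best-overlap", "any-overlap"):
        raise ValueError(f"unknown assignment policy {assignment!r}")
    trees = _footprint_trees(loci)
    names = [locus.name for locus in loci]
    counts = pd.Series(0, index=pd.Index(names, name="locus"), dtype=int)

    by_read: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        if r.mapped:
            by_read.setdefault(r.read_id, []).append(r)

    for read_records in by_read.values():
        overlap: dict[str, int] = {}
        for r in read_records:
            tree = trees.get(r.chrom)
            if tree is None:
                continue
            for start, end in r.aligned_blocks:
                for iv in tree.overlap(start - 1, end):
                    name, strand = iv.data
                    if stranded and strand != r.strand:
                        continue
                    ov = min(end, iv.end) - max(start - 1, iv.begin)
                    overlap[name] = overlap.get(name, 0) + ov
        if not overlap:
            continue
        if assignment == "any-overlap":
            for name in overlap:
                counts[name] += 1
        else:
            best = max(overlap.values())
            winner = min(name for name, ov in overlap.items() if ov == best)
            counts[winner] += 1
    return counts, len(by_read)


def build_count_matrix(
    sam_sources: Mapping[str, str | Path],
    loci: Sequence[RetroelementLocus],
    max_loci: int = 2,
    assignment: str = "best-overlap",
    stranded: bool = False,
) -> CountMatrix:
    """Run parse -> multimapper filter -> count for each sample SAM."""
    columns: dict[str, pd.Series] = {}
    sizes: dict[str, int] = {}
    for sample, source in sam_sources.items():
        records = filter_multimappers(read_alignments(source), max_loci=max_loci)
        col, libsize = count_by_locus(records, loci, assignment=assignment, stranded=stranded)
        columns[sample] = col
        sizes[sample] = libsize
    counts = pd.DataFrame(columns)
    return CountMatrix(counts=counts, library_size=pd.Series(sizes)[counts.columns])


def cpm_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million retained reads."""
    if (matrix.library_size <= 0).any():
        raise ValueError("library sizes must be positive for CPM")
    return matrix.counts * 1e6 / matrix.library_size
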