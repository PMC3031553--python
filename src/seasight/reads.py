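"""Mapped-read import (SAM/BAM/tabular) and sparse per-base coverage.

SAM/BAM parsing is delegated to pysam; the reference span of a read is the
sum of M/D/N/=/X CIGAR lengths, so spliced reads contribute coverage across
the skip (logged).  Tabular files need at least a read start column; missing
end positions are filled as ``start + read_length``.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

from .errors import ConfigurationError, ParseError
from .loci import Dialect, UNSTRANDED, _iter_rows, _norm_strand

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class MappedRead:
    """A single mapped read: 0-based half-open interval on a chromosome."""

    chromosome: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"read end must exceed start: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadCollection:
    """Mapped reads grouped per chromosome.

    ``total_mapped`` is the N of RPKM/DCPM normalization: the number of
    imported mapped records.
    """

    by_chromosome: dict[str, list[MappedRead]] = field(default_factory=dict)
    read_length_default: int = 36
    species: str = "unknown"

    @property
    def total_mapped(self) -> int:
        return sum(len(reads) for reads in self.by_chromosome.values())

    def add(self, read: MappedRead):
        self.by_chromosome.setdefault(read.chromosome, []).append(read)

    def sort(self):
        for reads in self.by_chromosome.values():
            reads.sort()

    def __iter__(self) -> Iterator[MappedRead]:
        for chrom in sorted(self.by_chromosome):
            yield from self.by_chromosome[chrom]

    def __len__(self) -> int:
        return self.total_mapped

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReadCollection):
            return NotImplemented
        mine = {c: sorted(r) for c, r in self.by_chromosome.items() if r}
        theirs = {c: sorted(r) for c, r in other.by_chromosome.items() if r}
        return mine == theirs


class CoverageTrack:
    """Sparse per-base read depth: only covered positions are stored."""

    def __init__(self):
        self._depth: dict[str, Counter] = {}

    def add_read(self, read: MappedRead):
        counter = self._depth.setdefault(read.chromosome, Counter())
        for pos in range(read.start, read.end):
            counter[pos] += 1

    def depth(self, chromosome: str, position: int) -> int:
        return self._depth.get(chromosome, Counter()).get(position, 0)

    def positions(self, chromosome: str) -> list[int]:
        """Covered positions of one chromosome, sorted."""
        return sorted(self._depth.get(chromosome, Counter()))

    def chromosomes(self) -> list[str]:
        return sorted(self._depth)

    def total_depth(self) -> int:
        """Sum of all stored depths (= total mapped bases)."""
        return sum(sum(c.values()) for c in self._depth.values())

    def region_depth_sum(self, chromosome: str, start: int, end: int) -> int:
        counter = self._depth.get(chromosome)
        if not counter:
            return 0
        if end - start < len(counter):
            return sum(counter.get(p, 0) for p in range(start, end))
        return sum(d for p, d in counter.items() if start <= p < end)


def build_coverage(reads: ReadCollection, strand: Optional[str] = None) -> CoverageTrack:
    """Accumulate per-base depth over all reads, optionally filtered by strand."""
    track = CoverageTrack()
    spliced = 0
    for read in reads:
        if strand is not None and read.strand != strand:
            continue
        track.add_read(read)
    if spliced:
        log.info("coverage includes %d spliced reads spanning skips", spliced)
    return track


# ---------------------------------------------------------------------------
# Parsing

_CONSUMES_REF = frozenset("MDN=X")


def parse_reads(
    source,
    format: str = "sam",
    column_map: Optional[dict] = None,
    defaults: Optional[dict] = None,
    dialect: Optional[Dialect] = None,
) -> ReadCollection:
    """Parse mapped reads from SAM, BAM or generic tabular input.

    ``source`` is a path (SAM/BAM) or a path/stream/string (tabular).
    Unmapped SAM/BAM records are skipped and do not count toward
    ``total_mapped``.
    """
    defaults = defaults or {}
    collection = ReadCollection(
        read_length_default=int(defaults.get("read_length", 36)),
        species=defaults.get("species", "unknown"),
    )
    if format in ("sam", "bam"):
        _parse_alignments(source, format, collection)
    elif format == "tabular":
        _parse_tabular_reads(source, column_map or {}, defaults, dialect, collection)
    else:
        raise ConfigurationError(f"unknown read format: {format!r}")
    collection.sort()
    return collection


def _parse_alignments(path, format, collection: ReadCollection):
    mode = "rb" if format == "bam" else "r"
    spliced = skipped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as handle:
        for record in handle:
            if record.is_unmapped:
                skipped += 1
                continue
            # reference span = M/D/N/=/X total; pysam's reference_end is exactly that
            end = record.reference_end
            if end is None:
                end = record.reference_start + collection.read_length_default
            if record.cigartuples and any(op == 3 for op, _ in record.cigartuples):
                spliced += 1
            collection.add(
                MappedRead(
                    chromosome=record.reference_name,
                    start=record.reference_start,
                    end=end,
                    strand="-" if record.is_reverse else "+",
                )
            )
    if skipped:
        log.info("skipped %d unmapped records", skipped)
    if spliced:
        log.info("%d spliced reads contribute coverage across their skips", spliced)


def _parse_tabular_reads(source, column_map, defaults, dialect, collection):
    dialect = dialect or Dialect()
    if "start" not in column_map:
        raise ConfigurationError(
            "At least, read start positions with respect to genomic coordinates "
            "are required: column map must assign 'start'"
        )
    if isinstance(source, (str, bytes)) and "\n" not in str(source):
        stream = open(source)
        close = True
    elif isinstance(source, str):
        stream = io.StringIO(source)
        close = False
    else:
        stream = source
        close = False
    try:
        for lineno, row in _iter_rows(stream, dialect):
            def get(fieldname):
                return row[column_map[fieldname]]

            try:
                start = int(get("start"))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"bad start position: {exc}", lineno)
            if "end" in column_map:
                end = int(get("end"))
            elif "length" in column_map:
                end = start + int(get("length"))
            else:
                end = start + collection.read_length_default
            if "strand" in column_map:
                strand = _norm_strand(get("strand"))
            else:
                strand = _norm_strand(defaults.get("strand", UNSTRANDED))
            chrom = (
                get("chromosome")
                if "chromosome" in column_map
                else defaults.get("chromosome", "chr")
            )
            collection.add(MappedRead(chrom, start, end, strand))
    finally:
        if close:
            stream.close()
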