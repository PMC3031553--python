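"""Genomic locus model, annotation parsing and the locus set algebra.

Internal coordinates are 0-based half-open throughout.  GFF and PTT input is
1-based inclusive and converted on the way in; BED export is emitted without
conversion, GFF export converts back.

The merge operations treat loci on different strands as unmergeable unless
``ignore_strand`` is set, in which case strand information is erased before
merging.  The gap between two loci ``a`` before ``b`` is ``b.start - a.end``;
overlapping loci have gap 0.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

from .errors import ConfigurationError, ParameterError, ParseError

log = logging.getLogger(__name__)

UNSTRANDED = "."
_STRANDS = {"+", "-", UNSTRANDED}


@dataclass(frozen=True, order=True)
class Locus:
    """A stranded interval on a named chromosome of a named species.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.
    """

    species: str
    chromosome: str
    start: int
    end: int
    strand: str = UNSTRANDED
    id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"locus start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"locus end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self, with_strand: bool = True):
        """Identity tuple used for deduplication and membership."""
        if with_strand:
            return (self.species, self.chromosome, self.start, self.end, self.strand)
        return (self.species, self.chromosome, self.start, self.end)

    def overlap(self, other: "Locus") -> int:
        """Number of shared bases (<= 0 when disjoint)."""
        return min(self.end, other.end) - max(self.start, other.start)

    def gap(self, other: "Locus") -> int:
        """Distance in bases between two loci; 0 when they overlap or abut."""
        return max(0, max(self.start, other.start) - min(self.end, other.end))


class LocusSet:
    """An ordered collection of loci with per-(species, chromosome) sorted access."""

    def __init__(self, loci: Iterable[Locus] = ()):
        self._loci: list[Locus] = list(loci)
        self._index: Optional[dict] = None

    def _build_index(self):
        index: dict[tuple, list[Locus]] = {}
        for locus in self._loci:
            index.setdefault((locus.species, locus.chromosome), []).append(locus)
        for group in index.values():
            group.sort(key=lambda l: (l.start, l.end))
        self._index = index

    @property
    def index(self) -> dict:
        if self._index is None:
            self._build_index()
        return self._index

    def chromosomes(self) -> list[tuple]:
        return sorted(self.index)

    def by_chromosome(self, species: str, chromosome: str) -> list[Locus]:
        """Loci of one chromosome in non-decreasing start order."""
        return self.index.get((species, chromosome), [])

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self._loci)

    def __contains__(self, locus: Locus) -> bool:
        return any(l.key() == locus.key() for l in self._loci)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LocusSet):
            return NotImplemented
        return sorted(l.key() for l in self._loci) == sorted(
            l.key() for l in other._loci
        )

    def __repr__(self) -> str:
        return f"LocusSet({len(self._loci)} loci)"


# ---------------------------------------------------------------------------
# Parsing


_LOCUS_FIELDS = {"id", "species", "chromosome", "start", "end", "length", "strand"}

_STRAND_TOKENS = {
    "+": "+", "-": "-", "−": "-",  # unicode minus
    "F": "+", "R": "-", "f": "+", "r": "-",
    "0": "+", "1": "-", ".": UNSTRANDED, "": UNSTRANDED,
}


def _norm_strand(token) -> str:
    return _STRAND_TOKENS.get(str(token).strip(), UNSTRANDED)


@dataclass
class Dialect:
    """Tabular dialect: separator, quote and comment characters."""

    sep: str = "\t"
    quote: str = '"'
    comment: str = "#"


def _iter_rows(stream, dialect: Dialect):
    """Yield (line_number, row) for data rows, skipping comments and blanks."""
    reader = csv.reader(stream, delimiter=dialect.sep, quotechar=dialect.quote)
    for lineno, row in enumerate(reader, start=1):
        if not row or not "".join(row).strip():
            continue
        if dialect.comment and row[0].lstrip().startswith(dialect.comment):
            continue
        yield lineno, row


def parse_loci(
    source,
    format: str = "gff",
    column_map: Optional[dict] = None,
    defaults: Optional[dict] = None,
    dialect: Optional[Dialect] = None,
) -> LocusSet:
    """Parse a locus annotation stream into a :class:`LocusSet`.

    ``format`` is one of ``gff`` (GFF3, 1-based inclusive), ``ptt`` (NCBI
    protein table, ``start..end`` location column) or ``tabular`` (generic
    delimited text driven by ``column_map``).  ``defaults`` fills in
    per-file attributes (species, chromosome, strand) absent from the file.
    """
    defaults = defaults or {}
    if isinstance(source, (str, bytes)):
        source = io.StringIO(source.decode() if isinstance(source, bytes) else source)
    if format == "gff":
        return _parse_gff(source, defaults)
    if format == "ptt":
        return _parse_ptt(source, defaults)
    if format == "tabular":
        return _parse_tabular_loci(source, column_map or {}, defaults, dialect)
    raise ConfigurationError(f"unknown locus format: {format!r}")


def _parse_gff(stream, defaults) -> LocusSet:
    species = defaults.get("species", "unknown")
    loci = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ParseError(f"GFF line has {len(cols)} columns, expected >= 8", lineno)
        chrom, _src, _type, start, end, _score, strand = cols[0:7]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise ParseError(f"non-numeric coordinate {start!r}/{end!r}", lineno)
        attrs = cols[8] if len(cols) > 8 else ""
        feature_id = None
        m = re.search(r"(?:^|;)\s*(?:ID|locus_tag|Name|gene_id)=([^;]+)", attrs)
        if m:
            feature_id = m.group(1).strip().strip('"')
        loci.append(
            Locus(
                species=species,
                chromosome=chrom,
                start=start_i - 1,  # 1-based inclusive -> 0-based half-open
                end=end_i,
                strand=_norm_strand(strand),
                id=feature_id,
            )
        )
    return LocusSet(loci)


_PTT_LOCATION = re.compile(r"^(\d+)\.\.(\d+)$")


def _parse_ptt(stream, defaults) -> LocusSet:
    species = defaults.get("species", "unknown")
    chromosome = defaults.get("chromosome", "chr")
    loci = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        m = _PTT_LOCATION.match(cols[0].strip())
        if m is None:
            # header lines: title, "N proteins", column names
            continue
        start_i, end_i = int(m.group(1)), int(m.group(2))
        strand = _norm_strand(cols[1]) if len(cols) > 1 else UNSTRANDED
        feature_id = None
        if len(cols) > 5 and cols[5].strip() not in ("", "-"):
            feature_id = cols[5].strip()
        loci.append(
            Locus(
                species=species,
                chromosome=chromosome,
                start=start_i - 1,
                end=end_i,
                strand=strand,
                id=feature_id,
            )
        )
    return LocusSet(loci)


def _parse_tabular_loci(stream, column_map, defaults, dialect) -> LocusSet:
    dialect = dialect or Dialect()
    unknown = set(column_map) - _LOCUS_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown locus fields in column map: {sorted(unknown)}")
    if "start" not in column_map:
        raise ConfigurationError("column map must assign the 'start' field")
    if "end" not in column_map and "length" not in column_map:
        raise ConfigurationError("column map must assign 'end' or 'length'")

    def get(row, fieldname, lineno):
        col = column_map[fieldname]
        try:
            return row[col]
        except IndexError:
            raise ParseError(f"row has no column {col} for field {fieldname!r}", lineno)

    loci = []
    for lineno, row in _iter_rows(stream, dialect):
        try:
            start = int(get(row, "start", lineno))
            if "end" in column_map:
                end = int(get(row, "end", lineno))
            else:
                end = start + int(get(row, "length", lineno))
        except ValueError as exc:
            raise ParseError(f"non-numeric coordinate: {exc}", lineno)
        strand = (
            _norm_strand(get(row, "strand", lineno))
            if "strand" in column_map
            else _norm_strand(defaults.get("strand", UNSTRANDED))
        )
        loci.append(
            Locus(
                species=(
                    get(row, "species", lineno)
                    if "species" in column_map
                    else defaults.get("species", "unknown")
                ),
                chromosome=(
                    get(row, "chromosome", lineno)
                    if "chromosome" in column_map
                    else defaults.get("chromosome", "chr")
                ),
                start=start,
                end=end,
                strand=strand,
                id=get(row, "id", lineno) if "id" in column_map else None,
            )
        )
    return LocusSet(loci)


# ---------------------------------------------------------------------------
# Export


def write_gff3(loci: LocusSet, stream, source: str = "seasight", feature_type: str = "gene"):
    """Write a LocusSet as GFF3 (1-based inclusive)."""
    stream.write("##gff-version 3\n")
    for locus in loci:
        attrs = f"ID={locus.id}" if locus.id else "."
        stream.write(
            "\t".join(
                [
                    locus.chromosome,
                    source,
                    feature_type,
                    str(locus.start + 1),
                    str(locus.end),
                    ".",
                    locus.strand,
                    ".",
                    attrs,
                ]
            )
            + "\n"
        )


def write_bed(loci: LocusSet, stream):
    """Write a LocusSet as BED (0-based half-open, as stored)."""
    for locus in loci:
        stream.write(
            "\t".join(
                [
                    locus.chromosome,
                    str(locus.start),
                    str(locus.end),
                    locus.id or ".",
                    "0",
                    locus.strand,
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Merge algebra


def _merge_groups(sets: Sequence[LocusSet], ignore_strand: bool):
    """Pool input loci and group them by (species, chromosome[, strand])."""
    groups: dict[tuple, list[Locus]] = {}
    for locus_set in sets:
        for locus in locus_set:
            if ignore_strand and locus.strand != UNSTRANDED:
                locus = replace(locus, strand=UNSTRANDED)
            key = (locus.species, locus.chromosome, locus.strand)
            groups.setdefault(key, []).append(locus)
    for group in groups.values():
        group.sort(key=lambda l: (l.start, l.end))
    return dict(sorted(groups.items()))


def _check_sets(sets):
    if not sets:
        raise ParameterError("at least one input LocusSet is required")


def merge_union(
    sets: Sequence[LocusSet], min_size: int = 1, ignore_strand: bool = False
) -> LocusSet:
    """Deduplicated union of all input loci, dropping loci shorter than min_size."""
    _check_sets(sets)
    if min_size < 1:
        raise ParameterError(f"min_size must be >= 1, got {min_size}")
    seen: dict[tuple, Locus] = {}
    for locus_set in sets:
        for locus in locus_set:
            if ignore_strand and locus.strand != UNSTRANDED:
                locus = replace(locus, strand=UNSTRANDED)
            seen.setdefault(locus.key(), locus)
    return LocusSet(
        sorted(
            (l for l in seen.values() if l.length >= min_size),
            key=lambda l: l.key(),
        )
    )


def merge_pairwise(
    sets: Sequence[LocusSet], min_size: int = 1, ignore_strand: bool = False
) -> LocusSet:
    """One locus per pair of neighbouring boundary coordinates.

    Per chromosome, the sorted unique set of all starts and ends
    c1 < c2 < ... < ck yields candidates [ci, ci+1); a candidate survives iff
    it overlaps at least one input locus and is at least min_size long.
    """
    _check_sets(sets)
    if min_size < 1:
        raise ParameterError(f"min_size must be >= 1, got {min_size}")
    out = []
    for (species, chrom, strand), group in _merge_groups(sets, ignore_strand).items():
        bounds = sorted({c for l in group for c in (l.start, l.end)})
        for lo, hi in zip(bounds, bounds[1:]):
            if hi - lo < min_size:
                continue
            if any(l.start < hi and lo < l.end for l in group):
                out.append(Locus(species, chrom, lo, hi, strand))
    return LocusSet(out)


def merge_greedy(
    sets: Sequence[LocusSet],
    min_overlap: Optional[int] = None,
    max_distance: Optional[int] = None,
    ignore_strand: bool = False,
) -> LocusSet:
    """Cluster pooled loci left to right by minimal overlap OR maximal distance.

    Exactly one of ``min_overlap`` / ``max_distance`` must be given.  The
    candidate locus is compared against the growing cluster's span; each
    closed cluster emits its spanning locus.
    """
    _check_sets(sets)
    if (min_overlap is None) == (max_distance is None):
        raise ParameterError(
            "exactly one of min_overlap and max_distance must be given"
        )
    if min_overlap is not None and min_overlap < 0:
        raise ParameterError(f"min_overlap must be >= 0, got {min_overlap}")
    if max_distance is not None and max_distance < 0:
        raise ParameterError(f"max_distance must be >= 0, got {max_distance}")
    out = []
    for (species, chrom, strand), group in _merge_groups(sets, ignore_strand).items():
        span_start, span_end = group[0].start, group[0].end
        for locus in group[1:]:
            if min_overlap is not None:
                joins = min(span_end, locus.end) - max(span_start, locus.start) >= min_overlap
            else:
                joins = max(0, locus.start - span_end) <= max_distance
            if joins:
                span_end = max(span_end, locus.end)
            else:
                out.append(Locus(species, chrom, span_start, span_end, strand))
                span_start, span_end = locus.start, locus.end
        out.append(Locus(species, chrom, span_start, span_end, strand))
    return LocusSet(out)


def merge_minmax(
    sets: Sequence[LocusSet],
    min_size: int = 1,
    max_size: Optional[int] = None,
    ignore_strand: bool = False,
) -> LocusSet:
    """Merge overlapping loci into maximal extensions within [min_size, max_size].

    Left-to-right accumulation: a locus is absorbed iff it overlaps the
    current extension and the extended span stays <= max_size.  A closed
    extension is emitted iff its length lies in [min_size, max_size].
    """
    _check_sets(sets)
    if max_size is None:
        max_size = 2**63
    if min_size < 1 or min_size > max_size:
        raise ParameterError(
            f"need 0 < min_size <= max_size, got {min_size}, {max_size}"
        )
    out = []
    for (species, chrom, strand), group in _merge_groups(sets, ignore_strand).items():
        span_start, span_end = group[0].start, group[0].end

        def close(start, end):
            if min_size <= end - start <= max_size:
                out.append(Locus(species, chrom, start, end, strand))

        for locus in group[1:]:
            overlaps = locus.start < span_end
            if overlaps and max(span_end, locus.end) - span_start <= max_size:
                span_end = max(span_end, locus.end)
            else:
                close(span_start, span_end)
                span_start, span_end = locus.start, locus.end
        close(span_start, span_end)
    return LocusSet(out)


def filter_loci(
    target: LocusSet,
    reference: LocusSet,
    min_overlap: int = 0,
    max_distance: int = 0,
) -> LocusSet:
    """Keep target loci close enough to some reference locus.

    A target locus ``t`` survives iff a reference locus ``r`` on the same
    species/chromosome (and a compatible strand) has
    ``overlap(t, r) >= min_overlap`` and ``gap(t, r) <= max_distance``.
    Output order is preserved.
    """
    if min_overlap < 0 or max_distance < 0:
        raise ParameterError("min_overlap and max_distance must be >= 0")
    if len(reference) == 0:
        log.warning("filter_loci: empty reference set, returning empty result")
        return LocusSet()
    kept = []
    for t in target:
        refs = reference.by_chromosome(t.species, t.chromosome)
        for r in refs:
            if (
                t.strand != UNSTRANDED
                and r.strand != UNSTRANDED
                and t.strand != r.strand
            ):
                continue
            if max(0, t.overlap(r)) >= min_overlap and t.gap(r) <= max_distance:
                kept.append(t)
                break
    return LocusSet(kept)


def edit_loci(
    locus_set: LocusSet,
    shift: int = 0,
    set_length: Optional[dict] = None,
    strand_op: str = "keep",
    rename: Optional[dict] = None,
) -> LocusSet:
    """Apply locus edits in the order rename -> strand_op -> shift -> set_length.

    ``set_length`` is ``{"value": bases, "anchor": "start"|"end"|"center"}``;
    ``strand_op`` is ``keep``, ``flip`` or ``clear``; ``rename`` maps old
    species/chromosome names to new ones.  The input set is not modified.
    """
    if strand_op not in ("keep", "flip", "clear"):
        raise ParameterError(f"unknown strand_op {strand_op!r}")
    if set_length is not None:
        if set_length.get("value", 0) <= 0:
            raise ParameterError("set_length value must be > 0")
        if set_length.get("anchor", "start") not in ("start", "end", "center"):
            raise ParameterError(f"unknown anchor {set_length.get('anchor')!r}")
    rename = rename or {}
    out = []
    for locus in locus_set:
        species = rename.get(locus.species, locus.species)
        chrom = rename.get(locus.chromosome, locus.chromosome)
        strand = locus.strand
        if strand_op == "flip" and strand != UNSTRANDED:
            strand = "+" if strand == "-" else "-"
        elif strand_op == "clear":
            strand = UNSTRANDED
        start, end = locus.start + shift, locus.end + shift
        if start < 0:
            raise ParameterError(
                f"shift {shift} pushes locus {locus.id or locus.key()} below position 0"
            )
        if set_length is not None:
            value = set_length["value"]
            anchor = set_length.get("anchor", "start")
            if anchor == "start":
                end = start + value
            elif anchor == "end":
                start = end - value
            else:
                center = (start + end) // 2
                start = center - value // 2
                end = start + value
            if start < 0:
                raise ParameterError(
                    f"set_length pushes locus {locus.id or locus.key()} below position 0"
                )
        out.append(Locus(species, chrom, start, end, strand, locus.id))
    return LocusSet(out)
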