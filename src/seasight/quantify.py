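"""Per-locus expression from mapped reads: counting, coverage, RPKM, DCPM,
and coverage-based locus derivation.

``coverage`` mode is mean per-base depth over the locus (length-independent);
RPKM is ``1e9 * count / (N * L)``; DCPM is mean depth per million mapped
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import DomainError, ParameterError, StateError
from .loci import Locus, LocusSet, UNSTRANDED
from .reads import CoverageTrack, ReadCollection

COUNT_RULES = ("overlap_any", "start_in", "contained")


@dataclass
class LocusExpression:
    """Per-locus expression values for one experiment."""

    values: dict[Locus, float] = field(default_factory=dict)
    mode: str = "naive"
    total_mapped: int = 0

    def __getitem__(self, locus: Locus) -> float:
        return self.values[locus]

    def __len__(self) -> int:
        return len(self.values)

    def by_id(self) -> dict[str, float]:
        """Values keyed by locus id (falls back to coordinate string)."""
        out = {}
        for locus, value in self.values.items():
            key = locus.id or f"{locus.chromosome}:{locus.start}-{locus.end}"
            out[key] = value
        return out

    def write_tabular(self, stream, sep: str = "\t"):
        stream.write(sep.join(["feature", "chrom", "start", "end", "strand", "value"]) + "\n")
        for locus in sorted(self.values, key=lambda l: l.key()):
            stream.write(
                sep.join(
                    [
                        locus.id or ".",
                        locus.chromosome,
                        str(locus.start),
                        str(locus.end),
                        locus.strand,
                        repr(self.values[locus]),
                    ]
                )
                + "\n"
            )


def _read_matches(read, locus, rule: str) -> bool:
    if rule == "overlap_any":
        return read.start < locus.end and locus.start < read.end
    if rule == "start_in":
        return locus.start <= read.start < locus.end
    if rule == "contained":
        return locus.start <= read.start and read.end <= locus.end
    raise ParameterError(f"unknown counting rule {rule!r}")


def count_reads(
    reads: ReadCollection,
    loci: LocusSet,
    rule: str = "overlap_any",
    stranded: bool = False,
) -> LocusExpression:
    """Count reads per locus.  A read may count toward several overlapping loci."""
    if rule not in COUNT_RULES:
        raise ParameterError(f"unknown counting rule {rule!r}")
    expr = LocusExpression(mode="naive", total_mapped=reads.total_mapped)
    for locus in loci:
        candidates = reads.by_chromosome.get(locus.chromosome, [])
        count = 0
        for read in candidates:
            if stranded:
                if read.strand == UNSTRANDED:
                    raise StateError(
                        "stranded counting requested but reads carry no strand"
                    )
                if locus.strand != UNSTRANDED and read.strand != locus.strand:
                    continue
            if _read_matches(read, locus, rule):
                count += 1
        expr.values[locus] = float(count)
    return expr


def coverage_value(track: CoverageTrack, loci: LocusSet) -> LocusExpression:
    """Mean per-base depth over each locus."""
    expr = LocusExpression(mode="coverage")
    for locus in loci:
        total = track.region_depth_sum(locus.chromosome, locus.start, locus.end)
        expr.values[locus] = total / locus.length
    return expr


def rpkm(count: float, total_mapped: int, length: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if total_mapped <= 0:
        raise DomainError("RPKM undefined for zero total mapped reads")
    if length <= 0:
        raise DomainError("RPKM undefined for zero-length locus")
    return 1e9 * count / (total_mapped * length)


def dcpm(track: CoverageTrack, locus: Locus, total_mapped: int) -> float:
    """Depth of coverage per base per million mapped reads."""
    if total_mapped <= 0:
        raise DomainError("DCPM undefined for zero total mapped reads")
    mean_depth = track.region_depth_sum(locus.chromosome, locus.start, locus.end) / locus.length
    return mean_depth / (total_mapped / 1e6)


def rpkm_expression(reads: ReadCollection, loci: LocusSet, rule: str = "overlap_any") -> LocusExpression:
    """Convenience: naive counts converted to RPKM in one step."""
    counts = count_reads(reads, loci, rule=rule)
    expr = LocusExpression(mode="rpkm", total_mapped=reads.total_mapped)
    for locus, count in counts.values.items():
        expr.values[locus] = rpkm(count, reads.total_mapped, locus.length)
    return expr


def dcpm_expression(track: CoverageTrack, loci: LocusSet, total_mapped: int) -> LocusExpression:
    expr = LocusExpression(mode="dcpm", total_mapped=total_mapped)
    for locus in loci:
        expr.values[locus] = dcpm(track, locus, total_mapped)
    return expr


def derive_loci(
    track: CoverageTrack,
    min_depth: int,
    min_length: int = 1,
    max_gap: int = 0,
    species: str = "unknown",
) -> LocusSet:
    """Derive loci as maximal runs of positions with depth >= min_depth.

    Internal gaps up to ``max_gap`` bases are bridged; runs shorter than
    ``min_length`` are dropped.  Deliberately basic: a proof-of-concept
    segmentation, not a peak caller.
    """
    if min_depth <= 0:
        raise ParameterError("min_depth must be > 0")
    out = []
    for chrom in track.chromosomes():
        positions = [p for p in track.positions(chrom) if track.depth(chrom, p) >= min_depth]
        if not positions:
            continue
        run_start = prev = positions[0]
        for pos in positions[1:]:
            if pos - prev - 1 > max_gap:
                if prev + 1 - run_start >= min_length:
                    out.append(Locus(species, chrom, run_start, prev + 1))
                run_start = pos
            prev = pos
        if prev + 1 - run_start >= min_length:
            out.append(Locus(species, chrom, run_start, prev + 1))
    return LocusSet(out)
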