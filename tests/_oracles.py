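"""Independent brute-force oracles for the locus merge algebra.

Deliberately naive: exhaustive pairwise interval arithmetic and explicit
per-base position sets, with fixed-point merging loops instead of sorted
sweeps.  Used by unit tests and the acceptance suite to cross-check the
production implementations.
"""

from seasight.loci import Locus, LocusSet


def _group(sets):
    groups = {}
    for locus_set in sets:
        for locus in locus_set:
            key = (locus.species, locus.chromosome, locus.strand)
            groups.setdefault(key, []).append((locus.start, locus.end))
    return groups


def _positions(span):
    return set(range(span[0], span[1]))


def oracle_union(sets, min_size):
    seen = {}
    for locus_set in sets:
        for locus in locus_set:
            seen.setdefault(locus.key(), locus)
    return LocusSet(l for l in seen.values() if l.length >= min_size)


def oracle_pairwise(sets, min_size):
    out = []
    for (species, chrom, strand), spans in _group(sets).items():
        covered = set()
        for span in spans:
            covered |= _positions(span)
        bounds = sorted({c for span in spans for c in span})
        for lo, hi in zip(bounds, bounds[1:]):
            if hi - lo < min_size:
                continue
            if _positions((lo, hi)) & covered:
                out.append(Locus(species, chrom, lo, hi, strand))
    return LocusSet(out)


def oracle_greedy(sets, min_overlap=None, max_distance=None):
    """Left-to-right clustering re-derived with explicit position sets.

    Note the scan is the definition: a short locus contained in the cluster
    span can fail the overlap criterion and reset the cluster, so a global
    fixed-point pairwise merge is NOT equivalent in overlap mode.
    """
    if min_overlap is not None:
        def joins(cluster, span):
            if min_overlap == 0:
                # touching or overlapping
                return span[0] <= cluster[1] and cluster[0] <= span[1]
            return len(_positions(cluster) & _positions(span)) >= min_overlap
    else:
        def joins(cluster, span):
            between = set(range(cluster[1], span[0]))
            return len(between - _positions(cluster)) <= max_distance
    out = []
    for (species, chrom, strand), spans in _group(sets).items():
        spans = sorted(spans)
        cluster = spans[0]
        for span in spans[1:]:
            if joins(cluster, span):
                cluster = (cluster[0], max(cluster[1], span[1]))
            else:
                out.append(Locus(species, chrom, *cluster, strand))
                cluster = span
        out.append(Locus(species, chrom, *cluster, strand))
    return LocusSet(out)


def oracle_minmax(sets, min_size, max_size):
    """Literal left-to-right accumulation re-derived with position sets."""
    out = []
    for (species, chrom, strand), spans in _group(sets).items():
        spans = sorted(spans)
        extension = _positions(spans[0])

        def emit(ext):
            if min_size <= len(ext) <= max_size:
                out.append(Locus(species, chrom, min(ext), max(ext) + 1, strand))

        for span in spans[1:]:
            positions = _positions(span)
            if extension & positions and len(extension | positions) <= max_size:
                extension |= positions
            else:
                emit(extension)
                extension = positions
        emit(extension)
    return LocusSet(out)
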