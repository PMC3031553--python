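"""Seeded synthetic-data generators for a two-condition, two-platform study.

The generated study mirrors the structure of a technical-replicate
cross-platform comparison: per condition, ``replicates`` microarray
hybridizations and ``replicates`` sequencing lanes interrogate the same set
of genes.  Everything is deterministic under ``seed``: gene structure and
probe affinities depend only on the seed, per-replicate noise additionally
on (platform, condition, replicate).

Array intensities follow the exponential-signal-plus-Gaussian-background
convolution model, so background-correction parameter recovery is a
well-posed test.  Reads are unspliced single-end with uniform starts within
their gene and Poisson-distributed per-gene counts proportional to
expression times length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .arrays import ProbesetMap, ProbeTable
from .errors import ParameterError
from .loci import Locus, LocusSet
from .reads import MappedRead, ReadCollection

_DOMAIN = {"structure": 0, "expression": 1, "reads": 2, "array": 3}


@dataclass
class StudyDesign:
    """Parameters of the synthetic study."""

    genes: int = 200
    conditions: int = 2
    replicates: int = 2  # per condition per platform
    de_fraction: float = 0.1
    fold_change: float = 4.0
    genome_length: int = 2_000_000
    read_length: int = 36
    depth: int = 30_000  # expected mapped reads per lane
    probes_per_gene: int = 11
    mean_gene_length: float = 1000.0
    gene_length_sigma: float = 0.4
    array_gain: float = 1.0
    bg_alpha: float = 100.0
    bg_mu: float = 50.0
    bg_sigma: float = 10.0
    seed: int = 0
    species: str = "synthia"
    chromosome: str = "chr1"

    def __post_init__(self):
        if min(self.genes, self.conditions, self.replicates, self.depth) <= 0:
            raise ParameterError("all design counts must be positive")
        if not 0 <= self.de_fraction < 1:
            raise ParameterError("de_fraction must lie in [0, 1)")

    def rng(self, domain: str, *indices: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed, _DOMAIN[domain], *indices]
        )

    def gene_id(self, i: int) -> str:
        return f"gene_{i:04d}"


@dataclass
class GroundTruth:
    """Per-gene truth: expression per condition and DE labels."""

    expression: pd.DataFrame  # genes x conditions
    lengths: pd.Series
    de_genes: pd.Series  # gene -> direction in {-1, 0, +1}

    def to_frame(self) -> pd.DataFrame:
        frame = self.expression.copy()
        frame.columns = [f"expr_c{c}" for c in range(frame.shape[1])]
        frame["length"] = self.lengths
        frame["de"] = self.de_genes
        frame.index.name = "gene"
        return frame


def synth_loci(design: StudyDesign) -> LocusSet:
    """Non-overlapping stranded gene loci with log-normal lengths."""
    rng = design.rng("structure")
    mu = math.log(design.mean_gene_length) - design.gene_length_sigma**2 / 2
    lengths = np.maximum(
        rng.lognormal(mu, design.gene_length_sigma, design.genes).astype(int), 50
    )
    total = int(lengths.sum())
    slack = design.genome_length - total
    if slack < design.genes:
        raise ParameterError(
            f"genome length {design.genome_length} cannot pack {design.genes} genes "
            f"spanning {total} bases"
        )
    gaps = rng.multinomial(slack - design.genes, np.full(design.genes, 1 / design.genes)) + 1
    strands = rng.choice(["+", "-"], size=design.genes)
    loci = []
    position = 0
    for i in range(design.genes):
        position += int(gaps[i])
        start = position
        end = start + int(lengths[i])
        position = end
        loci.append(
            Locus(design.species, design.chromosome, start, end, strands[i], design.gene_id(i))
        )
    return LocusSet(loci)


def ground_truth(design: StudyDesign) -> GroundTruth:
    """Deterministic per-gene expression levels and DE assignments."""
    rng = design.rng("expression")
    base = rng.lognormal(math.log(100.0), 1.0, design.genes)
    n_de = int(round(design.de_fraction * design.genes))
    de_idx = rng.choice(design.genes, size=n_de, replace=False)
    direction = np.zeros(design.genes, dtype=int)
    # half up-, half downregulated in the last condition
    direction[de_idx[: n_de // 2]] = 1
    direction[de_idx[n_de // 2:]] = -1
    genes = [design.gene_id(i) for i in range(design.genes)]
    expr = np.tile(base[:, None], (1, design.conditions)).astype(float)
    expr[:, -1] *= np.power(design.fold_change, direction.astype(float))
    loci = synth_loci(design)
    lengths = pd.Series(
        {l.id: l.length for l in loci}, name="length"
    ).reindex(genes)
    return GroundTruth(
        expression=pd.DataFrame(expr, index=genes,
                                columns=list(range(design.conditions))),
        lengths=lengths,
        de_genes=pd.Series(direction, index=genes, name="de"),
    )


def synth_reads(
    design: StudyDesign, condition: int, replicate: int = 0,
    truth: Optional[GroundTruth] = None, loci: Optional[LocusSet] = None,
) -> tuple[ReadCollection, pd.Series]:
    """One sequencing lane: Poisson counts per gene, uniform starts.

    Returns the collection and the realized per-gene read counts.
    """
    truth = truth or ground_truth(design)
    loci = loci or synth_loci(design)
    rng = design.rng("reads", condition, replicate)
    expr = truth.expression[condition]
    weights = expr * truth.lengths
    probs = weights / weights.sum()
    expected = design.depth * probs
    counts = pd.Series(rng.poisson(expected.to_numpy()), index=expected.index)
    collection = ReadCollection(read_length_default=design.read_length,
                                species=design.species)
    by_id = {l.id: l for l in loci}
    for gene, count in counts.items():
        if count == 0:
            continue
        locus = by_id[gene]
        hi = max(locus.start + 1, locus.end - design.read_length)
        starts = rng.integers(locus.start, hi, size=int(count))
        for start in starts:
            collection.add(
                MappedRead(
                    locus.chromosome,
                    int(start),
                    int(start) + design.read_length,
                    locus.strand,
                )
            )
    collection.sort()
    return collection, counts


def probe_affinities(design: StudyDesign) -> pd.DataFrame:
    """Log-normal probe affinities, shared across replicates and conditions."""
    rng = design.rng("structure", 1)
    values = rng.lognormal(0.0, 0.5, (design.genes, design.probes_per_gene))
    index = [design.gene_id(i) for i in range(design.genes)]
    return pd.DataFrame(values, index=index)


def probeset_map(design: StudyDesign) -> ProbesetMap:
    mapping = {}
    for i in range(design.genes):
        for j in range(design.probes_per_gene):
            mapping[f"{design.gene_id(i)}_p{j:02d}"] = design.gene_id(i)
    return ProbesetMap(mapping)


def synth_array(
    design: StudyDesign, condition: int, replicate: int = 0,
    truth: Optional[GroundTruth] = None,
) -> tuple[ProbeTable, ProbesetMap]:
    """One array hybridization under the convolution noise model.

    probe intensity = gain * expression * affinity + Exp(bg_alpha) + N(bg_mu, bg_sigma).
    Affinities are shared across replicates; only the background/noise draws
    depend on the replicate index.
    """
    truth = truth or ground_truth(design)
    affinities = probe_affinities(design)
    rng = design.rng("array", condition, replicate)
    expr = truth.expression[condition].to_numpy()[:, None]
    signal = design.array_gain * expr * affinities.to_numpy()
    noise = rng.exponential(design.bg_alpha, signal.shape) + rng.normal(
        design.bg_mu, design.bg_sigma, signal.shape
    )
    intensities = np.maximum(signal + noise, 0.0)
    probe_ids = [
        f"{design.gene_id(i)}_p{j:02d}"
        for i in range(design.genes)
        for j in range(design.probes_per_gene)
    ]
    fg = pd.DataFrame(
        {"ch1": intensities.reshape(-1)}, index=pd.Index(probe_ids, name="probe_id")
    )
    return ProbeTable(fg=fg), probeset_map(design)


# ---------------------------------------------------------------------------
# Bundle on disk


def _array_file(design, condition, replicate) -> str:
    return f"array_c{condition}_r{replicate}.tsv"


def _reads_file(design, condition, replicate) -> str:
    return f"reads_c{condition}_r{replicate}.sam"


def write_sam(collection: ReadCollection, design: StudyDesign, stream):
    """Minimal SAM rendering of a read collection (36M-style CIGAR)."""
    stream.write("@HD\tVN:1.6\tSO:coordinate\n")
    stream.write(f"@SQ\tSN:{design.chromosome}\tLN:{design.genome_length}\n")
    i = 0
    for read in collection:
        flag = 16 if read.strand == "-" else 0
        length = read.end - read.start
        stream.write(
            f"r{i:07d}\t{flag}\t{read.chromosome}\t{read.start + 1}\t255\t"
            f"{length}M\t*\t0\t0\t{'A' * length}\t*\n"
        )
        i += 1


def synth_study(design: StudyDesign, out_dir) -> dict:
    """Write the full study bundle and a ready-made pipeline config.

    Returns a manifest dict of the written files.
    """
    from .loci import write_gff3
    from .arrays import write_probeset_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = ground_truth(design)
    loci = synth_loci(design)
    manifest = {"loci": "loci.gff", "probeset_map": "probeset_map.tsv",
                "truth": "truth.tsv", "config": "config.yaml",
                "arrays": [], "reads": []}

    with open(out / "loci.gff", "w") as handle:
        write_gff3(loci, handle)
    with open(out / "probeset_map.tsv", "w") as handle:
        write_probeset_map(probeset_map(design), handle)
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", lineterminator="\n")

    for condition in range(design.conditions):
        for replicate in range(design.replicates):
            table, _ = synth_array(design, condition, replicate, truth=truth)
            name = _array_file(design, condition, replicate)
            frame = table.fg.rename(columns={"ch1": "intensity"})
            frame.to_csv(out / name, sep="\t", lineterminator="\n")
            manifest["arrays"].append(name)

            collection, _counts = synth_reads(
                design, condition, replicate, truth=truth, loci=loci
            )
            name = _reads_file(design, condition, replicate)
            with open(out / name, "w") as handle:
                write_sam(collection, design, handle)
            manifest["reads"].append(name)

    _write_pipeline_config(design, out)
    return manifest


def _write_pipeline_config(design: StudyDesign, out: Path):
    """Emit the case-study-shaped pipeline over the bundle.

    Arrays: normexp -> quantile -> log2 -> median-polish summarization ->
    identifier mapping.  Reads: locus attachment -> RPKM -> logarithmic
    interval mapping -> identifier mapping.  Closing step: quantile over
    all experiments.
    """
    from .engine import (
        CONFIG_VERSION, Context, DataState, Experiment, TransformationMatrix,
        save_config,
    )

    experiments = []
    array_names, read_names = [], []
    for condition in range(design.conditions):
        for replicate in range(design.replicates):
            name = f"array_c{condition}_r{replicate}"
            array_names.append(name)
            experiments.append(Experiment(
                name=name,
                state=DataState(entity="probe", channels=1, scale="linear",
                                measure="intensity",
                                row_count=design.genes * design.probes_per_gene),
                source={"path": _array_file(design, condition, replicate),
                        "format": "array_tabular",
                        "column_map": {"probe_id": "probe_id", "fg": ["intensity"]}},
            ))
    for condition in range(design.conditions):
        for replicate in range(design.replicates):
            name = f"seq_c{condition}_r{replicate}"
            read_names.append(name)
            experiments.append(Experiment(
                name=name,
                state=DataState(entity="read", channels=1, scale="linear",
                                measure="count"),
                source={"path": _reads_file(design, condition, replicate),
                        "format": "sam"},
            ))

    matrix = TransformationMatrix(experiments, context=Context(out))
    matrix.add_instance(0, array_names, "normexp")
    matrix.add_instance(0, read_names, "attach_loci",
                        {"source": "loci.gff", "format": "gff",
                         "defaults": {"species": design.species}})
    matrix.add_instance(1, array_names, "quantile")
    matrix.add_instance(1, read_names, "count",
                        {"mode": "rpkm", "rule": "overlap_any",
                         "source": "loci.gff", "format": "gff",
                         "defaults": {"species": design.species}})
    matrix.add_instance(2, array_names, "log2")
    matrix.add_instance(2, read_names, "interval_map_log", {"lo": 0.0, "hi": 16.0})
    matrix.add_instance(3, array_names, "summarize",
                        {"method": "median_polish", "map_source": "probeset_map.tsv"})
    matrix.add_instance(4, array_names, "map_identifiers")
    matrix.add_instance(4, read_names, "map_identifiers")
    matrix.add_instance(5, array_names + read_names, "quantile")
    save_config(matrix, out / "config.yaml")
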