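import numpy as np
import pytest

from seasight.loci import Locus, LocusSet
from seasight.synth import StudyDesign, synth_study


def random_locus_sets(rng, max_loci=50, max_coord=10_000, n_sets=3, stranded=True):
    """A random merge-problem instance: a few sets on a couple of chromosomes."""
    sets = []
    total = rng.integers(1, max_loci + 1)
    per_set = np.array_split(np.arange(total), n_sets)
    for chunk in per_set:
        loci = []
        for _ in chunk:
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, max_coord - 1))
            length = int(rng.integers(1, min(500, max_coord - start) + 1))
            strand = str(rng.choice(["+", "-", "."])) if stranded else "."
            loci.append(Locus("sp", chrom, start, start + length, strand))
        sets.append(LocusSet(loci))
    return [s for s in sets if len(s)] or [LocusSet([Locus("sp", "chr1", 0, 10)])]


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(genes=40, replicates=2, depth=4000, probes_per_gene=5,
                       genome_length=300_000, seed=11)


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign(seed=7)


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory, default_design):
    """The default synthetic study written to disk, shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = synth_study(default_design, out)
    return out, manifest, default_design
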