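# seasight

Cross-platform expression integration for bulk transcriptomics: import
mapped sequencing reads (SAM/BAM/tabular), raw microarray probe tables and
genomic locus annotations (GFF3/PTT/tabular); reconcile them onto a common
feature set via a locus-merging algebra; and transform every experiment into
one comparable expression matrix through a state-typed transformation-matrix
engine.

## Layout

| module | purpose |
|---|---|
| `seasight.loci` | Locus model, GFF3/PTT/tabular parsing, merge algebra (union / pairwise / greedy / minmax), filtering and locus edits |
| `seasight.reads` | SAM/BAM/tabular mapped-read import, sparse per-base coverage |
| `seasight.arrays` | Probe-level microarray import (1/2 channels), probe→feature maps |
| `seasight.quantify` | Read counting, coverage values, RPKM, DCPM, coverage-based locus derivation |
| `seasight.normalize` | Background correction (subtraction, exponential+Gaussian convolution model), quantile/scaling normalization, loess MA normalization, mean/median/median-polish summarization, generic value transforms |
| `seasight.engine` | Transformation matrix: typed data states, validation and state prediction without computation, column-wise execution, config persistence |
| `seasight.synth` | Seeded generators for a two-condition, two-platform study with technical replicates, including ground truth and a ready-made pipeline config |
| `seasight.cli` | `seasight` command-line entry point |

## CLI

Generate a synthetic study bundle, inspect the predicted states, then run
the pipeline:

```sh
seasight synth --out study/ --seed 1
seasight run --config study/config.yaml --out dataset.tsv --dry-run
seasight run --config study/config.yaml --out dataset.tsv
```

Locus algebra and quantification as standalone steps:

```sh
seasight merge-loci --method greedy --max-distance 100 a.gff b.gff --out merged.gff
seasight quantify --reads lane1.sam --loci merged.gff --mode rpkm --out expr.tsv
```

`seasight run --dry-run` (or `seasight states`) validates the whole pipeline
and prints the predicted per-step data states without touching any values;
a full run writes the dataset TSV plus a JSON manifest of sources
(checksummed), executed instances and timing.

## Pipeline configs

A config is a YAML document declaring experiments (source path, format,
column map) and transformation instances (column, transformation name,
parameters, experiment names). `seasight synth` emits a working example:
arrays flow through convolution-model background correction → quantile →
log2 → median-polish summarization, sequencing lanes through locus
attachment → RPKM → logarithmic interval mapping, and a closing quantile
step makes all experiments comparable.

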