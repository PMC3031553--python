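"""Raw microarray probe-level import and probe-to-feature maps.

Binary vendor formats are out of scope; the importer reads generic delimited
text with a configurable dialect plus a column map, which covers the standard
tabular exports of GenePix-, Agilent- and ImaGene-style files.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import ConfigurationError, ParseError
from .loci import Dialect

log = logging.getLogger(__name__)

#: Ready-made column maps mimicking common vendor tabular exports.
COLUMN_MAP_PRESETS = {
    "genepix": {
        "probe_id": "ID",
        "fg": ["F635 Median", "F532 Median"],
        "bg": ["B635 Median", "B532 Median"],
        "block": "Block",
    },
    "agilent": {
        "probe_id": "ProbeName",
        "fg": ["rMedianSignal", "gMedianSignal"],
        "bg": ["rBGMedianSignal", "gBGMedianSignal"],
    },
    "imagene": {"probe_id": "Gene ID", "fg": ["Signal Mean"], "bg": ["Background Mean"]},
}


@dataclass
class ProbeTable:
    """Probe-level intensities for one array (1 or 2 channels).

    ``fg``/``bg`` are DataFrames indexed by probe id with one column per
    channel; ``bg`` is None when no background columns were mapped.
    """

    fg: pd.DataFrame
    bg: Optional[pd.DataFrame] = None
    block: Optional[pd.Series] = None

    @property
    def channels(self) -> int:
        return self.fg.shape[1]

    @property
    def probe_ids(self) -> pd.Index:
        return self.fg.index

    def __len__(self) -> int:
        return len(self.fg)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProbeTable):
            return NotImplemented
        if not self.fg.equals(other.fg):
            return False
        if (self.bg is None) != (other.bg is None):
            return False
        return self.bg is None or self.bg.equals(other.bg)


@dataclass
class ProbesetMap:
    """Many-to-one probe -> feature mapping."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, probe_id: str) -> str:
        return self.mapping[probe_id]

    def get(self, probe_id, default=None):
        return self.mapping.get(probe_id, default)

    def features(self) -> set[str]:
        return set(self.mapping.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProbesetMap):
            return NotImplemented
        return self.mapping == other.mapping


def _as_stream(source):
    if isinstance(source, (str, bytes)):
        text = source.decode() if isinstance(source, bytes) else source
        if "\n" not in text:
            return open(text), True
        return io.StringIO(text), False
    return source, False


def parse_array(
    source,
    column_map: dict,
    dialect: Optional[Dialect] = None,
) -> ProbeTable:
    """Parse a probe-level intensity table.

    ``column_map`` assigns column names: ``probe_id``, ``fg`` (a list with
    one name per channel), optional ``bg`` (same length) and ``block``.
    Channel count is inferred from the mapped fg columns.
    """
    dialect = dialect or Dialect()
    if "probe_id" not in column_map or "fg" not in column_map:
        raise ConfigurationError("column map must assign 'probe_id' and 'fg'")
    fg_cols = column_map["fg"]
    if isinstance(fg_cols, str):
        fg_cols = [fg_cols]
    bg_cols = column_map.get("bg")
    if isinstance(bg_cols, str):
        bg_cols = [bg_cols]
    if bg_cols is not None and len(bg_cols) != len(fg_cols):
        raise ConfigurationError("bg column list must match fg channel count")
    if not 1 <= len(fg_cols) <= 2:
        raise ConfigurationError("1 or 2 fg channels supported")

    stream, close = _as_stream(source)
    try:
        frame = pd.read_csv(
            stream,
            sep=dialect.sep,
            quotechar=dialect.quote,
            comment=dialect.comment or None,
        )
    finally:
        if close:
            stream.close()

    missing = [
        c
        for c in [column_map["probe_id"], *fg_cols, *(bg_cols or [])]
        if c not in frame.columns
    ]
    if missing:
        raise ConfigurationError(f"mapped columns not in file: {missing}")

    ids = frame[column_map["probe_id"]].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ParseError(f"duplicate probe_id {dup.iloc[0]!r}")

    fg = frame[fg_cols].astype(float)
    fg.index = ids
    fg.columns = [f"ch{i + 1}" for i in range(len(fg_cols))]
    if (fg.values < 0).any():
        raise ParseError("negative foreground intensity")
    bg = None
    if bg_cols is not None:
        bg = frame[bg_cols].astype(float)
        bg.index = ids
        bg.columns = fg.columns
        if (bg.values < 0).any():
            raise ParseError("negative background intensity")
    block = None
    if "block" in column_map:
        block = frame[column_map["block"]].astype(int)
        block.index = ids
    return ProbeTable(fg=fg, bg=bg, block=block)


def parse_probeset_map(
    source,
    dialect: Optional[Dialect] = None,
    probe_column: int = 0,
    feature_column: int = 1,
) -> ProbesetMap:
    """Parse a two-column probe -> feature map; many-to-one enforced."""
    from .loci import _iter_rows

    dialect = dialect or Dialect()
    stream, close = _as_stream(source)
    mapping: dict[str, str] = {}
    try:
        for lineno, row in _iter_rows(stream, dialect):
            try:
                probe, feature = row[probe_column], row[feature_column]
            except IndexError:
                raise ParseError("row lacks probe or feature column", lineno)
            if probe in mapping and mapping[probe] != feature:
                raise ParseError(
                    f"probe {probe!r} mapped to both {mapping[probe]!r} and {feature!r}",
                    lineno,
                )
            mapping[probe] = feature
    finally:
        if close:
            stream.close()
    if not mapping:
        log.warning("probeset map is empty")
    return ProbesetMap(mapping)


def write_probeset_map(pmap: ProbesetMap, stream, sep: str = "\t"):
    for probe in sorted(pmap.mapping):
        stream.write(f"{probe}{sep}{pmap.mapping[probe]}\n")
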