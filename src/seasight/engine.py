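"""Transformation-matrix engine.

Experiments are rows, successive transformation steps are columns.  Each cell
holds at most one transformation instance; an instance may occupy several
cells of one column (its experiment set).  A companion state matrix of typed
:class:`DataState` descriptions is maintained so that applicability of a new
instance — and of everything downstream of it — is validated by pure state
prediction, without touching the data.  Execution then walks the columns left
to right; instances within a column touch disjoint experiment sets, so their
order is irrelevant.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import normalize as norm
from .arrays import ProbeTable, parse_array, parse_probeset_map
from .errors import ConfigurationError, SeaSightError, StateError
from .loci import Dialect, LocusSet, parse_loci
from .quantify import (
    coverage_value,
    count_reads,
    dcpm_expression,
    rpkm_expression,
)
from .reads import ReadCollection, build_coverage, parse_reads

log = logging.getLogger(__name__)

CONFIG_VERSION = 1

ENTITIES = ("probe", "probeset", "read", "locus", "identifier")
MEASURES = ("intensity", "ratio", "count", "coverage", "expression")


class MatrixValidationError(SeaSightError):
    """An instance was rejected by state-typed validation."""


@dataclass(frozen=True)
class DataState:
    """Typed description of an experiment's current data semantics."""

    entity: str = "probe"
    channels: int = 1
    scale: str = "linear"
    measure: str = "intensity"
    bg_corrected: bool = False
    normalized: bool = False
    row_count: Optional[int] = None
    loci_attached: bool = False

    def __post_init__(self):
        if self.entity not in ENTITIES:
            raise ValueError(f"unknown entity {self.entity!r}")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 or 2")
        if self.measure == "ratio" and self.entity == "read":
            raise ValueError("ratio measure cannot apply to raw reads")


@dataclass
class Payload:
    """The actual data of one experiment while flowing through the matrix."""

    table: Optional[pd.DataFrame] = None
    reads: Optional[ReadCollection] = None
    loci: Optional[LocusSet] = None
    blocks: Optional[pd.Series] = None

    def value_series(self) -> pd.Series:
        if self.table is None:
            raise StateError("experiment carries no tabular values yet")
        if "value" in self.table.columns:
            return self.table["value"]
        fg = [c for c in self.table.columns if c.startswith("fg_")]
        if len(fg) == 1:
            return self.table[fg[0]]
        raise StateError("experiment has no single value column (multi-channel?)")

    def set_value_series(self, series: pd.Series):
        if self.table is not None and "value" not in self.table.columns:
            fg = [c for c in self.table.columns if c.startswith("fg_")]
            if len(fg) == 1 and series.index.equals(self.table.index):
                self.table[fg[0]] = series
                return
        self.table = pd.DataFrame({"value": series})


@dataclass
class Experiment:
    """One data column of the study: name, typed state and (optionally) data."""

    name: str
    state: DataState
    payload: Optional[Payload] = None
    source: Optional[dict] = None  # how to (re)load the payload from disk

    def __eq__(self, other):
        if not isinstance(other, Experiment):
            return NotImplemented
        return (
            self.name == other.name
            and self.state == other.state
            and self.source == other.source
        )


# ---------------------------------------------------------------------------
# Transformation specs


@dataclass(frozen=True)
class TransformationSpec:
    """A transformation: applicability predicate, state map and executor."""

    name: str
    arity: str  # "per_experiment" | "group"
    accepts: Callable[[DataState, dict], Optional[str]]
    produces: Callable[[DataState, dict, "Context"], DataState]
    apply: Callable[[list[Experiment], dict, "Context"], None]
    defaults: dict = field(default_factory=dict)
    # optional data-level precondition, checked at add_instance time when
    # payloads are loaded (state fields cannot express e.g. bg presence)
    payload_check: Optional[Callable[[Experiment], Optional[str]]] = None


class Context:
    """Shared resolution context: base directory for paths, file caches."""

    def __init__(self, base_dir: Optional[Path] = None):
        self.base_dir = Path(base_dir) if base_dir else Path(".")
        self._loci_cache: dict[str, LocusSet] = {}
        self._map_cache: dict[str, dict] = {}

    def resolve(self, path) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p

    def load_loci(self, params: dict) -> LocusSet:
        if isinstance(params.get("loci"), LocusSet):
            return params["loci"]
        source = params.get("source")
        if source is None:
            raise ConfigurationError("locus step needs 'source' path or inline 'loci'")
        key = str(self.resolve(source))
        if key not in self._loci_cache:
            with open(key) as handle:
                self._loci_cache[key] = parse_loci(
                    handle,
                    format=params.get("format", "gff"),
                    defaults=params.get("defaults"),
                )
        return self._loci_cache[key]

    def load_mapping(self, params: dict) -> Optional[dict]:
        if params.get("mapping") is not None:
            return dict(params["mapping"])
        source = params.get("map_source")
        if source is None:
            return None
        key = str(self.resolve(source))
        if key not in self._map_cache:
            with open(key) as handle:
                self._map_cache[key] = parse_probeset_map(handle).mapping
        return self._map_cache[key]


def _vector(exp: Experiment) -> norm.ValueVector:
    return norm.ValueVector(exp.payload.value_series(), scale=exp.state.scale)


# -- accepts predicates ------------------------------------------------------


def _acc_raw_intensity(state: DataState, params) -> Optional[str]:
    if state.measure != "intensity":
        return f"requires intensity data, got {state.measure}"
    if state.scale != "linear":
        return "requires linear-scale data"
    if state.bg_corrected:
        return (
            "data is already background-corrected; further background "
            "correction is neither possible nor useful"
        )
    return None


def _acc_single_channel(state: DataState, params) -> Optional[str]:
    if state.channels != 1:
        return "requires single-channel values"
    if state.measure == "count" and state.entity == "read":
        return "requires per-feature values, not raw reads"
    return None


def _acc_linear_values(state: DataState, params) -> Optional[str]:
    err = _acc_single_channel(state, params)
    if err:
        return err
    if state.scale != "linear":
        return "requires linear-scale data"
    return None


def _acc_two_channel_linear(state: DataState, params) -> Optional[str]:
    if state.channels != 2:
        return "requires two-channel data"
    if state.scale != "linear":
        return "requires linear-scale intensities"
    if state.measure != "intensity":
        return "requires raw/background-corrected intensities"
    return None


def _acc_reads_with_loci(state: DataState, params) -> Optional[str]:
    if state.entity != "read":
        return "requires mapped-read data"
    if not state.loci_attached:
        return "requires attached locus information"
    return None


# -- apply functions ---------------------------------------------------------


def _apply_bg_subtract(exps, params, ctx):
    floor = params.get("floor", 0.5)
    for exp in exps:
        table = exp.payload.table
        fg_cols = [c for c in table.columns if c.startswith("fg_")]
        for col in fg_cols:
            bg_col = col.replace("fg_", "bg_")
            if bg_col not in table.columns:
                raise StateError(f"{exp.name}: no background column for {col}")
            corrected = norm.bg_subtract(
                norm.ValueVector(table[col]),
                norm.ValueVector(table[bg_col]),
                floor=floor,
            )
            table[col] = corrected.values
        exp.payload.table = table.drop(
            columns=[c for c in table.columns if c.startswith("bg_")]
        )


def _apply_normexp(exps, params, ctx):
    for exp in exps:
        table = exp.payload.table
        for col in [c for c in table.columns if c.startswith("fg_")]:
            fitted = norm.normexp_fit(table[col].to_numpy())
            corrected = norm.normexp_correct(norm.ValueVector(table[col]), fitted)
            table[col] = corrected.values
        if any(c.startswith("bg_") for c in table.columns):
            exp.payload.table = table.drop(
                columns=[c for c in table.columns if c.startswith("bg_")]
            )


def _apply_quantile(exps, params, ctx):
    vectors = [_vector(e) for e in exps]
    out = norm.quantile_normalize(vectors)
    for exp, vec in zip(exps, out):
        exp.payload.set_value_series(vec.values)


def _apply_scale(exps, params, ctx):
    vectors = [_vector(e) for e in exps]
    out = norm.scale_vectors(
        vectors, mode=params.get("mode", "average"), p=params.get("p", 75.0)
    )
    for exp, vec in zip(exps, out):
        exp.payload.set_value_series(vec.values)


def _apply_log2(exps, params, ctx):
    for exp in exps:
        out = norm.log_transform(_vector(exp), offset=params.get("offset", 1.0))
        exp.payload.set_value_series(out.values)


def _apply_interval_map_log(exps, params, ctx):
    shared = params.get("shared_range")
    for exp in exps:
        out = norm.interval_map_log(
            _vector(exp),
            lo=params.get("lo", 0.0),
            hi=params.get("hi", 16.0),
            shared_range=tuple(shared) if shared else None,
        )
        exp.payload.set_value_series(out.values)


def _two_channels(exp):
    table = exp.payload.table
    fg = [c for c in table.columns if c.startswith("fg_")]
    if len(fg) != 2:
        raise StateError(f"{exp.name}: expected 2 channels, found {len(fg)}")
    return norm.ValueVector(table[fg[0]]), norm.ValueVector(table[fg[1]])


def _apply_loess(exps, params, ctx, printtip=False):
    for exp in exps:
        red, green = _two_channels(exp)
        blocks = exp.payload.blocks if printtip else None
        if printtip and blocks is None:
            raise StateError(f"{exp.name}: printtip loess needs block indices")
        m, _a = norm.loess_ma(red, green, span=params.get("span", 0.3), printtip=blocks)
        exp.payload.table = pd.DataFrame({"value": m.values})


def _apply_ma(exps, params, ctx):
    for exp in exps:
        red, green = _two_channels(exp)
        m, a = norm.ma_transform(red, green)
        exp.payload.table = pd.DataFrame({"M": m.values, "A": a.values})


def _apply_dye_swap(exps, params, ctx):
    for exp in exps:
        table = exp.payload.table
        if "M" in table.columns:
            table["M"] = -table["M"]
        else:
            exp.payload.set_value_series(-exp.payload.value_series())


def _apply_summarize(exps, params, ctx):
    mapping = ctx.load_mapping(params)
    if mapping is None:
        raise ConfigurationError("summarize needs 'mapping' or 'map_source'")
    table = pd.DataFrame({e.name: e.payload.value_series() for e in exps})
    groups = pd.Series(mapping)
    summarized = norm.summarize(
        table, groups.reindex(table.index), method=params.get("method", "median_polish")
    )
    for exp in exps:
        exp.payload.table = pd.DataFrame({"value": summarized[exp.name]})


def _apply_attach_loci(exps, params, ctx):
    loci = ctx.load_loci(params)
    for exp in exps:
        exp.payload.loci = loci


def _apply_count(exps, params, ctx):
    mode = params.get("mode", "rpkm")
    rule = params.get("rule", "overlap_any")
    for exp in exps:
        loci = exp.payload.loci
        reads = exp.payload.reads
        if loci is None or reads is None:
            raise StateError(f"{exp.name}: counting needs reads and attached loci")
        if mode == "naive":
            expr = count_reads(reads, loci, rule=rule)
        elif mode == "rpkm":
            expr = rpkm_expression(reads, loci, rule=rule)
        elif mode == "coverage":
            expr = coverage_value(build_coverage(reads), loci)
        elif mode == "dcpm":
            expr = dcpm_expression(build_coverage(reads), loci, reads.total_mapped)
        else:
            raise ConfigurationError(f"unknown counting mode {mode!r}")
        values = pd.Series(expr.by_id(), dtype=float).sort_index()
        exp.payload.table = pd.DataFrame({"value": values})


def _apply_map_identifiers(exps, params, ctx):
    mapping = ctx.load_mapping(params)
    for exp in exps:
        out = norm.map_identifiers(_vector(exp), mapping)
        exp.payload.table = pd.DataFrame({"value": out.values})


# -- produces functions ------------------------------------------------------


def _prod_bg(state, params, ctx):
    return replace(state, bg_corrected=True)


def _prod_same(state, params, ctx):
    return state


def _prod_normalized(state, params, ctx):
    return replace(state, normalized=True)


def _prod_log(state, params, ctx):
    return replace(state, scale="log")


def _prod_interval_map(state, params, ctx):
    return replace(state, scale="log", normalized=True)


def _prod_loess(state, params, ctx):
    return replace(state, channels=1, scale="log", measure="ratio", normalized=True)


def _prod_ma(state, params, ctx):
    return replace(state, scale="log", measure="ratio")


def _prod_summarize(state, params, ctx):
    mapping = ctx.load_mapping(params)
    rows = len(set(mapping.values())) if mapping else state.row_count
    return replace(state, entity="probeset", row_count=rows)


def _prod_attach_loci(state, params, ctx):
    return replace(state, loci_attached=True)


def _prod_count(state, params, ctx):
    mode = params.get("mode", "rpkm")
    measure = {"naive": "count", "coverage": "coverage"}.get(mode, "expression")
    try:
        rows = len(ctx.load_loci(params))
    except (ConfigurationError, FileNotFoundError):
        rows = None
    return replace(
        state, entity="locus", channels=1, scale="linear", measure=measure,
        row_count=rows, loci_attached=True,
    )


def _prod_map_identifiers(state, params, ctx):
    mapping = ctx.load_mapping(params)
    rows = state.row_count
    if mapping:
        rows = None  # depends on which ids are present; resolved at execution
    return replace(state, entity="identifier", row_count=rows)


def _acc_summarize(state, params) -> Optional[str]:
    err = _acc_single_channel(state, params)
    if err:
        return err
    if state.entity != "probe":
        return "summarization applies to probe-level data"
    if params.get("method", "median_polish") == "median_polish" and state.scale != "log":
        return "median polish expects log-scale data"
    return None


def _acc_attach_loci(state, params) -> Optional[str]:
    if state.entity not in ("read", "probe", "probeset", "identifier"):
        return "cannot attach loci to this entity"
    return None


def _acc_count(state, params) -> Optional[str]:
    err = _acc_reads_with_loci(state, params)
    if err:
        return err
    return None


CATALOG: dict[str, TransformationSpec] = {}


def _register(spec: TransformationSpec):
    CATALOG[spec.name] = spec
    return spec


def _has_background(exp: Experiment) -> Optional[str]:
    table = exp.payload.table
    if table is None or not any(c.startswith("bg_") for c in table.columns):
        return "background subtraction needs background columns"
    return None


_register(TransformationSpec(
    "bg_subtract", "per_experiment", _acc_raw_intensity, _prod_bg, _apply_bg_subtract,
    defaults={"floor": 0.5}, payload_check=_has_background))
_register(TransformationSpec(
    "normexp", "per_experiment", _acc_raw_intensity, _prod_bg, _apply_normexp))
_register(TransformationSpec(
    "quantile", "group", _acc_single_channel, _prod_normalized, _apply_quantile))
_register(TransformationSpec(
    "scale", "group", _acc_linear_values, _prod_normalized, _apply_scale,
    defaults={"mode": "average", "p": 75.0}))
_register(TransformationSpec(
    "log2", "per_experiment", _acc_linear_values, _prod_log, _apply_log2,
    defaults={"offset": 1.0}))
_register(TransformationSpec(
    "interval_map_log", "per_experiment", _acc_linear_values, _prod_interval_map,
    _apply_interval_map_log, defaults={"lo": 0.0, "hi": 16.0}))
_register(TransformationSpec(
    "loess", "per_experiment", _acc_two_channel_linear, _prod_loess, _apply_loess))
_register(TransformationSpec(
    "printtip_loess", "per_experiment", _acc_two_channel_linear, _prod_loess,
    lambda e, p, c: _apply_loess(e, p, c, printtip=True)))
_register(TransformationSpec(
    "ma_transform", "per_experiment", _acc_two_channel_linear, _prod_ma, _apply_ma))
_register(TransformationSpec(
    "dye_swap", "per_experiment",
    lambda s, p: None if s.measure == "ratio" else "dye swap requires ratio data",
    _prod_same, _apply_dye_swap))
_register(TransformationSpec(
    "summarize", "group", _acc_summarize, _prod_summarize, _apply_summarize,
    defaults={"method": "median_polish"}))
_register(TransformationSpec(
    "attach_loci", "per_experiment", _acc_attach_loci, _prod_attach_loci,
    _apply_attach_loci))
_register(TransformationSpec(
    "count", "per_experiment", _acc_count, _prod_count, _apply_count,
    defaults={"mode": "rpkm", "rule": "overlap_any"}))
_register(TransformationSpec(
    "map_identifiers", "per_experiment", _acc_single_channel, _prod_map_identifiers,
    _apply_map_identifiers))


# ---------------------------------------------------------------------------
# Matrix


@dataclass
class TransformationInstance:
    """One application of a transformation to a set of experiments at a column."""

    spec_name: str
    column: int
    experiments: tuple[str, ...]
    params: dict = field(default_factory=dict)

    @property
    def spec(self) -> TransformationSpec:
        try:
            return CATALOG[self.spec_name]
        except KeyError:
            raise ConfigurationError(f"unknown transformation {self.spec_name!r}")

    def merged_params(self) -> dict:
        return {**self.spec.defaults, **self.params}

    def __eq__(self, other):
        if not isinstance(other, TransformationInstance):
            return NotImplemented
        return (
            self.spec_name == other.spec_name
            and self.column == other.column
            and set(self.experiments) == set(other.experiments)
            and self.params == other.params
        )


@dataclass
class ValidationReport:
    ok: bool
    message: str = ""
    states: Optional["StateMatrix"] = None


class StateMatrix:
    """n experiments x (m+1) columns of predicted DataStates."""

    def __init__(self, experiment_names: Sequence[str], columns: list[dict]):
        self.experiment_names = list(experiment_names)
        self.columns = columns  # list of {exp_name: DataState}

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def state(self, experiment: str, column: int) -> DataState:
        return self.columns[column][experiment]

    def final(self, experiment: str) -> DataState:
        return self.columns[-1][experiment]

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name in self.experiment_names:
            rows[name] = {
                j: (
                    f"{s.entity}/{s.channels}ch/{s.scale}/{s.measure}"
                    + ("/bg" if s.bg_corrected else "")
                    + ("/norm" if s.normalized else "")
                    + (f"/{s.row_count}rows" if s.row_count is not None else "")
                )
                for j, col in enumerate(self.columns)
                for s in [col[name]]
            }
        return pd.DataFrame.from_dict(rows, orient="index")


class TransformationMatrix:
    """The grid of experiments x steps holding transformation instances."""

    def __init__(self, experiments: Sequence[Experiment], context: Optional[Context] = None):
        names = [e.name for e in experiments]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate experiment names")
        self.experiments: list[Experiment] = list(experiments)
        self.instances: list[TransformationInstance] = []
        self.context = context or Context()

    # -- structure ----------------------------------------------------------

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def n_columns(self) -> int:
        return max((i.column + 1 for i in self.instances), default=0)

    def experiment(self, name: str) -> Experiment:
        for exp in self.experiments:
            if exp.name == name:
                return exp
        raise ConfigurationError(f"unknown experiment {name!r}")

    def column_instances(self, column: int) -> list[TransformationInstance]:
        return [i for i in self.instances if i.column == column]

    def cell(self, experiment: str, column: int) -> Optional[TransformationInstance]:
        for inst in self.column_instances(column):
            if experiment in inst.experiments:
                return inst
        return None

    def __eq__(self, other):
        if not isinstance(other, TransformationMatrix):
            return NotImplemented
        return (
            self.experiments == other.experiments
            and sorted(self.instances, key=lambda i: (i.column, i.experiments))
            == sorted(other.instances, key=lambda i: (i.column, i.experiments))
        )

    # -- validation and prediction ------------------------------------------

    def predict_states(self) -> StateMatrix:
        """Pure state prediction: no value computation is performed."""
        current = {e.name: e.state for e in self.experiments}
        columns = [dict(current)]
        for j in range(self.n_columns):
            for inst in self.column_instances(j):
                spec = inst.spec
                params = inst.merged_params()
                for name in inst.experiments:
                    err = spec.accepts(current[name], params)
                    if err:
                        raise MatrixValidationError(
                            f"column {j}, {spec.name!r} on {name!r}: {err}"
                        )
                    current[name] = spec.produces(current[name], params, self.context)
            columns.append(dict(current))
        return StateMatrix([e.name for e in self.experiments], columns)

    def add_instance(
        self,
        column: int,
        experiments: Sequence[str],
        spec_name: str,
        params: Optional[dict] = None,
    ) -> ValidationReport:
        """Validate and insert an instance; rejected instances leave the
        matrix untouched and raise :class:`MatrixValidationError`."""
        if spec_name not in CATALOG:
            raise ConfigurationError(f"unknown transformation {spec_name!r}")
        spec = CATALOG[spec_name]
        if column < 0 or column > self.n_columns:
            raise MatrixValidationError(
                f"column {column} out of range (0..{self.n_columns})"
            )
        names = list(dict.fromkeys(experiments))
        if not names:
            raise MatrixValidationError("instance needs at least one experiment")
        for name in names:
            self.experiment(name)  # existence check
        if spec.arity == "group" and len(names) < 2:
            raise MatrixValidationError(
                f"{spec_name!r} operates on a group and needs >= 2 experiments"
            )
        for name in names:
            occupant = self.cell(name, column)
            if occupant is not None:
                raise MatrixValidationError(
                    f"cell ({name!r}, column {column}) already occupied by "
                    f"{occupant.spec_name!r}"
                )
        instance = TransformationInstance(
            spec_name=spec_name,
            column=column,
            experiments=tuple(names),
            params=dict(params or {}),
        )
        self.instances.append(instance)
        try:
            states = self.predict_states()
            if spec.payload_check is not None:
                for name in names:
                    exp = self.experiment(name)
                    if exp.payload is not None:
                        err = spec.payload_check(exp)
                        if err:
                            raise MatrixValidationError(
                                f"{spec_name!r} on {name!r}: {err}"
                            )
        except MatrixValidationError:
            self.instances.pop()
            raise
        return ValidationReport(ok=True, states=states)

    # -- execution ----------------------------------------------------------

    def execute(self, assembly: str = "union") -> "Dataset":
        """Run all instances column by column and assemble the final dataset."""
        if assembly not in ("union", "intersection"):
            raise ConfigurationError(f"unknown assembly mode {assembly!r}")
        predicted = self.predict_states()  # validates the whole matrix up front
        for exp in self.experiments:
            if exp.payload is None:
                raise StateError(f"experiment {exp.name!r} has no data loaded")
        # work on copies so execute() is repeatable and pure w.r.t. inputs
        work = {
            e.name: Experiment(e.name, e.state, _copy_payload(e.payload), e.source)
            for e in self.experiments
        }
        for j in range(self.n_columns):
            for inst in self.column_instances(j):
                spec = inst.spec
                exps = [work[name] for name in inst.experiments]
                params = inst.merged_params()
                try:
                    spec.apply(exps, params, self.context)
                except SeaSightError:
                    raise
                except Exception as exc:  # surface the failing instance
                    raise StateError(
                        f"column {j}, {spec.name!r} on {inst.experiments}: {exc}"
                    ) from exc
                for exp in exps:
                    exp.state = spec.produces(exp.state, params, self.context)
        final_states = {name: work[name].state for name in work}
        entities = {s.entity for s in final_states.values()}
        scales = {s.scale for s in final_states.values()}
        if len(entities) > 1 or len(scales) > 1:
            detail = {n: f"{s.entity}/{s.scale}" for n, s in final_states.items()}
            raise StateError(
                f"final states are not assembly-compatible: {detail}"
            )
        series = {}
        loci_map = None
        for exp in self.experiments:
            w = work[exp.name]
            series[exp.name] = w.payload.value_series()
            if loci_map is None and w.payload.loci is not None:
                loci_map = {
                    (l.id or f"{l.chromosome}:{l.start}-{l.end}"): l
                    for l in w.payload.loci
                }
        frame = pd.DataFrame(series)
        if assembly == "intersection":
            frame = frame.dropna()
        frame = frame.sort_index()
        observed = {
            name: replace(final_states[name], row_count=int(work[name].payload.value_series().notna().sum()))
            for name in work
        }
        return Dataset(values=frame, loci=loci_map, final_states=observed)


def _copy_payload(payload: Payload) -> Payload:
    return Payload(
        table=None if payload.table is None else payload.table.copy(),
        reads=payload.reads,  # reads are never mutated by transformations
        loci=payload.loci,
        blocks=None if payload.blocks is None else payload.blocks.copy(),
    )


@dataclass
class Dataset:
    """Final features x experiments value matrix with optional locus annotation."""

    values: pd.DataFrame
    loci: Optional[dict] = None
    final_states: Optional[dict] = None

    def write_tsv(self, stream):
        frame = self.values.copy()
        if self.loci:
            ann = {}
            for feature in frame.index:
                locus = self.loci.get(feature)
                if locus is not None:
                    ann[feature] = (locus.chromosome, locus.start, locus.end, locus.strand)
            if ann:
                meta = pd.DataFrame.from_dict(
                    ann, orient="index", columns=["chrom", "start", "end", "strand"]
                ).reindex(frame.index)
                frame = pd.concat([meta, frame], axis=1)
        frame.index.name = "feature_id"
        frame.to_csv(stream, sep="\t", na_rep="NA", lineterminator="\n")


# ---------------------------------------------------------------------------
# Persistence


def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _state_to_dict(state: DataState) -> dict:
    return {
        "entity": state.entity,
        "channels": state.channels,
        "scale": state.scale,
        "measure": state.measure,
        "bg_corrected": state.bg_corrected,
        "normalized": state.normalized,
        "row_count": state.row_count,
        "loci_attached": state.loci_attached,
    }


def save_config(matrix: TransformationMatrix, target) -> None:
    """Persist the matrix configuration (instances + source references).

    Bulk data is persisted by reference: each experiment records its source
    path plus a content checksum rather than embedding the values.
    """
    doc = {
        "version": CONFIG_VERSION,
        "experiments": [],
        "instances": [],
    }
    for exp in matrix.experiments:
        entry = {
            "name": exp.name,
            "state": _state_to_dict(exp.state),
            "source": copy.deepcopy(exp.source),
        }
        if exp.source and exp.source.get("path"):
            path = matrix.context.resolve(exp.source["path"])
            if path.exists() and "checksum" not in entry["source"]:
                entry["source"]["checksum"] = _checksum(path)
        doc["experiments"].append(entry)
    for inst in sorted(matrix.instances, key=lambda i: (i.column, i.experiments)):
        doc["instances"].append(
            {
                "column": inst.column,
                "transformation": inst.spec_name,
                "experiments": list(inst.experiments),
                "params": _clean_params(inst.params),
            }
        )
    text = yaml.safe_dump(doc, sort_keys=False)
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)


def _clean_params(params: dict) -> dict:
    out = {}
    for key, value in params.items():
        if isinstance(value, LocusSet):
            raise ConfigurationError(
                "cannot persist an inline LocusSet; use a 'source' path instead"
            )
        out[key] = value
    return out


def load_config(source, base_dir: Optional[Path] = None, load_data: bool = False) -> TransformationMatrix:
    """Reconstruct a matrix from a config document.

    With ``load_data`` the experiment payloads are parsed from their source
    references; a dangling source path is an error either way.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
        if base_dir is None:
            base_dir = Path(".")
    else:
        path = Path(source)
        doc = yaml.safe_load(path.read_text())
        if base_dir is None:
            base_dir = path.parent
    if not isinstance(doc, dict) or doc.get("version") != CONFIG_VERSION:
        raise ConfigurationError(
            f"config version mismatch: expected {CONFIG_VERSION}, got {doc.get('version')!r}"
        )
    context = Context(base_dir)
    experiments = []
    for entry in doc.get("experiments", []):
        state = DataState(**entry["state"])
        exp = Experiment(name=entry["name"], state=state, source=entry.get("source"))
        if exp.source and exp.source.get("path"):
            path = context.resolve(exp.source["path"])
            if not path.exists():
                raise ConfigurationError(
                    f"experiment {exp.name!r}: source file not found: {path}"
                )
            recorded = exp.source.get("checksum")
            if recorded and recorded != _checksum(path):
                log.warning("experiment %s: source checksum changed: %s", exp.name, path)
        if load_data:
            exp.payload = load_payload(exp, context)
            exp.state = replace(exp.state, row_count=_payload_rows(exp.payload))
        experiments.append(exp)
    matrix = TransformationMatrix(experiments, context=context)
    for entry in doc.get("instances", []):
        name = entry.get("transformation")
        if name not in CATALOG:
            raise ConfigurationError(f"unknown transformation {name!r} in config")
        matrix.instances.append(
            TransformationInstance(
                spec_name=name,
                column=int(entry["column"]),
                experiments=tuple(entry["experiments"]),
                params=dict(entry.get("params") or {}),
            )
        )
    matrix.predict_states()  # full validation of the reloaded pipeline
    return matrix


def _payload_rows(payload: Payload) -> Optional[int]:
    if payload.table is not None:
        return len(payload.table)
    if payload.reads is not None:
        return payload.reads.total_mapped
    return None


# ---------------------------------------------------------------------------
# Experiment construction helpers


def probe_experiment(name: str, table: ProbeTable) -> Experiment:
    """Wrap a parsed probe table as a matrix row in its post-parse state."""
    frame = table.fg.copy()
    frame.columns = [f"fg_{c}" for c in frame.columns]
    if table.bg is not None:
        bg = table.bg.copy()
        bg.columns = [f"bg_{c}" for c in bg.columns]
        frame = pd.concat([frame, bg], axis=1)
    state = DataState(
        entity="probe",
        channels=table.channels,
        scale="linear",
        measure="intensity",
        row_count=len(table),
    )
    return Experiment(
        name=name,
        state=state,
        payload=Payload(table=frame, blocks=table.block),
    )


def read_experiment(name: str, collection: ReadCollection) -> Experiment:
    state = DataState(
        entity="read",
        channels=1,
        scale="linear",
        measure="count",
        row_count=collection.total_mapped,
    )
    return Experiment(name=name, state=state, payload=Payload(reads=collection))


def value_experiment(
    name: str, values: pd.Series, entity: str = "identifier",
    scale: str = "linear", measure: str = "expression",
) -> Experiment:
    state = DataState(
        entity=entity, channels=1, scale=scale, measure=measure, row_count=len(values)
    )
    return Experiment(
        name=name, state=state, payload=Payload(table=pd.DataFrame({"value": values}))
    )


def load_payload(exp: Experiment, context: Context) -> Payload:
    """Parse an experiment's payload from its source reference."""
    source = exp.source or {}
    fmt = source.get("format")
    path = context.resolve(source["path"])
    dialect_spec = source.get("dialect") or {}
    dialect = Dialect(**dialect_spec) if dialect_spec else Dialect()
    if fmt in ("sam", "bam"):
        collection = parse_reads(path, format=fmt, defaults=source.get("defaults"))
        return Payload(reads=collection)
    if fmt == "reads_tabular":
        with open(path) as handle:
            collection = parse_reads(
                handle, format="tabular",
                column_map=source.get("column_map"),
                defaults=source.get("defaults"), dialect=dialect,
            )
        return Payload(reads=collection)
    if fmt == "array_tabular":
        with open(path) as handle:
            table = parse_array(handle, column_map=source["column_map"], dialect=dialect)
        return probe_experiment(exp.name, table).payload
    raise ConfigurationError(f"experiment {exp.name!r}: unknown source format {fmt!r}")
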