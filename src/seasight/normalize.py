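"""Transformation catalog: background correction, inter-array and two-channel
normalization, summarization and generic value transforms.

Vectors are pandas Series keyed by feature id, wrapped in :class:`ValueVector`
with a linear/log scale tag.  Log base is 2 throughout; count-derived values
use a pseudo-count of 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DomainError, FitError, ParameterError, StateError

log = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class ValueVector:
    """One experiment/channel of per-feature values with a scale tag."""

    values: pd.Series
    scale: str = "linear"  # "linear" | "log"

    def __post_init__(self):
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        self.values = self.values.astype(float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def index(self) -> pd.Index:
        return self.values.index


def _require_scale(vector: ValueVector, scale: str, op: str):
    if vector.scale != scale:
        raise StateError(f"{op} requires {scale}-scale input, got {vector.scale}")


def _require_same_features(vectors: Sequence[ValueVector]):
    base = set(vectors[0].index)
    for i, v in enumerate(vectors[1:], start=2):
        other = set(v.index)
        if other != base:
            diff = sorted(base.symmetric_difference(other))[:5]
            raise ParameterError(
                f"vector {i} has a different feature set (e.g. {diff})"
            )


# ---------------------------------------------------------------------------
# Background correction


def bg_subtract(fg: ValueVector, bg: ValueVector, floor: float = 0.5) -> ValueVector:
    """Foreground minus background, floored at a small positive constant."""
    _require_scale(fg, "linear", "bg_subtract")
    _require_scale(bg, "linear", "bg_subtract")
    _require_same_features([fg, bg])
    corrected = (fg.values - bg.values.reindex(fg.index)).clip(lower=floor)
    return ValueVector(corrected, scale="linear")


@dataclass(frozen=True)
class NormexpParams:
    """Convolution model: observed = Exponential(mean alpha) + Normal(mu, sigma^2)."""

    alpha: float
    mu: float
    sigma: float

    def __post_init__(self):
        if self.alpha <= 0 or self.sigma <= 0:
            raise DomainError(
                f"normexp requires alpha > 0 and sigma > 0, got {self.alpha}, {self.sigma}"
            )


def _normexp_nll(theta, x):
    log_alpha, mu, log_sigma = theta
    alpha, sigma = math.exp(log_alpha), math.exp(log_sigma)
    z = (x - mu) / sigma - sigma / alpha
    ll = -log_alpha + sigma * sigma / (2 * alpha * alpha) - (x - mu) / alpha + log_ndtr(z)
    return -ll.sum()


def normexp_fit(observed, refine: bool = True) -> NormexpParams:
    """Fit the exponential-plus-Gaussian convolution model.

    Estimation scheme: method-of-moments start — alpha from the third
    central moment (the Gaussian part is symmetric, so skewness is carried
    entirely by the exponential signal: m3 = 2*alpha^3), mu as the mean
    excess over alpha, sigma^2 as the residual variance — then, by default,
    refinement by maximizing the closed-form convolution likelihood from
    that start.  The refinement is required for sigma, whose moment
    estimate is unusable when alpha >> sigma.
    """
    x = np.asarray(
        observed.values if isinstance(observed, ValueVector) else observed, dtype=float
    )
    if x.size < 100:
        log.warning("normexp_fit: only %d observations, estimates will be noisy", x.size)
    if x.size < 4 or np.ptp(x) == 0:
        raise FitError("degenerate (constant or near-empty) input")
    m1 = x.mean()
    m2 = x.var()
    m3 = ((x - m1) ** 3).mean()
    alpha0 = max(np.cbrt(max(m3, 1e-12) / 2.0), 1e-6)
    mu0 = m1 - alpha0
    sigma0 = math.sqrt(max(m2 - alpha0 * alpha0, 1e-6))
    if not refine:
        return NormexpParams(alpha=float(alpha0), mu=float(mu0), sigma=float(sigma0))
    result = minimize(
        _normexp_nll,
        [math.log(alpha0), mu0, math.log(max(sigma0, 1e-3))],
        args=(x,),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    alpha = float(math.exp(result.x[0]))
    mu = float(result.x[1])
    sigma = float(math.exp(result.x[2]))
    if alpha < 0.05 * sigma:
        log.warning("normexp_fit: alpha near zero (%.3g); signal may be absent", alpha)
    return NormexpParams(alpha=alpha, mu=mu, sigma=sigma)


def normexp_correct(observed: ValueVector, params: NormexpParams) -> ValueVector:
    """Replace each value by E[signal | observed] under the convolution model.

    The posterior of the signal given an observation x is a Gaussian with
    mean x - mu - sigma^2/alpha and sd sigma, truncated to (0, inf); its
    mean is strictly positive and monotone in x.
    """
    _require_scale(observed, "linear", "normexp_correct")
    x = observed.values.to_numpy(dtype=float)
    shifted = x - params.mu - params.sigma**2 / params.alpha
    z = shifted / params.sigma
    # sigma * phi(z)/Phi(z), evaluated in log space for stability
    tail = params.sigma * np.exp(-0.5 * z * z - _LOG_SQRT_2PI - log_ndtr(z))
    corrected = shifted + tail
    return ValueVector(pd.Series(corrected, index=observed.index), scale="linear")


# ---------------------------------------------------------------------------
# Inter-array normalization


def _quantile_target(matrix: np.ndarray) -> np.ndarray:
    return np.sort(matrix, axis=0).mean(axis=1)


def quantile_normalize(
    vectors: Sequence[ValueVector], reference: Optional[ValueVector] = None
) -> list[ValueVector]:
    """Force identical empirical distributions across vectors.

    The value at rank r in each vector is replaced by the across-vector
    mean of rank-r values (or the reference's rank-r value); tied values
    get the mean of their spanned rank values.
    """
    if reference is None and len(vectors) < 2:
        raise ParameterError("quantile normalization needs >= 2 vectors or a reference")
    _require_same_features(list(vectors) + ([reference] if reference is not None else []))
    index = vectors[0].index
    matrix = np.column_stack([v.values.reindex(index).to_numpy() for v in vectors])
    if reference is not None:
        target = np.sort(reference.values.reindex(index).to_numpy())
    else:
        target = _quantile_target(matrix)
    n = matrix.shape[0]
    out = []
    for j, vector in enumerate(vectors):
        column = matrix[:, j]
        # average ranks (1-based); ties -> fractional ranks -> interpolate target
        ranks = pd.Series(column).rank(method="average").to_numpy()
        new = np.interp(ranks, np.arange(1, n + 1), target)
        out.append(ValueVector(pd.Series(new, index=index), scale=vector.scale))
    return out


def scale_vectors(
    vectors: Sequence[ValueVector], mode: str = "average", p: float = 75.0
) -> list[ValueVector]:
    """Rescale each vector so its mean (or p-th percentile) matches the
    across-vector mean of that statistic."""
    if mode not in ("average", "percentile"):
        raise ParameterError(f"unknown scaling mode {mode!r}")
    if mode == "percentile" and not 0 < p < 100:
        raise ParameterError(f"percentile must be in (0, 100), got {p}")
    for v in vectors:
        _require_scale(v, "linear", "scale")
    stats = []
    for v in vectors:
        stat = (
            float(v.values.mean())
            if mode == "average"
            else float(np.percentile(v.values.to_numpy(), p))
        )
        if stat == 0:
            raise DomainError(f"zero {mode} statistic; cannot rescale")
        stats.append(stat)
    grand = float(np.mean(stats))
    return [
        ValueVector(v.values * (grand / stat), scale=v.scale)
        for v, stat in zip(vectors, stats)
    ]


# ---------------------------------------------------------------------------
# Two-channel normalization


def ma_transform(red: ValueVector, green: ValueVector) -> tuple[ValueVector, ValueVector]:
    """(R, G) -> (M, A) with M = log2(R/G) and A = mean log2 intensity."""
    _require_scale(red, "linear", "ma_transform")
    _require_scale(green, "linear", "ma_transform")
    _require_same_features([red, green])
    r = red.values.to_numpy(dtype=float)
    g = green.values.reindex(red.index).to_numpy(dtype=float)
    if (r <= 0).any() or (g <= 0).any():
        raise DomainError("MA transform requires strictly positive intensities")
    m = np.log2(r / g)
    a = 0.5 * np.log2(r * g)
    idx = red.index
    return (
        ValueVector(pd.Series(m, index=idx), scale="log"),
        ValueVector(pd.Series(a, index=idx), scale="log"),
    )


def loess_ma(
    red: ValueVector,
    green: ValueVector,
    span: float = 0.3,
    printtip: Optional[pd.Series] = None,
    min_block: int = 10,
) -> tuple[ValueVector, ValueVector]:
    """Loess-normalize a two-channel array in MA space.

    Returns (M - loess_fit(A), A).  With ``printtip`` block indices an
    independent fit is done per block; blocks smaller than ``min_block``
    fall back to the global fit with a warning.
    """
    m_vec, a_vec = ma_transform(red, green)
    m = m_vec.values.to_numpy()
    a = a_vec.values.to_numpy()

    def fit(mask):
        return lowess(m[mask], a[mask], frac=span, return_sorted=False)

    residual = np.empty_like(m)
    if printtip is None:
        residual = m - fit(np.ones(len(m), dtype=bool))
    else:
        blocks = printtip.reindex(m_vec.index).to_numpy()
        global_fit = None
        for block in np.unique(blocks):
            mask = blocks == block
            if mask.sum() < min_block:
                log.warning(
                    "printtip block %s has %d < %d features; using global fit",
                    block, int(mask.sum()), min_block,
                )
                if global_fit is None:
                    global_fit = m - fit(np.ones(len(m), dtype=bool))
                residual[mask] = global_fit[mask]
            else:
                residual[mask] = m[mask] - fit(mask)
    return (
        ValueVector(pd.Series(residual, index=m_vec.index), scale="log"),
        a_vec,
    )


def dye_swap(m_vector: ValueVector) -> ValueVector:
    """Exchange the two channels: M -> -M."""
    _require_scale(m_vector, "log", "dye_swap")
    return ValueVector(-m_vector.values, scale="log")


# ---------------------------------------------------------------------------
# Summarization


def median_polish(
    matrix: np.ndarray, tol: float = 1e-4, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish (rows swept before columns).

    Returns (overall, row_effects, col_effects, residuals).
    """
    residual = np.asarray(matrix, dtype=float).copy()
    nrow, ncol = residual.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    for _ in range(max_iter):
        rdelta = np.median(residual, axis=1)
        residual -= rdelta[:, None]
        row_eff += rdelta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        cdelta = np.median(residual, axis=0)
        residual -= cdelta[None, :]
        col_eff += cdelta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        change = max(np.abs(rdelta).max(initial=0.0), np.abs(cdelta).max(initial=0.0))
        if change < tol:
            break
    return overall, row_eff, col_eff, residual


def summarize(
    table: pd.DataFrame,
    groups: pd.Series,
    method: str = "median_polish",
    tol: float = 1e-4,
    max_iter: int = 10,
) -> pd.DataFrame:
    """Summarize probe rows into one value per feature per experiment.

    ``table`` is probes x experiments; ``groups`` maps probe id -> feature
    id.  ``median_polish`` reports overall + column effect per feature (the
    RMA convention, expects log-scale input); ``mean``/``median`` are
    column-wise per group.
    """
    if method not in ("mean", "median", "median_polish"):
        raise ParameterError(f"unknown summarization method {method!r}")
    groups = groups.reindex(table.index)
    known = groups.notna()
    if not known.all():
        log.warning("summarize: %d probes lack a feature mapping, dropped", int((~known).sum()))
    table = table.loc[known]
    groups = groups.loc[known]
    rows = {}
    for feature, probe_index in table.groupby(groups, sort=True).groups.items():
        block = table.loc[probe_index]
        if block.empty:
            log.warning("summarize: empty group %s skipped", feature)
            continue
        if method == "mean":
            rows[feature] = block.mean(axis=0)
        elif method == "median":
            rows[feature] = block.median(axis=0)
        else:
            overall, _rows, cols, _resid = median_polish(
                block.to_numpy(), tol=tol, max_iter=max_iter
            )
            rows[feature] = pd.Series(overall + cols, index=table.columns)
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        sorted(rows), table.columns
    ]


# ---------------------------------------------------------------------------
# Generic value transforms


def log_transform(vector: ValueVector, offset: float = 1.0) -> ValueVector:
    """value -> log2(value + offset)."""
    _require_scale(vector, "linear", "log2")
    x = vector.values.to_numpy()
    if (x + offset <= 0).any():
        raise DomainError("log2 requires value + offset > 0")
    return ValueVector(pd.Series(np.log2(x + offset), index=vector.index), scale="log")


def interval_map_log(
    vector: ValueVector,
    lo: float = 0.0,
    hi: float = 16.0,
    shared_range: Optional[tuple[float, float]] = None,
) -> ValueVector:
    """Map values logarithmically onto [lo, hi].

    y = lo + (hi-lo) * (log2(x+1) - m) / (M - m) with m, M the min/max of
    log2(x+1) over the vector, or a caller-supplied shared range for
    cross-experiment comparability.
    """
    _require_scale(vector, "linear", "interval_map_log")
    x = vector.values.to_numpy()
    if (x < 0).any():
        raise DomainError("interval_map_log requires non-negative input")
    logged = np.log2(x + 1.0)
    if shared_range is not None:
        m, big_m = shared_range
    else:
        m, big_m = float(logged.min()), float(logged.max())
    if big_m == m:
        log.warning("interval_map_log: constant vector, mapping everything to lo")
        mapped = np.full_like(logged, lo)
    else:
        mapped = lo + (hi - lo) * (logged - m) / (big_m - m)
    return ValueVector(pd.Series(mapped, index=vector.index), scale="log")


def map_identifiers(
    vector: ValueVector, mapping: Optional[dict] = None
) -> ValueVector:
    """Replace feature ids via a map; collisions are aggregated by mean.

    ``mapping=None`` keeps ids unchanged (pure re-typing of the entity).
    """
    if mapping is None:
        return replace(vector, values=vector.values.copy())
    mapped = vector.values.rename(index=lambda k: mapping.get(k, k))
    dropped = vector.values.index.difference(list(mapping))
    if len(dropped):
        log.debug("map_identifiers: %d ids passed through unmapped", len(dropped))
    aggregated = mapped.groupby(level=0).mean()
    return ValueVector(aggregated, scale=vector.scale)
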