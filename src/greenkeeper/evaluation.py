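"""Summary metrics: nitrogen budgets, NUE, percent reductions, the
clipping-to-quality map, prediction-ratio statistics, and the NDRE-clipping
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import NitrogenCycleParams

__all__ = [
    "QualityMap",
    "DEFAULT_QUALITY_MAP",
    "NBudgetSummary",
    "RatioStats",
    "CorrelationResult",
    "quality_from_clipping",
    "nitrogen_use_efficiency",
    "n_budget",
    "percent_reduction",
    "ratio_stats",
    "ndre_clipping_correlation",
]


@dataclass(frozen=True)
class QualityMap:
    """Piecewise-linear map from daily clipping yield to visual quality (1-9).

    Anchored at observed (yield, quality) pairs.  Below the lowest anchor the
    map interpolates down to (0 yield, floor quality) -- no growth means dead
    turf; above the highest anchor the last segment's slope is extended
    before clipping to the ceiling.
    """

    anchors: Tuple[Tuple[float, float], ...] = ((1.25, 6.0), (1.6, 7.0))
    floor: float = 1.0
    ceiling: float = 9.0

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least two anchor points")
        ys = [a[0] for a in self.anchors]
        qs = [a[1] for a in self.anchors]
        if any(b <= a for a, b in zip(ys, ys[1:])) or any(b <= a for a, b in zip(qs, qs[1:])):
            raise ValueError("anchors must be strictly increasing in both coordinates")
        if self.floor >= self.ceiling:
            raise ValueError("floor must be < ceiling")


DEFAULT_QUALITY_MAP = QualityMap()


def quality_from_clipping(daily_yield, qmap: QualityMap = DEFAULT_QUALITY_MAP):
    """Visual quality for a daily clipping yield (g m^-2 d^-1), clipped to [1, 9].

    Accepts a scalar or array; returns the same shape.
    """
    y = np.asarray(daily_yield, dtype=float)
    if np.any(y < 0.0):
        raise ValueError("daily yield must be >= 0")
    xs = np.array([0.0] + [a[0] for a in qmap.anchors])
    qs = np.array([qmap.floor] + [a[1] for a in qmap.anchors])
    out = np.interp(y, xs, qs)
    hi_slope = (qs[-1] - qs[-2]) / (xs[-1] - xs[-2])
    out = np.where(y > xs[-1], qs[-1] + (y - xs[-1]) * hi_slope, out)
    out = np.clip(out, qmap.floor, qmap.ceiling)
    return float(out) if np.isscalar(daily_yield) or np.ndim(daily_yield) == 0 else out


@dataclass(frozen=True)
class NBudgetSummary:
    """Cumulative nitrogen budget for one plot x strategy.

    ``nue`` is None for plots that received no fertilizer (undefined).
    """

    cum_n_applied: float  # kg ha^-1
    cum_clipping: float  # g m^-2
    uptake: float  # kg ha^-1
    nue: float | None  # percent


def nitrogen_use_efficiency(
    cum_clipping: float,
    control_clipping: float,
    cum_n_applied: float,
    ncp: NitrogenCycleParams = NitrogenCycleParams(),
) -> float:
    """NUE in percent: control-corrected clipping N over fertilizer N applied.

    (uptake - control uptake) / applied * 100, with uptake the clipping mass
    times tissue N fraction, both expressed in kg ha^-1.
    """
    if cum_n_applied <= 0.0:
        raise ValueError("NUE undefined when no fertilizer was applied")
    uptake = ncp.clipping_to_n_kg_ha(cum_clipping)
    control_uptake = ncp.clipping_to_n_kg_ha(control_clipping)
    return (uptake - control_uptake) / cum_n_applied * 100.0


def n_budget(
    observations: pd.DataFrame,
    fertilization: pd.DataFrame,
    control_clipping: float,
    ncp: NitrogenCycleParams = NitrogenCycleParams(),
) -> NBudgetSummary:
    """Assemble the N budget for one plot from its daily observations and
    fertilization log.

    ``observations`` needs a ``clipping_gm2_d`` column of daily yields (their
    sum is the cumulative clipping mass); ``fertilization`` needs
    ``dose_kg_ha``.  ``control_clipping`` is the cumulative clipping of an
    unfertilized control plot over the same period.
    """
    cum_clipping = float(observations["clipping_gm2_d"].sum())
    cum_n = float(fertilization["dose_kg_ha"].sum()) if len(fertilization) else 0.0
    uptake = ncp.clipping_to_n_kg_ha(cum_clipping)
    nue = (
        nitrogen_use_efficiency(cum_clipping, control_clipping, cum_n, ncp)
        if cum_n > 0.0
        else None
    )
    return NBudgetSummary(cum_n_applied=cum_n, cum_clipping=cum_clipping, uptake=uptake, nue=nue)


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def percent_reduction(reference_total: float, other_total: float, *, rounded: bool = True) -> float:
    """Percent by which ``other_total`` falls below ``reference_total``.

    Reported rounded to the nearest integer (half away from zero) unless
    ``rounded=False``.
    """
    if reference_total <= 0.0:
        raise ValueError("reference_total must be > 0")
    value = (reference_total - other_total) / reference_total * 100.0
    return _round_half_away(value) if rounded else value


@dataclass(frozen=True)
class RatioStats:
    """Five-number summary of per-interval predicted/observed yield ratios."""

    ratios: Tuple[float, ...]
    min: float = field(init=False)
    q25: float = field(init=False)
    median: float = field(init=False)
    q75: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratios, dtype=float)
        if arr.size == 0:
            raise ValueError("need at least one ratio")
        object.__setattr__(self, "min", float(arr.min()))
        object.__setattr__(self, "q25", float(np.percentile(arr, 25)))
        object.__setattr__(self, "median", float(np.median(arr)))
        object.__setattr__(self, "q75", float(np.percentile(arr, 75)))
        object.__setattr__(self, "max", float(arr.max()))


def ratio_stats(predicted: Sequence[float], observed: Sequence[float]) -> RatioStats:
    """Elementwise predicted/observed ratios with their five-number summary."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if np.any(o <= 0.0):
        raise ValueError("observed values must be > 0 to form ratios")
    return RatioStats(ratios=tuple((p / o).tolist()))


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n: int


def ndre_clipping_correlation(
    clipping: Sequence[float], ndre: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation between paired daily clipping yields and NDRE.

    Returns NaN statistics (undefined) when either series has zero variance.
    """
    x = np.asarray(clipping, dtype=float)
    y = np.asarray(ndre, dtype=float)
    if x.shape != y.shape:
        raise ValueError("clipping and ndre must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        return CorrelationResult(math.nan, math.nan, int(x.size))
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))
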