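"""Temperature-based growth-potential model and its fertilizer-dosing rule.

The growth potential (GP) is a Gaussian index of expected cool-season grass
growth as a function of average air temperature: 1.0 at the species optimum
and falling off symmetrically on either side.  The dosing rule converts the
mean GP over a lookback window into a nitrogen dose that would replace the
nitrogen removed if the turf grew at its (calibrated) maximum rate scaled by
that GP.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import DecisionError, NitrogenCycleParams, Recommendation, WeatherDay

__all__ = [
    "GPParams",
    "GPDoseRule",
    "growth_potential",
    "calibrate_max_daily_n",
    "gp_dose",
]


@dataclass(frozen=True)
class GPParams:
    """Shape parameters of the growth-potential curve (cool-season defaults)."""

    t_opt: float = 20.0
    var: float = 5.5

    def __post_init__(self) -> None:
        if self.var <= 0.0:
            raise ValueError(f"var must be > 0, got {self.var}")


def growth_potential(tavg: float, params: GPParams = GPParams()) -> float:
    """Growth potential in (0, 1] at average air temperature ``tavg`` (degC).

    Computed as ``exp(-0.5 * ((tavg - t_opt) / var) ** 2)``; equals 1 at the
    optimum and is symmetric about it.
    """
    if not math.isfinite(tavg):
        raise ValueError("tavg must be finite")
    z = (tavg - params.t_opt) / params.var
    return math.exp(-0.5 * z * z)


def growth_potential_series(
    tavgs: Iterable[float], params: GPParams = GPParams()
) -> np.ndarray:
    """Vectorized :func:`growth_potential` over a sequence of temperatures."""
    t = np.asarray(list(tavgs), dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperatures must be finite")
    z = (t - params.t_opt) / params.var
    return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class GPDoseRule:
    """Dosing parameters: maximum daily growth rate and decision interval.

    ``max_growth_rate`` (g m^-2 d^-1) is the calibrated ceiling of daily
    clipping production; multiplied by the tissue N fraction it yields the
    maximum daily N use rate that caps each dose.
    """

    max_growth_rate: float = 3.2
    interval_days: int = 14
    ncp: NitrogenCycleParams = field(default_factory=NitrogenCycleParams)

    def __post_init__(self) -> None:
        if self.max_growth_rate <= 0.0:
            raise ValueError("max_growth_rate must be > 0")
        if self.interval_days < 1:
            raise ValueError("interval_days must be >= 1")

    @property
    def max_daily_n(self) -> float:
        """Maximum daily N use rate, g N m^-2 d^-1."""
        return self.max_growth_rate * self.ncp.tissue_n_fraction

    @property
    def dose_cap_kg_ha(self) -> float:
        """Largest possible dose per decision, kg ha^-1."""
        return self.max_daily_n * self.interval_days * self.ncp.area_mass_conversion

    @classmethod
    def from_calibration(
        cls,
        max_daily_n: float,
        ncp: NitrogenCycleParams = NitrogenCycleParams(),
        interval_days: int = 14,
    ) -> "GPDoseRule":
        """Build a rule from a calibrated maximum daily N use rate (g N m^-2 d^-1)."""
        return cls(
            max_growth_rate=max_daily_n / ncp.tissue_n_fraction,
            interval_days=interval_days,
            ncp=ncp,
        )


def calibrate_max_daily_n(
    prior_clipping: Sequence[float],
    ncp: NitrogenCycleParams = NitrogenCycleParams(),
    quantile: float = 1.0,
) -> float:
    """Maximum daily N use rate (g N m^-2 d^-1) from a prior season's yields.

    Takes a quantile (default: the maximum) of the observed daily clipping
    series and multiplies by the tissue N fraction.
    """
    arr = np.asarray(prior_clipping, dtype=float)
    if arr.size == 0:
        raise ValueError("calibration requires a non-empty clipping series")
    if np.any(arr < 0.0):
        raise ValueError("clipping yields must be >= 0")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    return float(np.quantile(arr, quantile)) * ncp.tissue_n_fraction


def gp_dose(
    weather_lookback: Sequence[WeatherDay],
    rule: GPDoseRule,
    params: GPParams = GPParams(),
    *,
    date: datetime.date | None = None,
) -> Recommendation:
    """Dose for one decision: mean lookback GP times the interval N-use cap.

    dose = mean(GP) * max_daily_n * interval_days * 10  (kg ha^-1), which can
    never exceed the cap because GP <= 1.
    """
    if len(weather_lookback) == 0:
        raise DecisionError("gp_dose requires at least one day of weather history")
    gp = growth_potential_series((d.tavg for d in weather_lookback), params)
    mean_gp = float(np.mean(gp))
    dose = mean_gp * rule.max_daily_n * rule.interval_days * rule.ncp.area_mass_conversion
    dose = min(dose, rule.dose_cap_kg_ha)
    when = date if date is not None else weather_lookback[-1].date
    return Recommendation(
        date=when,
        dose_kg_ha=dose,
        strategy="gp",
        branch="gp-corrected",
        inputs={
            "mean_gp": mean_gp,
            "lookback_days": float(len(weather_lookback)),
            "dose_cap_kg_ha": rule.dose_cap_kg_ha,
        },
    )
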