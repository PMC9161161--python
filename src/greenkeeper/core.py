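"""Shared domain types used by every strategy, the simulator, and the evaluation code."""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Mapping


class ConfigurationError(ValueError):
    """Raised when a configuration object is internally inconsistent."""


class DecisionError(ValueError):
    """Raised when a dosing rule cannot be evaluated from the supplied history."""


@dataclass(frozen=True)
class NitrogenCycleParams:
    """Constants of the simplified putting-green nitrogen budget.

    ``tissue_n_fraction`` is the fraction of dry clipping mass that is nitrogen
    (assumed constant over a season).  ``area_mass_conversion`` converts
    g m^-2 to kg ha^-1 and is fixed at 10 by unit algebra.
    """

    tissue_n_fraction: float = 0.039
    area_mass_conversion: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tissue_n_fraction < 0.10:
            raise ConfigurationError(
                f"tissue_n_fraction must be in (0, 0.10), got {self.tissue_n_fraction}"
            )
        if self.area_mass_conversion != 10.0:
            raise ConfigurationError("area_mass_conversion is fixed at 10 (g m^-2 -> kg ha^-1)")

    def clipping_to_n_kg_ha(self, clipping_gm2: float) -> float:
        """Nitrogen contained in a clipping mass, expressed in kg ha^-1."""
        return clipping_gm2 * self.tissue_n_fraction * self.area_mass_conversion


@dataclass(frozen=True)
class WeatherDay:
    """One calendar day of meteorological drivers.

    Temperatures in degrees C, precipitation and reference ET in mm,
    relative humidities in percent, wind speed in km h^-1.
    """

    date: datetime.date
    tmax: float
    tmin: float
    tavg: float
    precip: float
    rhmax: float
    rhmin: float
    rhavg: float
    wind_avg: float
    et: float

    _EPS = 1e-9

    def __post_init__(self) -> None:
        if not (self.tmin <= self.tavg + self._EPS and self.tavg <= self.tmax + self._EPS):
            raise ValueError(f"require tmin <= tavg <= tmax on {self.date}")
        if not (
            -self._EPS <= self.rhmin
            and self.rhmin <= self.rhavg + self._EPS
            and self.rhavg <= self.rhmax + self._EPS
            and self.rhmax <= 100.0 + self._EPS
        ):
            raise ValueError(f"require 0 <= rhmin <= rhavg <= rhmax <= 100 on {self.date}")
        if self.precip < 0.0:
            raise ValueError("precip must be >= 0")
        if self.et < 0.0:
            raise ValueError("et must be >= 0")
        for name in ("tmax", "tmin", "tavg"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class Recommendation:
    """A dated nitrogen dose together with the rule branch that produced it.

    ``inputs`` records the quantities the decision was based on (mean growth
    potential, window-mean NDRE, predicted yield, ...) for auditability.
    """

    date: datetime.date | None
    dose_kg_ha: float
    strategy: str
    branch: str
    inputs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose_kg_ha < 0.0:
            raise ValueError(f"dose must be >= 0, got {self.dose_kg_ha}")
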