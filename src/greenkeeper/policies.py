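"""Adapters that turn each dosing rule into a season-driving fertilization policy.

A policy consumes a :class:`~greenkeeper.synthetic_green.DecisionContext` at
each biweekly decision point and returns a dated
:class:`~greenkeeper.core.Recommendation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import Recommendation
from .gp_model import GPDoseRule, GPParams, gp_dose
from .mlrf_growth import (
    FEATURE_COLUMNS,
    GrowthPredictor,
    MLRFDoseRule,
    mlrf_dose,
    predict_biweekly_yield,
)
from .schedule_strategies import ExperienceSchedule, NDRERule, experience_dose, ndre_dose
from .synthetic_green import DecisionContext

__all__ = [
    "ConstantDosePolicy",
    "ControlPolicy",
    "ExperiencePolicy",
    "GPPolicy",
    "NDREPolicy",
    "MLRFPolicy",
]


@dataclass
class ConstantDosePolicy:
    """Apply a fixed dose at every decision point (testing / control plots)."""

    dose: float
    name: str = "constant"

    def recommend(self, ctx: DecisionContext) -> Recommendation:
        return Recommendation(ctx.date, self.dose, self.name, "constant")


def ControlPolicy() -> ConstantDosePolicy:
    """Zero-dose policy for unfertilized control plots."""
    return ConstantDosePolicy(dose=0.0, name="control")


@dataclass
class ExperiencePolicy:
    schedule: ExperienceSchedule = field(default_factory=ExperienceSchedule)
    name: str = "experience"

    def recommend(self, ctx: DecisionContext) -> Recommendation:
        return experience_dose(ctx.date, self.schedule, ctx.season_start)


@dataclass
class GPPolicy:
    """Growth-potential dosing over the trailing decision interval.

    The first decision of a season, with fewer than ``interval_days`` of
    history, uses all available days (including the decision day).
    """

    rule: GPDoseRule = field(default_factory=GPDoseRule)
    params: GPParams = field(default_factory=GPParams)
    name: str = "gp"

    def recommend(self, ctx: DecisionContext) -> Recommendation:
        lookback = ctx.weather_history[-self.rule.interval_days :]
        return gp_dose(lookback, self.rule, self.params, date=ctx.date)


@dataclass
class NDREPolicy:
    """NDRE-threshold rule; fertilizes unconditionally when no readings exist
    yet (the first application of a season)."""

    rule: NDRERule = field(default_factory=NDRERule)
    name: str = "ndre"

    def recommend(self, ctx: DecisionContext) -> Recommendation:
        history = [(o.date, o.ndre) for o in ctx.observations]
        if not history:
            return Recommendation(
                ctx.date, self.rule.dose, self.name, "no-history", {"mean_ndre": float("nan")}
            )
        return ndre_dose(history, ctx.date, self.rule)


@dataclass
class MLRFPolicy:
    """Predict the upcoming interval's cumulative clipping with a fitted
    growth model and dose by clipping replacement.

    Future feature rows use the realized upcoming weather and management
    series; NDRE persists from the latest observation (``prior_ndre`` before
    any exists), and the recent-N feature is the previous decision's dose.
    """

    model: GrowthPredictor
    rule: MLRFDoseRule = field(default_factory=MLRFDoseRule)
    prior_ndre: float = 0.28
    name: str = "mlrf"

    def recommend(self, ctx: DecisionContext) -> Recommendation:
        features = self._future_features(ctx)
        predicted = predict_biweekly_yield(self.model, features)
        rec = mlrf_dose(predicted, self.rule, date=ctx.date)
        return rec

    def _future_features(self, ctx: DecisionContext) -> pd.DataFrame:
        s = ctx.sampling_interval
        i = ctx.day_index
        ndre = ctx.observations[-1].ndre if ctx.observations else self.prior_ndre
        n_recent = ctx.recommendations[-1].dose_kg_ha if ctx.recommendations else 0.0

        def moisture_at(day: int) -> float:
            ahead_idx = day - i - 1
            if 0 <= ahead_idx < len(ctx.moisture_ahead):
                return float(ctx.moisture_ahead[ahead_idx])
            if ctx.observations:
                return float(ctx.observations[min(day, len(ctx.observations) - 1)].soil_moisture)
            return float(ctx.zone.moisture_baseline)

        rows = []
        for day in range(i + 1, i + 1 + len(ctx.weather_ahead)):
            if day % s != 0:
                continue
            w = ctx.weather_ahead[day - i - 1]
            rows.append(
                {
                    "soil_moisture_3d": 0.5 * (moisture_at(day) + moisture_at(day - s)),
                    "traffic_weekly": float(ctx.traffic_ahead[day - i - 1]),
                    "ndre": ndre,
                    "root_zone": ctx.zone.zone_id,
                    "days_between_mowing": s,
                    "tmax": w.tmax,
                    "tmin": w.tmin,
                    "tavg": w.tavg,
                    "precip": w.precip,
                    "rhmax": w.rhmax,
                    "rhmin": w.rhmin,
                    "rhavg": w.rhavg,
                    "wind_avg": w.wind_avg,
                    "et": w.et,
                    "n_rate_recent": n_recent,
                }
            )
        return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
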