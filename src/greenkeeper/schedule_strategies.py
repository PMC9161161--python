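"""Experience-based fixed schedule and the NDRE virtual-reference threshold rule."""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

from .core import DecisionError, Recommendation

__all__ = ["ExperienceSchedule", "NDRERule", "experience_dose", "ndre_dose"]


@dataclass(frozen=True)
class ExperienceSchedule:
    """Fixed biweekly schedule: a constant dose every ``interval_days``."""

    dose: float = 10.0
    interval_days: int = 14
    season_weeks: int = 30

    def __post_init__(self) -> None:
        if self.dose < 0.0:
            raise ValueError("dose must be >= 0")
        if self.interval_days < 1:
            raise ValueError("interval_days must be >= 1")
        if self.season_weeks < 1:
            raise ValueError("season_weeks must be >= 1")


@dataclass(frozen=True)
class NDRERule:
    """Withhold fertilizer when the lookback-mean NDRE exceeds the reference.

    The reference threshold is calibrated against turf areas at minimally
    acceptable visual quality; withholding requires the window mean to be
    strictly greater than the threshold.
    """

    threshold: float = 0.28
    dose: float = 10.0
    lookback_days: int = 14

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.dose < 0.0:
            raise ValueError("dose must be >= 0")
        if self.lookback_days < 1:
            raise ValueError("lookback_days must be >= 1")


def experience_dose(
    decision_date: datetime.date,
    schedule: ExperienceSchedule,
    season_start: datetime.date,
) -> Recommendation:
    """Dose on the fixed schedule: ``schedule.dose`` on each biweekly date.

    Dates outside the configured season produce a zero dose flagged
    ``off-season``; non-decision dates inside the season produce a zero dose.
    """
    offset = (decision_date - season_start).days
    season_days = schedule.season_weeks * 7
    if offset < 0 or offset >= season_days:
        return Recommendation(decision_date, 0.0, "experience", "off-season")
    if offset % schedule.interval_days == 0:
        return Recommendation(decision_date, schedule.dose, "experience", "scheduled")
    return Recommendation(decision_date, 0.0, "experience", "between-applications")


def ndre_dose(
    ndre_history: Iterable[Tuple[datetime.date, float]],
    decision_date: datetime.date,
    rule: NDRERule,
) -> Recommendation:
    """Threshold rule on the lookback-window mean NDRE.

    Readings in the half-open window ``(decision_date - lookback_days,
    decision_date]`` are averaged with equal weight; fertilizer is withheld
    only when that mean is strictly greater than the threshold.
    """
    window_start = decision_date - datetime.timedelta(days=rule.lookback_days)
    values = [v for d, v in ndre_history if window_start < d <= decision_date]
    if not values:
        raise DecisionError(
            f"no NDRE readings in the {rule.lookback_days}-day window ending {decision_date}"
        )
    mean_ndre = float(np.mean(values))
    if mean_ndre > rule.threshold:
        dose, branch = 0.0, "withhold"
    else:
        dose, branch = rule.dose, "fertilize"
    return Recommendation(
        date=decision_date,
        dose_kg_ha=dose,
        strategy="ndre",
        branch=branch,
        inputs={
            "mean_ndre": mean_ndre,
            "threshold": rule.threshold,
            "n_readings": float(len(values)),
        },
    )
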