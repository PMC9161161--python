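"""Ensemble-of-trees growth prediction and the clipping-replacement dosing rule.

Feature rows are built per clipping-collection event from daily observations,
weather, and the fertilization log; a seeded random-forest regressor trained
on prior seasons predicts per-event clipping mass, which is summed over the
upcoming two-week interval and converted to a nitrogen dose by a three-branch
replacement rule.
"""

from __future__ import annotations

import datetime
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .core import NitrogenCycleParams, Recommendation

__all__ = [
    "FEATURE_COLUMNS",
    "TrainingSet",
    "MLRFDoseRule",
    "GrowthPredictor",
    "build_features",
    "train_growth_model",
    "predict_biweekly_yield",
    "mlrf_dose",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "soil_moisture_3d",
    "traffic_weekly",
    "ndre",
    "root_zone",
    "days_between_mowing",
    "tmax",
    "tmin",
    "tavg",
    "precip",
    "rhmax",
    "rhmin",
    "rhavg",
    "wind_avg",
    "et",
    "n_rate_recent",
]


@dataclass
class TrainingSet:
    """Feature rows aligned with per-event clipping targets (g m^-2 per collection)."""

    features: pd.DataFrame
    targets: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.features) != len(self.targets):
            raise ValueError(
                f"feature/target row mismatch: {len(self.features)} vs {len(self.targets)}"
            )
        if (np.asarray(self.targets, dtype=float) < 0.0).any():
            raise ValueError("targets must be >= 0")

    def __len__(self) -> int:
        return len(self.features)

    @staticmethod
    def concat(parts: Sequence["TrainingSet"]) -> "TrainingSet":
        return TrainingSet(
            features=pd.concat([p.features for p in parts], ignore_index=True),
            targets=pd.concat([p.targets for p in parts], ignore_index=True),
            provenance="+".join(p.provenance for p in parts if p.provenance),
        )


@dataclass(frozen=True)
class MLRFDoseRule:
    """Clipping-replacement dosing band (g m^-2 per 2 weeks)."""

    low: float = 17.5
    high: float = 22.5
    median_target: float = 20.0
    ncp: NitrogenCycleParams = field(default_factory=NitrogenCycleParams)

    def __post_init__(self) -> None:
        if not self.low < self.median_target < self.high:
            raise ValueError("require low < median_target < high")


def build_features(
    observations: pd.DataFrame,
    weather: pd.DataFrame,
    management: pd.DataFrame | None,
    root_zone: str,
    *,
    sampling_interval: int = 2,
    interval_days: int = 14,
    provenance: str = "",
) -> TrainingSet:
    """One feature row (and clipping target) per collection event.

    ``observations`` holds daily rows (date, clipping_gm2_d, ndre,
    soil_moisture_pct, traffic_rounds_wk); ``weather`` the canonical daily
    weather table; ``management`` the fertilization log (date, dose_kg_ha).
    Collection events fall every ``sampling_interval`` days from the first
    observation; the target is the clipping mass accumulated since the
    previous event.  The 3-day soil moisture feature averages the event's
    and the previous event's readings.  Events with missing weather are
    excluded and logged.
    """
    obs = observations.copy()
    obs["date"] = _as_dates(obs["date"])
    obs = obs.set_index("date").sort_index()
    wx = weather.copy()
    wx["date"] = _as_dates(wx["date"])
    wx = wx.set_index("date").sort_index()

    start = obs.index[0]
    dose_by_offset: dict[int, float] = {}
    if management is not None and len(management):
        mg = management.copy()
        mg["date"] = _as_dates(mg["date"])
        for _, row in mg.iterrows():
            off = (row["date"] - start).days
            dose_by_offset[off] = dose_by_offset.get(off, 0.0) + float(row["dose_kg_ha"])

    n_days = (obs.index[-1] - start).days + 1
    event_offsets = list(range(0, n_days, sampling_interval))
    rows, targets = [], []
    for prev_off, off in zip(event_offsets, event_offsets[1:]):
        d = start + datetime.timedelta(days=off)
        d_prev = start + datetime.timedelta(days=prev_off)
        if d not in obs.index or d_prev not in obs.index:
            continue
        if d not in wx.index:
            logger.warning("no weather for %s; event excluded", d)
            continue
        target = float(
            obs.loc[
                (obs.index > d_prev) & (obs.index <= d), "clipping_gm2_d"
            ].sum()
        )
        interval_idx = off // interval_days
        prev_interval = range((interval_idx - 1) * interval_days, interval_idx * interval_days)
        n_recent = sum(dose_by_offset.get(o, 0.0) for o in prev_interval)
        w = wx.loc[d]
        rows.append(
            {
                "soil_moisture_3d": 0.5
                * (obs.at[d, "soil_moisture_pct"] + obs.at[d_prev, "soil_moisture_pct"]),
                "traffic_weekly": obs.at[d, "traffic_rounds_wk"],
                "ndre": obs.at[d, "ndre"],
                "root_zone": root_zone,
                "days_between_mowing": off - prev_off,
                "tmax": w["tmax"],
                "tmin": w["tmin"],
                "tavg": w["tavg"],
                "precip": w["precip"],
                "rhmax": w["rhmax"],
                "rhmin": w["rhmin"],
                "rhavg": w["rhavg"],
                "wind_avg": w["wind_avg"],
                "et": w["et"],
                "n_rate_recent": n_recent,
            }
        )
        targets.append(target)
    if not rows:
        raise ValueError("no overlapping dates between observations and weather")
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return TrainingSet(features=features, targets=pd.Series(targets, name="clipping_gm2"), provenance=provenance)


def _as_dates(col: pd.Series) -> pd.Series:
    return pd.to_datetime(col).dt.date if not isinstance(col.iloc[0], datetime.date) else col


class GrowthPredictor:
    """Seeded random-forest regressor over per-event feature rows.

    Falls back to a mean predictor (with a warning) when every feature
    column is degenerate.  Predictions are clipped at zero.
    """

    def __init__(self, n_estimators: int = 500, seed: int = 0, min_rows: int = 50):
        self.n_estimators = n_estimators
        self.seed = seed
        self.min_rows = min_rows
        self._model: RandomForestRegressor | None = None
        self._mean: float | None = None
        self._columns: list[str] | None = None

    @property
    def is_fitted(self) -> bool:
        return self._model is not None or self._mean is not None

    def fit(self, train: TrainingSet) -> "GrowthPredictor":
        if len(train) < self.min_rows:
            raise ValueError(f"need >= {self.min_rows} training rows, got {len(train)}")
        X = self._encode(train.features)
        if all(X[c].nunique() <= 1 for c in X.columns):
            warnings.warn(
                "all feature columns are degenerate; falling back to a mean predictor",
                stacklevel=2,
            )
            self._mean = float(np.mean(train.targets))
            self._model = None
            self._columns = list(X.columns)
            return self
        self._model = RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        )
        self._model.fit(X.to_numpy(dtype=float), np.asarray(train.targets, dtype=float))
        self._mean = None
        self._columns = list(X.columns)
        return self

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if not self.is_fitted:
            raise ValueError("predictor is not fitted")
        X = self._encode(features)
        if self._mean is not None:
            return np.full(len(X), max(self._mean, 0.0))
        X = X.reindex(columns=self._columns, fill_value=0.0)
        return np.maximum(0.0, self._model.predict(X.to_numpy(dtype=float)))

    @staticmethod
    def _encode(features: pd.DataFrame) -> pd.DataFrame:
        if "root_zone" in features.columns:
            return pd.get_dummies(features, columns=["root_zone"], dtype=float)
        return features.copy()

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": 1,
                "n_estimators": self.n_estimators,
                "seed": self.seed,
                "min_rows": self.min_rows,
                "columns": self._columns,
                "mean": self._mean,
                "model": self._model,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "GrowthPredictor":
        blob = joblib.load(path)
        if blob.get("format_version") != 1:
            raise ValueError("unrecognized model file format")
        obj = cls(
            n_estimators=blob["n_estimators"], seed=blob["seed"], min_rows=blob["min_rows"]
        )
        obj._columns = blob["columns"]
        obj._mean = blob["mean"]
        obj._model = blob["model"]
        return obj


def train_growth_model(train: TrainingSet, seed: int, **kwargs) -> GrowthPredictor:
    """Fit a :class:`GrowthPredictor` on a training set, reproducibly."""
    return GrowthPredictor(seed=seed, **kwargs).fit(train)


def predict_biweekly_yield(model: GrowthPredictor, features: pd.DataFrame) -> float:
    """Predicted 2-week cumulative clipping: sum of per-event predictions."""
    if len(features) == 0:
        raise ValueError("no feature rows for the upcoming interval")
    return float(np.sum(model.predict(features)))


def mlrf_dose(
    predicted_yield: float,
    rule: MLRFDoseRule = MLRFDoseRule(),
    *,
    date: datetime.date | None = None,
) -> Recommendation:
    """Three-branch clipping-replacement dose for a predicted biweekly yield.

    In-band predictions are replaced 1:1 (yield x tissue N x 10); predictions
    below the band fall back to the band median; predictions above it get no
    fertilizer.
    """
    if predicted_yield < 0.0:
        raise ValueError("predicted_yield must be >= 0")
    ncp = rule.ncp
    if predicted_yield > rule.high:
        dose, branch = 0.0, "above-range"
    elif predicted_yield < rule.low:
        dose, branch = ncp.clipping_to_n_kg_ha(rule.median_target), "below-range"
    else:
        dose, branch = ncp.clipping_to_n_kg_ha(predicted_yield), "replacement"
    return Recommendation(
        date=date,
        dose_kg_ha=dose,
        strategy="mlrf",
        branch=branch,
        inputs={"predicted_yield": float(predicted_yield)},
    )
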