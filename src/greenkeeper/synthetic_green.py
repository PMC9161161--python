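"""Virtual putting green: seeded synthetic weather/management series and a
daily-time-step simulator of one creeping-bentgrass plot under any
fertilization policy.

The simulator embodies a simplified nitrogen cycle for sand-based root zones:
fertilizer and background mineralization are the only inputs to a plant-
available soil N pool, and clipping removal is the only output.  Daily growth
is a maximum rate scaled down by multiplicative temperature (growth
potential), nitrogen, water, and traffic factors, with lognormal noise.
NDRE is a saturating function of the plant N status, calibrated so that a
plot held at minimally acceptable quality reads near the virtual-reference
threshold.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    NitrogenCycleParams,
    Recommendation,
    WeatherDay,
)
from .evaluation import DEFAULT_QUALITY_MAP, QualityMap, quality_from_clipping
from .gp_model import GPParams, growth_potential

__all__ = [
    "ClimateConfig",
    "RootZoneProfile",
    "GrowthParams",
    "ManagementConfig",
    "PlotState",
    "DailyObservation",
    "DecisionContext",
    "FertilizationPolicy",
    "SeasonResult",
    "generate_weather",
    "generate_management",
    "step_plot",
    "run_season",
    "default_root_zones",
    "weather_frame",
    "weather_from_frame",
    "weather_from_csv",
]

# Strategies need one 14-day lookback plus at least one decision.
_MIN_SEASON_DAYS = 28


@dataclass(frozen=True)
class ClimateConfig:
    """Seeded generator settings for one synthetic growing season.

    Daily mean temperature follows a half-sine seasonal curve peaking at
    ``mean_peak_temp`` mid-season, plus AR(1) noise.  Defaults emulate a
    ~30-week upper-midwest season with a seasonal mean near 20 degC.
    """

    season_start: datetime.date = datetime.date(2020, 5, 1)
    season_length_days: int = 210
    mean_peak_temp: float = 22.5
    temp_amplitude: float = 7.0
    temp_ar1_coeff: float = 0.6
    temp_noise_sd: float = 1.5
    precip_wet_prob: float = 0.35
    precip_mean_mm: float = 6.0
    seed: int = 0
    # secondary drivers
    temp_diurnal_spread: float = 4.0
    rh_mean: float = 70.0
    rh_sd: float = 8.0
    wind_mean: float = 9.0
    wind_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.season_length_days < _MIN_SEASON_DAYS:
            raise ConfigurationError(
                f"season_length_days must be >= {_MIN_SEASON_DAYS}, got {self.season_length_days}"
            )
        if not 0.0 <= self.temp_ar1_coeff < 1.0:
            raise ConfigurationError("temp_ar1_coeff must be in [0, 1)")
        if not 0.0 <= self.precip_wet_prob <= 1.0:
            raise ConfigurationError("precip_wet_prob must be in [0, 1]")
        if self.temp_noise_sd < 0.0 or self.precip_mean_mm < 0.0:
            raise ConfigurationError("noise parameters must be >= 0")


@dataclass(frozen=True)
class RootZoneProfile:
    """A sand-based root zone, distinguished by its background N supply.

    ``mineralization_rate`` (g N m^-2 d^-1) is the constant daily release of
    plant-available N from soil organic matter; ``som_level`` is the
    qualitative organic-matter scalar it is derived from.
    """

    zone_id: str
    mineralization_rate: float = 0.0056
    som_level: float = 0.7
    moisture_baseline: float = 25.0

    _SOM_TO_MINERALIZATION = 0.008  # g N m^-2 d^-1 per unit som_level

    def __post_init__(self) -> None:
        if self.mineralization_rate < 0.0:
            raise ConfigurationError("mineralization_rate must be >= 0")

    @classmethod
    def from_som(
        cls, zone_id: str, som_level: float, moisture_baseline: float = 25.0
    ) -> "RootZoneProfile":
        return cls(
            zone_id=zone_id,
            mineralization_rate=cls._SOM_TO_MINERALIZATION * som_level,
            som_level=som_level,
            moisture_baseline=moisture_baseline,
        )


def default_root_zones() -> tuple[RootZoneProfile, RootZoneProfile]:
    """Two contrasting root zones (low and high organic matter)."""
    return (
        RootZoneProfile.from_som("A", som_level=0.7),
        RootZoneProfile.from_som("B", som_level=1.2),
    )


@dataclass(frozen=True)
class GrowthParams:
    """Growth-response and observation-model constants of the virtual plot.

    ``gmax`` is the plot's physiological ceiling of daily clipping production;
    it is deliberately lower than the dosing rules' calibrated maximum growth
    rate (over-calibration of that rule is part of what the virtual trials
    expose).  ``n_half_sat`` is the Michaelis-Menten half-saturation of the
    soil-N growth factor (g N m^-2); with the default background
    mineralization it leaves unfertilized plots at a small fraction of
    well-fertilized growth.  NDRE is a saturating function of the soil N pool,
    ``ndre = ndre_floor + ndre_span * pool / (pool + ndre_half_sat)``,
    anchored so a plot held at quality 6 (daily yield ``quality6_yield``)
    reads near the virtual-reference threshold: see :meth:`ndre_anchored`.
    """

    gmax: float = 1.7  # g m^-2 d^-1 ceiling of daily clipping production
    n_half_sat: float = 0.5  # g N m^-2
    initial_soil_n: float = 0.5  # g N m^-2 at season start
    moisture_opt: float = 25.0  # %
    moisture_sens: float = 0.3
    traffic_sens: float = 0.0015  # per round wk^-1
    yield_noise_sd: float = 0.10  # lognormal sigma, mean-one
    ndre_floor: float = 0.24
    ndre_span: float = 0.12
    ndre_half_sat: float = 2.7777778  # g N m^-2 pool scale; see ndre_anchored()
    ndre_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        for name in ("gmax", "n_half_sat", "ndre_span", "ndre_half_sat"):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.yield_noise_sd < 0.0 or self.ndre_noise_sd < 0.0:
            raise ConfigurationError("noise sds must be >= 0")

    @classmethod
    def ndre_anchored(
        cls,
        ndre_at_quality6: float = 0.28,
        quality6_yield: float = 1.25,
        **kwargs,
    ) -> "GrowthParams":
        """Build params with ``ndre_half_sat`` solved from the quality-6 anchor.

        At the anchor the plot grows at ``quality6_yield`` with temperature,
        water, and traffic factors near 1, so the N factor is
        ``quality6_yield / gmax`` and the pool sits at the corresponding
        point of the Michaelis curve; ``ndre_half_sat`` is chosen so the NDRE
        curve passes through ``ndre_at_quality6`` there.
        """
        base = cls(**kwargs)
        s = quality6_yield / base.gmax  # N factor at the anchor
        if not 0.0 < s < 1.0:
            raise ConfigurationError("quality6_yield must be below gmax")
        pool_at_anchor = base.n_half_sat * s / (1.0 - s)
        h = (ndre_at_quality6 - base.ndre_floor) / base.ndre_span
        if not 0.0 < h < 1.0:
            raise ConfigurationError("anchor NDRE outside the representable range")
        return replace(base, ndre_half_sat=pool_at_anchor * (1.0 - h) / h)

    def n_factor(self, soil_n_pool: float) -> float:
        """Saturating nitrogen growth factor in [0, 1)."""
        return soil_n_pool / (soil_n_pool + self.n_half_sat)

    def ndre_response(self, soil_n_pool: float) -> float:
        """Noise-free NDRE for a given soil N pool (g N m^-2)."""
        return self.ndre_floor + self.ndre_span * soil_n_pool / (
            soil_n_pool + self.ndre_half_sat
        )


@dataclass(frozen=True)
class ManagementConfig:
    """Generator settings for the soil-moisture and traffic series."""

    moisture_ar1: float = 0.8
    moisture_noise_sd: float = 1.2
    traffic_mean: float = 25.0  # rounds wk^-1
    traffic_sd: float = 5.0


@dataclass(frozen=True)
class PlotState:
    """Evolving soil-N/turf state of one virtual plot.

    Mass-per-area fields are in g m^-2 (N pools in g N m^-2); cumulative
    fields are non-decreasing and the pool is floored at zero.
    """

    soil_n_pool: float
    cum_clipping: float = 0.0
    cum_n_applied: float = 0.0  # g N m^-2
    cum_uptake: float = 0.0
    cum_mineralization: float = 0.0
    last_mow_date: datetime.date | None = None
    ndre: float | None = None


@dataclass(frozen=True)
class DailyObservation:
    """What gets measured on the plot each day."""

    date: datetime.date
    clipping_yield: float  # g m^-2 d^-1
    ndre: float
    soil_moisture: float  # %
    traffic: float  # rounds wk^-1
    quality: float  # 1-9

    def __post_init__(self) -> None:
        if self.clipping_yield < 0.0:
            raise ValueError("clipping_yield must be >= 0")
        if not 0.0 <= self.ndre <= 1.0:
            raise ValueError("ndre must be in [0, 1]")
        if not 1.0 <= self.quality <= 9.0:
            raise ValueError("quality must be in [1, 9]")


def generate_weather(config: ClimateConfig) -> list[WeatherDay]:
    """One :class:`WeatherDay` per day of the season, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.season_length_days
    days = np.arange(n)
    base = (config.mean_peak_temp - config.temp_amplitude) + config.temp_amplitude * np.sin(
        math.pi * (days + 0.5) / n
    )
    ar = np.empty(n)
    x = 0.0
    for i in range(n):
        x = config.temp_ar1_coeff * x + rng.normal(0.0, config.temp_noise_sd)
        ar[i] = x
    tavg = base + ar
    spread_hi = config.temp_diurnal_spread * (0.5 + 0.5 * rng.random(n))
    spread_lo = config.temp_diurnal_spread * (0.5 + 0.5 * rng.random(n))
    wet = rng.random(n) < config.precip_wet_prob
    precip = np.where(wet, rng.exponential(config.precip_mean_mm, n), 0.0)
    rhavg = np.clip(rng.normal(config.rh_mean, config.rh_sd, n) + 6.0 * wet, 25.0, 98.0)
    rhmax = np.minimum(100.0, rhavg + 8.0 + 10.0 * rng.random(n))
    rhmin = np.maximum(0.0, rhavg - 8.0 - 12.0 * rng.random(n))
    wind = np.maximum(0.0, rng.normal(config.wind_mean, config.wind_sd, n))
    # reference ET: deterministic, increasing in tavg and in (100 - rhavg)
    et = np.maximum(0.0, 0.32 * np.maximum(tavg, 0.0) * (1.2 - rhavg / 100.0))
    out = []
    for i in range(n):
        out.append(
            WeatherDay(
                date=config.season_start + datetime.timedelta(days=int(i)),
                tmax=float(tavg[i] + spread_hi[i]),
                tmin=float(tavg[i] - spread_lo[i]),
                tavg=float(tavg[i]),
                precip=float(precip[i]),
                rhmax=float(rhmax[i]),
                rhmin=float(rhmin[i]),
                rhavg=float(rhavg[i]),
                wind_avg=float(wind[i]),
                et=float(et[i]),
            )
        )
    return out


def generate_management(
    n_days: int,
    zone: RootZoneProfile,
    seed: int,
    config: ManagementConfig = ManagementConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Daily soil-moisture (%) and weekly traffic intensity (rounds wk^-1) series."""
    rng = np.random.default_rng(seed)
    moisture = np.empty(n_days)
    x = 0.0
    for i in range(n_days):
        x = config.moisture_ar1 * x + rng.normal(0.0, config.moisture_noise_sd)
        moisture[i] = np.clip(zone.moisture_baseline + x, 5.0, 45.0)
    n_weeks = (n_days + 6) // 7
    weekly = np.maximum(0.0, rng.normal(config.traffic_mean, config.traffic_sd, n_weeks))
    traffic = np.repeat(weekly, 7)[:n_days]
    return moisture, traffic


def step_plot(
    state: PlotState,
    day: WeatherDay,
    zone: RootZoneProfile,
    ncp: NitrogenCycleParams,
    fert_today: float,
    growth_params: GrowthParams,
    *,
    soil_moisture: float,
    traffic: float,
    rng: np.random.Generator,
    gp_params: GPParams = GPParams(),
    quality_map: QualityMap = DEFAULT_QUALITY_MAP,
) -> tuple[PlotState, DailyObservation]:
    """Advance the plot by one day under ``fert_today`` kg ha^-1 of fertilizer.

    Inputs (fertilizer, mineralization) enter the soil N pool first; growth
    then draws on the updated pool, with uptake capped by the pool so the
    mass balance is exact and the pool never goes negative.
    """
    if fert_today < 0.0:
        raise ValueError(f"fert_today must be >= 0, got {fert_today}")
    gp = growth_params

    fert_g = fert_today / ncp.area_mass_conversion
    mineralized = zone.mineralization_rate
    pool = state.soil_n_pool + fert_g + mineralized

    f_temp = growth_potential(day.tavg, gp_params)
    f_n = gp.n_factor(pool)
    dm = (soil_moisture - gp.moisture_opt) / gp.moisture_opt
    f_water = float(np.clip(1.0 - gp.moisture_sens * dm * dm, 0.2, 1.0))
    f_traffic = max(0.2, 1.0 - gp.traffic_sens * traffic)
    if gp.yield_noise_sd > 0.0:
        noise = math.exp(rng.normal(-0.5 * gp.yield_noise_sd**2, gp.yield_noise_sd))
    else:
        noise = 1.0
    y = gp.gmax * f_temp * f_n * f_water * f_traffic * noise

    uptake = y * ncp.tissue_n_fraction
    if uptake > pool:  # cannot remove more N than is available
        uptake = pool
        y = uptake / ncp.tissue_n_fraction
    pool -= uptake

    ndre = gp.ndre_response(pool + uptake)  # sensed before mowing removes the day's uptake
    if gp.ndre_noise_sd > 0.0:
        ndre += rng.normal(0.0, gp.ndre_noise_sd)
    ndre = float(np.clip(ndre, 0.0, 1.0))
    quality = float(np.clip(quality_from_clipping(y, quality_map), 1.0, 9.0))

    new_state = replace(
        state,
        soil_n_pool=pool,
        cum_clipping=state.cum_clipping + y,
        cum_n_applied=state.cum_n_applied + fert_g,
        cum_uptake=state.cum_uptake + uptake,
        cum_mineralization=state.cum_mineralization + mineralized,
        ndre=ndre,
    )
    obs = DailyObservation(
        date=day.date,
        clipping_yield=y,
        ndre=ndre,
        soil_moisture=float(soil_moisture),
        traffic=float(traffic),
        quality=quality,
    )
    return new_state, obs


@dataclass(frozen=True)
class DecisionContext:
    """Everything a fertilization policy may consult at one decision point.

    ``weather_history`` runs through the decision day inclusive;
    ``observations`` run through the previous day (the decision is made
    before that day's measurement).  ``*_ahead`` carry the upcoming decision
    interval's realized drivers for growth-predicting policies.
    """

    day_index: int
    date: datetime.date
    season_start: datetime.date
    zone: RootZoneProfile
    interval_days: int
    sampling_interval: int
    weather_history: tuple[WeatherDay, ...]
    weather_ahead: tuple[WeatherDay, ...]
    observations: tuple[DailyObservation, ...]
    recommendations: tuple[Recommendation, ...]
    moisture_ahead: tuple[float, ...]
    traffic_ahead: tuple[float, ...]


class FertilizationPolicy(Protocol):
    """Structural interface for season-driving policies."""

    name: str

    def recommend(self, ctx: DecisionContext) -> Recommendation: ...


@dataclass(frozen=True)
class SeasonResult:
    """Aligned observation, weather, and application records for one plot-year."""

    zone: RootZoneProfile
    policy_name: str
    weather: tuple[WeatherDay, ...]
    observations: tuple[DailyObservation, ...]
    recommendations: tuple[Recommendation, ...]
    daily_dose: tuple[float, ...]  # kg ha^-1, one entry per day
    final_state: PlotState
    initial_soil_n: float
    decision_interval: int
    sampling_interval: int

    @property
    def cum_n_applied_kg_ha(self) -> float:
        return float(sum(self.daily_dose))

    @property
    def cum_clipping_gm2(self) -> float:
        return self.final_state.cum_clipping

    def interval_clipping(self) -> list[float]:
        """Observed cumulative clipping per decision interval (g m^-2)."""
        sums: dict[int, float] = {}
        for i, obs in enumerate(self.observations):
            sums.setdefault(i // self.decision_interval, 0.0)
            sums[i // self.decision_interval] += obs.clipping_yield
        return [sums[k] for k in sorted(sums)]

    def observations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [o.date for o in self.observations],
                "clipping_gm2_d": [o.clipping_yield for o in self.observations],
                "ndre": [o.ndre for o in self.observations],
                "soil_moisture_pct": [o.soil_moisture for o in self.observations],
                "traffic_rounds_wk": [o.traffic for o in self.observations],
                "quality": [o.quality for o in self.observations],
            }
        )

    def fert_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [r.date for r in self.recommendations],
                "dose_kg_ha": [r.dose_kg_ha for r in self.recommendations],
                "strategy": [r.strategy for r in self.recommendations],
                "branch": [r.branch for r in self.recommendations],
            }
        )

    def weather_frame(self) -> pd.DataFrame:
        return weather_frame(self.weather)


def run_season(
    zone: RootZoneProfile,
    climate: ClimateConfig,
    fertilization_policy: FertilizationPolicy,
    seed: int,
    *,
    ncp: NitrogenCycleParams = NitrogenCycleParams(),
    growth_params: GrowthParams = GrowthParams(),
    management: ManagementConfig = ManagementConfig(),
    decision_interval: int = 14,
    sampling_interval: int = 2,
    weather: Sequence[WeatherDay] | None = None,
    gp_params: GPParams = GPParams(),
) -> SeasonResult:
    """Simulate one plot-year under a fertilization policy.

    The policy is consulted on the biweekly (``decision_interval``) schedule;
    every other day applies a zero dose.  ``seed`` drives weather (unless a
    pre-generated ``weather`` series is supplied), management, and plot-level
    noise through independent child seeds.
    """
    ss = np.random.SeedSequence(seed)
    weather_seed, mgmt_seed, plot_seed = (int(c.generate_state(1)[0]) for c in ss.spawn(3))
    if weather is None:
        weather = generate_weather(dataclasses.replace(climate, seed=weather_seed))
    weather = list(weather)
    n_days = len(weather)
    moisture, traffic = generate_management(n_days, zone, mgmt_seed, management)
    rng = np.random.default_rng(plot_seed)

    state = PlotState(soil_n_pool=growth_params.initial_soil_n)
    initial_pool = growth_params.initial_soil_n
    observations: list[DailyObservation] = []
    recommendations: list[Recommendation] = []
    daily_dose: list[float] = []
    season_start = weather[0].date

    for i, day in enumerate(weather):
        dose = 0.0
        if i % decision_interval == 0:
            ctx = DecisionContext(
                day_index=i,
                date=day.date,
                season_start=season_start,
                zone=zone,
                interval_days=decision_interval,
                sampling_interval=sampling_interval,
                weather_history=tuple(weather[: i + 1]),
                weather_ahead=tuple(weather[i + 1 : i + 1 + decision_interval]),
                observations=tuple(observations),
                recommendations=tuple(recommendations),
                moisture_ahead=tuple(moisture[i + 1 : i + 1 + decision_interval]),
                traffic_ahead=tuple(traffic[i + 1 : i + 1 + decision_interval]),
            )
            rec = fertilization_policy.recommend(ctx)
            recommendations.append(rec)
            dose = rec.dose_kg_ha
        daily_dose.append(dose)
        state, obs = step_plot(
            state,
            day,
            zone,
            ncp,
            dose,
            growth_params,
            soil_moisture=float(moisture[i]),
            traffic=float(traffic[i]),
            rng=rng,
            gp_params=gp_params,
        )
        if i % sampling_interval == 0:
            state = replace(state, last_mow_date=day.date)
        observations.append(obs)

    return SeasonResult(
        zone=zone,
        policy_name=getattr(fertilization_policy, "name", "unknown"),
        weather=tuple(weather),
        observations=tuple(observations),
        recommendations=tuple(recommendations),
        daily_dose=tuple(daily_dose),
        final_state=state,
        initial_soil_n=initial_pool,
        decision_interval=decision_interval,
        sampling_interval=sampling_interval,
    )


# ---------------------------------------------------------------------------
# CSV-facing helpers (spec'd external interface column layouts)

_WEATHER_COLUMNS = [
    "date",
    "tmax",
    "tmin",
    "tavg",
    "precip",
    "rhmax",
    "rhmin",
    "rhavg",
    "wind_avg",
    "et",
]


def weather_frame(weather: Sequence[WeatherDay]) -> pd.DataFrame:
    """Weather series as a DataFrame with the canonical column layout."""
    return pd.DataFrame(
        [
            {
                "date": d.date,
                "tmax": d.tmax,
                "tmin": d.tmin,
                "tavg": d.tavg,
                "precip": d.precip,
                "rhmax": d.rhmax,
                "rhmin": d.rhmin,
                "rhavg": d.rhavg,
                "wind_avg": d.wind_avg,
                "et": d.et,
            }
            for d in weather
        ],
        columns=_WEATHER_COLUMNS,
    )


def weather_from_frame(df: pd.DataFrame) -> list[WeatherDay]:
    missing = [c for c in _WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row.date
        if isinstance(d, str):
            d = datetime.date.fromisoformat(d)
        elif isinstance(d, pd.Timestamp):
            d = d.date()
        out.append(
            WeatherDay(
                date=d,
                tmax=float(row.tmax),
                tmin=float(row.tmin),
                tavg=float(row.tavg),
                precip=float(row.precip),
                rhmax=float(row.rhmax),
                rhmin=float(row.rhmin),
                rhavg=float(row.rhavg),
                wind_avg=float(row.wind_avg),
                et=float(row.et),
            )
        )
    return out


def weather_from_csv(path) -> list[WeatherDay]:
    """Read a weather CSV (ISO dates, header required)."""
    return weather_from_frame(pd.read_csv(path))
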