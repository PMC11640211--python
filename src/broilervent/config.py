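"""Validated configuration schema for the house, flock, schedules and weather.

All physical constants of the building and ventilation plant live here as
pydantic models so that a malformed configuration (negative volume, pad
efficiency above 1, a non-increasing fan-stage ladder) is rejected at load
time with a field-specific message rather than surfacing as a numerical
oddity mid-simulation.

Default values describe a commercial tunnel-ventilated broiler house:
87 m x 14 m floor, 3.5 m eaves, 5 m ridge, 14 exhaust fans of 37,000 m3/h
each arranged in six stages (stage 0 = two fans run intermittently for
minimum ventilation; stages 1-5 = 4/6/8/10/14 fans continuous), and a
two-pad evaporative cooling inlet with efficiency 0.65.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

# ---------------------------------------------------------------------------
# Reference geometry of the default house (m)
# ---------------------------------------------------------------------------

FLOOR_LENGTH_M = 87.0
FLOOR_WIDTH_M = 14.0
EAVE_HEIGHT_M = 3.5
RIDGE_HEIGHT_M = 5.0


def default_floor_area() -> float:
    """Floor area of the default house (m^2)."""
    return FLOOR_LENGTH_M * FLOOR_WIDTH_M


def default_wall_area() -> float:
    """Envelope area above grade: side walls + gable ends + roof (m^2).

    Side walls: 2 * L * eave; gables: 2 * (W*eave + triangular apex);
    roof: two pitched planes from eave to ridge.
    """
    rise = RIDGE_HEIGHT_M - EAVE_HEIGHT_M
    side_walls = 2.0 * FLOOR_LENGTH_M * EAVE_HEIGHT_M
    gables = 2.0 * (FLOOR_WIDTH_M * EAVE_HEIGHT_M + 0.5 * FLOOR_WIDTH_M * rise)
    slope = math.hypot(FLOOR_WIDTH_M / 2.0, rise)
    roof = 2.0 * FLOOR_LENGTH_M * slope
    return side_walls + gables + roof


def default_house_volume() -> float:
    """Interior air volume: rectangular body plus the triangular roof prism (m^3)."""
    body = FLOOR_LENGTH_M * FLOOR_WIDTH_M * EAVE_HEIGHT_M
    apex = FLOOR_LENGTH_M * 0.5 * FLOOR_WIDTH_M * (RIDGE_HEIGHT_M - EAVE_HEIGHT_M)
    return body + apex


class EnvelopeSpec(BaseModel):
    """Thermal transmittances and areas of wall/roof and floor."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    Uw: float = Field(0.247, gt=0, description="wall/roof U-value, W m-2 K-1")
    Uf: float = Field(2.75, gt=0, description="floor U-value, W m-2 K-1")
    Aw: float = Field(default_factory=default_wall_area, gt=0, description="wall+roof area, m2")
    Af: float = Field(default_factory=default_floor_area, gt=0, description="floor area, m2")


class HouseConfig(BaseModel):
    """Physical and operational constants of the house and ventilation plant.

    ``delta_t`` is the energy-balance horizon of the controller (the time over
    which the indoor-air excess heat is to be removed); ``control_interval``
    is how often a decision is taken. They are distinct on purpose: the
    controller re-plans every 10 s against a 150 s horizon.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    Vb: float = Field(default_factory=default_house_volume, gt=0, description="house air volume, m3")
    rho: float = Field(1.2, gt=0, description="air density, kg m-3")
    cp: float = Field(1006.0, gt=0, description="air specific heat, J kg-1 C-1")
    delta_t: float = Field(150.0, gt=0, description="energy-balance horizon, s")
    Tda: float = Field(1.5, gt=0, description="allowable temperature band, C")
    pad_efficiency: float = Field(0.65, ge=0, le=1)
    fan_capacity: float = Field(37000.0, gt=0, description="per-fan airflow, m3 h-1")
    fan_power_w: float = Field(836.0, ge=0, description="per-fan electrical power, W")
    pad_power_w: float = Field(1100.0, ge=0, description="cooling-pad pump power, W")
    stage_fans: tuple[int, ...] = (2, 4, 6, 8, 10, 14)
    min_vent_schedule: tuple[tuple[float, float], ...] = ((0.0, 1233.0), (35.0, 22611.0))
    envelope: EnvelopeSpec = Field(default_factory=EnvelopeSpec)
    control_interval: float = Field(10.0, gt=0, description="decision cadence, s")
    degenerate_dT_tol: float = Field(0.2, gt=0, description="|dT| below which Eq-2 is degenerate, C")

    @field_validator("stage_fans")
    @classmethod
    def _stages_increasing(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if len(v) < 2:
            raise ValueError("at least stage 0 and stage 1 are required")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("stage_fans must be strictly increasing")
        if any(n <= 0 for n in v):
            raise ValueError("fan counts must be positive")
        return v

    @field_validator("min_vent_schedule")
    @classmethod
    def _min_vent_monotone(cls, v):
        ages = [a for a, _ in v]
        rates = [r for _, r in v]
        if sorted(ages) != ages or len(set(ages)) != len(ages):
            raise ValueError("min_vent_schedule ages must be strictly increasing")
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise ValueError("minimum ventilation must be non-decreasing with age")
        if any(r < 0 for r in rates):
            raise ValueError("minimum ventilation must be non-negative")
        return v

    @property
    def fan_capacity_m3s(self) -> float:
        return self.fan_capacity / 3600.0

    @property
    def top_stage(self) -> int:
        return len(self.stage_fans) - 1

    def min_vent(self, age_days: float) -> float:
        """Age-interpolated minimum ventilation rate (m3 h-1), flat beyond the table."""
        ages = [a for a, _ in self.min_vent_schedule]
        rates = [r for _, r in self.min_vent_schedule]
        return float(np.interp(age_days, ages, rates))


class SetpointSchedule(BaseModel):
    """Age-dependent set temperature Td (C): warm for chicks, cooler as birds grow."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    points: tuple[tuple[float, float], ...] = ((0.0, 32.0), (28.0, 24.0))

    @model_validator(mode="after")
    def _non_increasing(self) -> "SetpointSchedule":
        ages = [a for a, _ in self.points]
        temps = [t for _, t in self.points]
        if sorted(ages) != ages or len(set(ages)) != len(ages):
            raise ValueError("setpoint ages must be strictly increasing")
        if any(b > a for a, b in zip(temps, temps[1:])):
            raise ValueError("set temperature must be non-increasing with age")
        return self

    def setpoint(self, age_days: float) -> float:
        ages = [a for a, _ in self.points]
        temps = [t for _, t in self.points]
        return float(np.interp(age_days, ages, temps))


class StageThresholdTable(BaseModel):
    """Indoor-temperature start thresholds per fan stage for the baseline controller.

    The default is synthetic: it anchors each stage start at Td(age) + k * stage_step
    and the pad threshold at Td(age) + pad_offset, with Td from a declining setpoint
    schedule. It does NOT reproduce any particular farm's programmed values, which
    are operator-specific; supply explicit rows to model a real installation.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    setpoints: SetpointSchedule = Field(default_factory=SetpointSchedule)
    stage_step: float = Field(1.0, gt=0, description="C between successive stage starts")
    pad_offset: float = Field(5.0, gt=0, description="C above Td at which the pad engages")
    max_age_days: float = Field(60.0, gt=0)

    def stage_starts(self, age_days: float) -> list[float]:
        """Start temperatures for stages 1..5 at this age (strictly increasing)."""
        if age_days < 0 or age_days > self.max_age_days:
            raise ValueError(f"age {age_days} outside table range [0, {self.max_age_days}]")
        td = self.setpoints.setpoint(age_days)
        return [td + k * self.stage_step for k in range(1, 6)]

    def pad_threshold(self, age_days: float) -> float:
        if age_days < 0 or age_days > self.max_age_days:
            raise ValueError(f"age {age_days} outside table range [0, {self.max_age_days}]")
        return self.setpoints.setpoint(age_days) + self.pad_offset


class WeatherScenario(BaseModel):
    """Sinusoidal diurnal weather with seeded Gaussian noise.

    Temperature swings between ``night_min_T`` and ``day_max_T`` peaking at
    ``peak_hour``; relative humidity runs in anti-phase between ``RH_day``
    (at the temperature peak) and ``RH_night``.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    day_max_T: float = 30.0
    night_min_T: float = 20.0
    peak_hour: float = Field(15.0, ge=0, lt=24)
    RH_day: float = Field(55.0, gt=0, le=100)
    RH_night: float = Field(85.0, gt=0, le=100)
    day_count: int = Field(1, ge=1)
    seed: int = Field(0, ge=0)
    noise_sd: float = Field(0.0, ge=0, description="temperature noise SD, C")

    @model_validator(mode="after")
    def _ordered(self) -> "WeatherScenario":
        if self.day_max_T < self.night_min_T:
            raise ValueError("day_max_T must be >= night_min_T")
        return self


#: Named scenario presets. ``hot_spell`` emulates an extreme summer regime:
#: daytime outdoor temperature in the 33-37 C range with nights above 26 C
#: and daytime RH near 50% rising toward 90% at night.
SCENARIO_PRESETS: dict[str, dict] = {
    "hot_spell": dict(day_max_T=37.0, night_min_T=26.0, peak_hour=15.0,
                      RH_day=52.0, RH_night=90.0),
    "mild": dict(day_max_T=28.0, night_min_T=18.0, peak_hour=15.0,
                 RH_day=55.0, RH_night=85.0),
    "winter": dict(day_max_T=5.0, night_min_T=-5.0, peak_hour=14.0,
                   RH_day=50.0, RH_night=80.0),
}


def scenario_preset(name: str, *, day_count: int = 1, seed: int = 0,
                    noise_sd: float = 0.0) -> WeatherScenario:
    if name not in SCENARIO_PRESETS:
        raise KeyError(f"unknown scenario preset {name!r}; choose from {sorted(SCENARIO_PRESETS)}")
    return WeatherScenario(**SCENARIO_PRESETS[name], day_count=day_count, seed=seed,
                           noise_sd=noise_sd)


class ConfigDocument(BaseModel):
    """Top-level configuration file schema (YAML or JSON mapping)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    house: HouseConfig = Field(default_factory=HouseConfig)
    setpoints: SetpointSchedule = Field(default_factory=SetpointSchedule)
    baseline_table: StageThresholdTable = Field(default_factory=StageThresholdTable)
    scenario: WeatherScenario = Field(default_factory=WeatherScenario)
    controller: Literal["vrr", "baseline"] = "vrr"
    denominator_mode: Literal["as_printed", "inlet_corrected"] = "inlet_corrected"
    bird_count: int = Field(28120, ge=0)
    stocking_age_days: int = Field(20, ge=0)
    seed: int = Field(0, ge=0)


def load_config(path: str | Path) -> ConfigDocument:
    """Load and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration root must be a mapping")
    return ConfigDocument.model_validate(raw)
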