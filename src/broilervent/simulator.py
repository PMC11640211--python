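"""Single-zone thermal model of the house and closed-loop episode runner.

The house is one well-mixed air zone: indoor temperature obeys

    rho*Cp*Vb * dTi/dt = Qa + Ql + Qd + rho*Cp*q*((To - Tc) - Ti)

with q the delivered airflow (m3/s), To - Tc the inlet temperature after
the cooling pad, and Qa/Ql/Qd the flock and envelope loads. Integration is
explicit Euler at the control interval (10 s default), with optional
sub-stepping for stiff high-airflow regimes. Spatial gradients, wall
thermal mass and indoor moisture balance are deliberately absent; indoor
RH is reported as not-available in simulated logs.

A seeded sinusoidal weather generator supplies outdoor temperature and
humidity, including a ``hot_spell`` preset (33-37 C days, >26 C nights)
for summer heat-stress experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Literal

import numpy as np
import pandas as pd

from .baseline import decide_baseline
from .bioenergetics import FlockState, broiler_mass, flock_heat
from .config import HouseConfig, SetpointSchedule, StageThresholdTable, WeatherScenario
from .controller import ControlDecision, DenominatorMode, decide
from .thermo import EnvironmentState, envelope_heat, pad_temperature_drop, wet_bulb

#: Canonical column order of a time-series operation log.
LOG_COLUMNS = ("timestamp_s", "Ti_C", "To_C", "RHo_pct", "Td_C", "age_days",
               "stage", "n_fans", "pad_on", "actual_vent_m3h")


@dataclass(slots=True)
class SimulationState:
    """Mutable integrator state plus usage accumulators.

    ``fan_seconds`` is duty-weighted (stage 0 counts the intermittent pair
    at its duty fraction), so fan-hours and fan energy follow directly.
    """

    time_s: float = 0.0
    Ti: float = 25.0
    pad_state: bool = False
    fan_seconds: float = 0.0
    pad_seconds: float = 0.0
    fan_energy_j: float = 0.0
    pad_energy_j: float = 0.0


@dataclass(slots=True)
class TimeSeriesLog:
    """Uniform-cadence operation log with usage summary accumulators."""

    frame: pd.DataFrame
    interval_s: float
    fan_hours: float = 0.0
    pad_hours: float = 0.0
    fan_energy_kwh: float = 0.0
    pad_energy_kwh: float = 0.0

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"log frame missing columns: {missing}")
        ts = self.frame["timestamp_s"].to_numpy()
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("log timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)


def weather_generate(scenario: WeatherScenario, interval_s: float = 10.0,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outdoor (time_s, To, RHo) series at ``interval_s`` cadence.

    Temperature is a 24 h sinusoid between ``night_min_T`` and ``day_max_T``
    peaking at ``peak_hour``, plus seeded Gaussian noise; RH runs in exact
    anti-phase between ``RH_day`` (at the temperature peak) and
    ``RH_night``. Deterministic for a fixed scenario seed.
    """
    n = int(round(scenario.day_count * 86400.0 / interval_s))
    t = np.arange(n) * interval_s
    hour = (t / 3600.0) % 24.0
    phase = np.cos(2.0 * math.pi * (hour - scenario.peak_hour) / 24.0)
    t_mean = 0.5 * (scenario.day_max_T + scenario.night_min_T)
    t_amp = 0.5 * (scenario.day_max_T - scenario.night_min_T)
    To = t_mean + t_amp * phase
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        To = To + rng.normal(0.0, scenario.noise_sd, n)
    rh_mean = 0.5 * (scenario.RH_day + scenario.RH_night)
    rh_amp = 0.5 * (scenario.RH_night - scenario.RH_day)
    RHo = np.clip(rh_mean - rh_amp * phase, 5.0, 99.0)
    return t, To, RHo


def is_daytime(hour: float, peak_hour: float = 15.0, half_width_h: float = 4.0) -> bool:
    """Daytime window: within ``half_width_h`` hours of the temperature peak."""
    offset = abs(((hour - peak_hour + 12.0) % 24.0) - 12.0)
    return offset <= half_width_h


def delivered_airflow(decision: ControlDecision, cfg: HouseConfig) -> float:
    """Airflow the fans actually deliver for a decision (m3 s-1).

    Stage 0 delivers the intermittent pair at its duty fraction (the
    age-dependent minimum ventilation); stages >= 1 deliver the full stage
    fan count continuously.
    """
    if decision.stage == 0:
        return decision.stage0_duty * cfg.stage_fans[0] * cfg.fan_capacity_m3s
    return decision.n_fans_running * cfg.fan_capacity_m3s


def step(state: SimulationState, decision: ControlDecision, To: float, Tc: float,
         flock: FlockState, cfg: HouseConfig, dt: float) -> SimulationState:
    """Advance the zone temperature by one explicit-Euler step of ``dt`` seconds.

    ``Tc`` is the effective pad temperature drop for this step (already
    duty-weighted for intermittent pad operation). Mutates and returns
    ``state``; raises on a non-finite temperature (instability guard).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > cfg.control_interval + 1e-9:
        raise ValueError("dt must not exceed the control interval")
    hour = (state.time_s / 3600.0) % 24.0
    Qa, Ql = flock_heat(flock, state.Ti, hour, clamp_negative=True)
    Qd = envelope_heat(state.Ti, To, cfg.envelope)
    q = delivered_airflow(decision, cfg)
    rho_cp = cfg.rho * cfg.cp
    dTi = (Qa + Ql + Qd + rho_cp * q * ((To - Tc) - state.Ti)) / (rho_cp * cfg.Vb)
    state.Ti += dTi * dt
    if not math.isfinite(state.Ti):
        raise FloatingPointError(f"indoor temperature diverged at t={state.time_s:.0f} s")
    state.time_s += dt
    eff_fans = (decision.stage0_duty * cfg.stage_fans[0] if decision.stage == 0
                else decision.n_fans_running)
    state.fan_seconds += eff_fans * dt
    state.fan_energy_j += eff_fans * cfg.fan_power_w * dt
    if decision.pad_command:
        state.pad_seconds += decision.pad_duty * dt
        state.pad_energy_j += decision.pad_duty * cfg.pad_power_w * dt
    return state


def run_episode(controller: Literal["vrr", "baseline"],
                scenario: WeatherScenario,
                cfg: HouseConfig,
                setpoints: SetpointSchedule,
                baseline_table: StageThresholdTable | None = None,
                *,
                bird_count: int = 28120,
                start_age_days: int = 20,
                denominator_mode: DenominatorMode = "inlet_corrected",
                initial_Ti: float | None = None,
                substeps: int = 1) -> TimeSeriesLog:
    """Closed-loop run of one controller against a weather scenario.

    Every control interval: sample weather, take a control decision from
    the logged indoor temperature, apply the resulting airflow and pad
    cooling to the thermal model, and append a log record. Deterministic
    for a fixed scenario seed. Bird age advances daily from
    ``start_age_days``; body mass follows the growth curve.
    """
    if controller not in ("vrr", "baseline"):
        raise ValueError(f"unknown controller {controller!r}")
    if controller == "baseline" and baseline_table is None:
        baseline_table = StageThresholdTable(setpoints=setpoints)
    interval = cfg.control_interval
    t_arr, To_arr, RHo_arr = weather_generate(scenario, interval)
    state = SimulationState(
        Ti=setpoints.setpoint(start_age_days) + 1.0 if initial_Ti is None else initial_Ti
    )
    prev_pad = False
    cols: dict[str, list] = {c: [] for c in LOG_COLUMNS}
    dt = interval / substeps
    for i in range(len(t_arr)):
        To = float(To_arr[i])
        RHo = float(RHo_arr[i])
        age = start_age_days + int(state.time_s // 86400.0)
        Td = setpoints.setpoint(age)
        flock = FlockState(age, bird_count, broiler_mass(age, floor_mass=True))
        if controller == "vrr":
            env = EnvironmentState(Ti=state.Ti, To=To, RHo=RHo,
                                   timestamp=state.time_s)
            decision = decide(env, flock, setpoints, cfg, prev_pad,
                              denominator_mode)
            tow = env.Tow
        else:
            decision = decide_baseline(state.Ti, age, baseline_table, cfg, prev_pad)
            tow = wet_bulb(To, RHo) if decision.pad_command else To
        tc_raw = pad_temperature_drop(To, tow, cfg.pad_efficiency,
                                      decision.pad_command)
        tc_eff = tc_raw * decision.pad_duty
        cols["timestamp_s"].append(state.time_s)
        cols["Ti_C"].append(state.Ti)
        cols["To_C"].append(To)
        cols["RHo_pct"].append(RHo)
        cols["Td_C"].append(Td)
        cols["age_days"].append(age)
        cols["stage"].append(decision.stage)
        cols["n_fans"].append(decision.n_fans_running)
        cols["pad_on"].append(decision.pad_command)
        cols["actual_vent_m3h"].append(delivered_airflow(decision, cfg) * 3600.0)
        for _ in range(substeps):
            step(state, decision, To, tc_eff, flock, cfg, dt)
        prev_pad = decision.pad_command
    frame = pd.DataFrame(cols)
    return TimeSeriesLog(
        frame=frame,
        interval_s=interval,
        fan_hours=state.fan_seconds / 3600.0,
        pad_hours=state.pad_seconds / 3600.0,
        fan_energy_kwh=state.fan_energy_j / 3.6e6,
        pad_energy_kwh=state.pad_energy_j / 3.6e6,
    )
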