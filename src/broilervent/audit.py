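"""Operation-log auditing: discrepancy quadrants and usage/energy accounting.

Given a logged rearing period (real or simulated), the audit recomputes the
ventilation rate requirement at every record from the logged indoor and
outdoor temperatures, set temperature and bird age, and compares it with
the airflow actually delivered:

    VR_disc = VRR - actual ventilation     (m3/h; > 0 means under-ventilated)
    T_disc  = Td - Ti                      (C;    < 0 means too hot)

Records are then sorted into a proper band (|T_disc| within the allowable
range) and four sign quadrants, and fan/pad usage is converted into
fan-hours, pad-hours and electrical energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .bioenergetics import FlockState, broiler_mass, flock_heat
from .config import HouseConfig, SetpointSchedule
from .controller import (DegenerateDenominator, DenominatorMode, air_exchange_rate,
                         required_ventilation_rate, ventilation_heat_requirement)
from .simulator import TimeSeriesLog
from .thermo import envelope_heat, pad_temperature_drop, wet_bulb

#: Default audit cadence (s): one record every 10 minutes.
DEFAULT_AUDIT_CADENCE_S = 600.0


@dataclass(frozen=True, slots=True)
class OperationLogRecord:
    """One audited time step of a rearing log."""

    timestamp: float
    Ti: float
    To: float
    RHo: float
    Td: float
    age_days: int
    stage: int
    n_fans: float
    pad_on: bool
    actual_vent: float  # m3 h-1

    def __post_init__(self) -> None:
        if self.actual_vent < 0:
            raise ValueError("actual_vent must be >= 0")


@dataclass(frozen=True, slots=True)
class DiscrepancyRecord:
    """Required-minus-actual ventilation and setpoint-minus-indoor temperature."""

    timestamp: float
    vr_disc: float  # m3 h-1
    t_disc: float   # C
    pad_on: bool


@dataclass(frozen=True, slots=True)
class QuadrantSummary:
    """Share of audited time in the proper band and each discrepancy quadrant.

    ``high_undervent``: too hot while under-ventilated (VRR > actual);
    ``low_overvent``: too cold while over-ventilated — both fixable by
    following the computed requirement. ``anomalous``: too hot despite
    over-ventilation; ``rare``: too cold despite under-ventilation.
    """

    proper_pct: float
    high_undervent_pct: float
    low_overvent_pct: float
    anomalous_pct: float
    rare_pct: float
    record_count: int

    @property
    def potential_proper_pct(self) -> float:
        """Share achievable by correct ventilation: proper plus both fixable quadrants."""
        return self.proper_pct + self.high_undervent_pct + self.low_overvent_pct


def _required_vent_m3h(Ti: float, To: float, RHo: float, Td: float, age_days: float,
                       pad_on: bool, cfg: HouseConfig, flock: FlockState,
                       hour: float, denominator_mode: DenominatorMode) -> float:
    """Required ventilation (m3/h) for one record, applying the controller's
    exception logic to the logged conditions."""
    Qa, Ql = flock_heat(flock, Ti, hour, clamp_negative=True)
    Qd = envelope_heat(Ti, To, cfg.envelope)
    Qv = ventilation_heat_requirement(Ti, Td, Qa, Ql, Qd, cfg)
    vrr2 = air_exchange_rate(cfg)
    if Qv < 0.0 or Ti < Td + cfg.Tda:
        return cfg.min_vent(age_days)
    tc = 0.0
    if pad_on:
        tc = pad_temperature_drop(To, wet_bulb(To, RHo), cfg.pad_efficiency, True)
    try:
        vrr = required_ventilation_rate(Qv, Ti, To, tc, cfg, denominator_mode)
    except DegenerateDenominator:
        vrr = vrr2
    if not pad_on and To >= Td + cfg.Tda:
        vrr = min(vrr, vrr2)
    return vrr * 3600.0


def compute_discrepancies(log: TimeSeriesLog, cfg: HouseConfig,
                          bird_count: int,
                          schedule: SetpointSchedule | None = None,
                          denominator_mode: DenominatorMode = "inlet_corrected",
                          ) -> list[DiscrepancyRecord]:
    """Recompute the ventilation requirement at every log record and return
    per-record discrepancies.

    The set temperature is taken from the log's ``Td_C`` column (what the
    installed controller was actually targeting); pass ``schedule`` to
    override it from an age schedule instead. Bird mass at each record
    comes from the growth curve at the logged age.
    """
    if len(log) == 0:
        raise ValueError("cannot audit an empty log")
    frame = log.frame
    out: list[DiscrepancyRecord] = []
    for row in frame.itertuples(index=False):
        age = int(row.age_days)
        td = schedule.setpoint(age) if schedule is not None else float(row.Td_C)
        flock = FlockState(age, bird_count, broiler_mass(age, floor_mass=True))
        hour = (float(row.timestamp_s) / 3600.0) % 24.0
        required = _required_vent_m3h(float(row.Ti_C), float(row.To_C),
                                      float(row.RHo_pct), td, age,
                                      bool(row.pad_on), cfg, flock, hour,
                                      denominator_mode)
        out.append(DiscrepancyRecord(
            timestamp=float(row.timestamp_s),
            vr_disc=required - float(row.actual_vent_m3h),
            t_disc=td - float(row.Ti_C),
            pad_on=bool(row.pad_on),
        ))
    return out


def quadrant_summary(discs: Sequence[DiscrepancyRecord], band: float = 1.5,
                     exclude_pad_on: bool = True) -> QuadrantSummary:
    """Classify discrepancy records into the proper band and sign quadrants.

    Pad-on records are excluded by default (evaporative cooling confounds
    the ventilation-temperature relation). Records exactly on a sign
    boundary outside the proper band count with the non-negative side.
    Percentages are computed with exact rational arithmetic on counts, so
    they always sum to 100.
    """
    included = [d for d in discs if not (exclude_pad_on and d.pad_on)]
    n = len(included)
    if n == 0:
        raise ValueError("no records remain after pad-on exclusion")
    proper = high_under = low_over = anomalous = rare = 0
    for d in included:
        if abs(d.t_disc) <= band:
            proper += 1
        elif d.t_disc < 0:           # too hot
            if d.vr_disc >= 0:       # under-ventilated (or exactly matched)
                high_under += 1
            else:                    # over-ventilated yet hot
                anomalous += 1
        else:                        # too cold
            if d.vr_disc < 0:        # over-ventilated
                low_over += 1
            else:                    # under-ventilated yet cold
                rare += 1
    pct = lambda c: float(Fraction(100 * c, n))
    return QuadrantSummary(
        proper_pct=pct(proper),
        high_undervent_pct=pct(high_under),
        low_overvent_pct=pct(low_over),
        anomalous_pct=pct(anomalous),
        rare_pct=pct(rare),
        record_count=n,
    )


def fan_hours(log: TimeSeriesLog, fan_capacity_m3h: float | None = None) -> float:
    """Total fan usage in fan-hours: sum over records of (running fans) x dt.

    With ``fan_capacity_m3h`` given, the running-fan count of each record is
    the delivered airflow divided by the per-fan capacity — equal to
    ``n_fans`` for continuous stages and duty-weighted at the intermittent
    minimum-ventilation stage. Without it, the logged ``n_fans`` column is
    summed directly. Requires a uniform timestep; additive over log
    concatenation.
    """
    frame = log.frame
    if len(frame) == 0:
        return 0.0
    ts = frame["timestamp_s"].to_numpy(dtype=float)
    if len(ts) > 1:
        steps = np.diff(ts)
        if not np.allclose(steps, steps[0]):
            raise ValueError("fan_hours requires a uniform log timestep")
    if fan_capacity_m3h is not None:
        if fan_capacity_m3h <= 0:
            raise ValueError("fan_capacity_m3h must be positive")
        eff_fans = frame["actual_vent_m3h"].to_numpy(dtype=float) / fan_capacity_m3h
    else:
        eff_fans = frame["n_fans"].to_numpy(dtype=float)
    return float(np.sum(eff_fans) * log.interval_s / 3600.0)


def pad_hours(log: TimeSeriesLog, pad_duty: float = 1.0) -> float:
    """Total pad running time in hours (duty-weighted for intermittent pads)."""
    on = log.frame["pad_on"].to_numpy(dtype=bool)
    return float(on.sum()) * pad_duty * log.interval_s / 3600.0


def fan_energy_kwh(fan_hours: float, fan_power_w: float = 836.0) -> float:
    """Fan electrical energy (kWh) from fan-hours and per-fan power draw."""
    if fan_hours < 0 or fan_power_w < 0:
        raise ValueError("fan_hours and fan_power_w must be >= 0")
    return fan_hours * fan_power_w / 1000.0


@dataclass(frozen=True, slots=True)
class UsageSummary:
    """Fan/pad usage and energy of one building over one period."""

    fan_hours: float
    pad_hours: float
    fan_energy_kwh: float
    pad_energy_kwh: float = 0.0

    @classmethod
    def from_log(cls, log: TimeSeriesLog, fan_power_w: float = 836.0,
                 pad_power_w: float = 1100.0, pad_duty: float = 1.0,
                 fan_capacity_m3h: float | None = None) -> "UsageSummary":
        fh = fan_hours(log, fan_capacity_m3h)
        ph = pad_hours(log, pad_duty)
        return cls(fan_hours=fh, pad_hours=ph,
                   fan_energy_kwh=fan_energy_kwh(fh, fan_power_w),
                   pad_energy_kwh=ph * pad_power_w / 1000.0)


@dataclass(frozen=True, slots=True)
class UsageComparison:
    """Experimental building's usage relative to the control building."""

    fan_usage_pct: float        # 100 * experimental / control fan-hours
    pad_fold_change: float      # experimental / control pad-hours
    fan_energy_saved_kwh: float  # control - experimental fan energy
    control: UsageSummary
    experimental: UsageSummary


def usage_comparison(control: UsageSummary, experimental: UsageSummary,
                     ) -> UsageComparison:
    """Head-to-head usage report: percent-of-control fan usage, pad-hour
    fold change, and fan energy saved. Both summaries must cover periods of
    equal duration for the comparison to be meaningful."""
    if control.fan_hours <= 0:
        raise ValueError("control fan-hours must be positive")
    if control.pad_hours < 0 or experimental.pad_hours < 0:
        raise ValueError("pad-hours must be >= 0")
    if control.pad_hours > 0:
        pad_fold = experimental.pad_hours / control.pad_hours
    elif experimental.pad_hours == 0:
        pad_fold = 1.0  # neither building ran pads
    else:
        pad_fold = float("inf")
    return UsageComparison(
        fan_usage_pct=100.0 * experimental.fan_hours / control.fan_hours,
        pad_fold_change=pad_fold,
        fan_energy_saved_kwh=control.fan_energy_kwh - experimental.fan_energy_kwh,
        control=control,
        experimental=experimental,
    )
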