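"""Heat-balance ventilation-rate-requirement (VRR) controller.

Every control tick the controller computes the heat that must leave the
house over the planning horizon delta_t,

    Qv = rho*Cp*Vb*(Ti - Td)/delta_t + Qa + Ql + Qd,

(air-mass cooling toward the setpoint, plus flock sensible and latent heat,
plus envelope exchange) and converts it to an airflow requirement

    VRR = Qv / (rho*Cp*dT_eff),

where dT_eff is the difference between indoor air and the air the fans
draw in. With the evaporative pad running the inlet air is To - Tc, so the
default ``inlet_corrected`` mode uses dT_eff = Ti - (To - Tc); the
``as_printed`` mode uses dT_eff = Ti - To - Tc for literal replication of
the original formulation (which shrinks the denominator when pads run).

Three exception clauses, checked in order with the first match winning,
guard the plain formula:

1. If Qv < 0 or Ti < Td + Tda: no cooling is needed — fan stage 0
   (age-dependent minimum ventilation, two fans intermittent).
2. If the pad hysteresis engages (hot outdoor air and Ti well above the
   setpoint): run the pads, then recompute VRR with the cooled inlet.
3. If To >= Td + Tda (warm outside, pads not triggered): the denominator
   may be tiny and VRR unreliable, so the stage is taken from
   min(VRR, VRR2) where VRR2 = Vb/delta_t exchanges the house air once
   per horizon.

A near-zero denominator outside these paths falls back to VRR2 as well.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Literal

from .bioenergetics import FlockState, flock_heat
from .config import HouseConfig, SetpointSchedule
from .thermo import EnvironmentState, envelope_heat, pad_temperature_drop

DenominatorMode = Literal["as_printed", "inlet_corrected"]


class DegenerateDenominator(ValueError):
    """Raised when |dT_eff| is below the configured tolerance and no
    exception clause absorbs the condition."""


@dataclass(frozen=True, slots=True)
class ControlDecision:
    """Outcome of one control tick."""

    stage: int
    n_fans_running: int
    pad_command: bool
    vrr: float               # required airflow, m3 s-1 (0 on the stage-0 path)
    qv: float                # heat to remove over the horizon, W
    exception_fired: int | None   # None, 1, 2 or 3
    stage0_duty: float = 0.0      # duty fraction of the intermittent pair at stage 0
    pad_duty: float = 1.0         # fraction of the tick the pad runs when commanded


def ventilation_heat_requirement(Ti: float, Td: float, Qa: float, Ql: float,
                                 Qd: float, cfg: HouseConfig) -> float:
    """Heat to be removed by ventilation over the horizon (W). Negative means
    the house needs warming, not ventilation."""
    air_mass = cfg.rho * cfg.cp * cfg.Vb * (Ti - Td) / cfg.delta_t
    return air_mass + Qa + Ql + Qd


def effective_delta_t(Ti: float, To: float, Tc: float,
                      mode: DenominatorMode = "inlet_corrected") -> float:
    """Indoor-to-inlet temperature difference used in the VRR denominator."""
    if mode == "inlet_corrected":
        return Ti - (To - Tc)
    if mode == "as_printed":
        return Ti - To - Tc
    raise ValueError(f"unknown denominator mode {mode!r}")


def required_ventilation_rate(Qv: float, Ti: float, To: float, Tc: float,
                              cfg: HouseConfig,
                              denominator_mode: DenominatorMode = "inlet_corrected",
                              ) -> float:
    """Airflow (m3 s-1) that removes Qv over the horizon; clamped to >= 0.

    Raises :class:`DegenerateDenominator` when the indoor-to-inlet
    difference is within ``cfg.degenerate_dT_tol`` of zero — the caller must
    fall back to the air-exchange bound VRR2 = Vb/delta_t.
    """
    dT = effective_delta_t(Ti, To, Tc, denominator_mode)
    if abs(dT) < cfg.degenerate_dT_tol:
        raise DegenerateDenominator(
            f"|Ti - inlet| = {abs(dT):.3g} C below tolerance {cfg.degenerate_dT_tol} C"
        )
    return max(Qv / (cfg.rho * cfg.cp * dT), 0.0)


def air_exchange_rate(cfg: HouseConfig) -> float:
    """VRR2: one full house-volume exchange per horizon (m3 s-1)."""
    return cfg.Vb / cfg.delta_t


def stage_from_vrr(vrr: float, age_days: float, cfg: HouseConfig,
                   ) -> tuple[int, int, float]:
    """Map a required airflow onto the fan-stage ladder.

    Returns ``(stage, n_fans, stage0_duty)``. The required fan count is
    ``ceil(vrr / per-fan capacity)`` and the stage is the smallest whose
    count covers it (capped at the top stage — ceil guarantees capacity
    where the ladder allows). Requirements at or below the age-dependent
    minimum ventilation map to stage 0, where the intermittent two-fan
    pair runs at the duty fraction delivering exactly the minimum rate.
    """
    if vrr < 0:
        raise ValueError("vrr must be >= 0")
    min_vent_m3h = cfg.min_vent(age_days)
    pair = cfg.stage_fans[0]
    if vrr * 3600.0 <= min_vent_m3h:
        duty = min(min_vent_m3h / (pair * cfg.fan_capacity), 1.0)
        return 0, pair, duty
    n_req = math.ceil(vrr / cfg.fan_capacity_m3s - 1e-9)
    for stage in range(1, len(cfg.stage_fans)):
        if cfg.stage_fans[stage] >= n_req:
            return stage, cfg.stage_fans[stage], 0.0
    top = cfg.top_stage
    return top, cfg.stage_fans[top], 0.0


def pad_hysteresis(Ti: float, To: float, Td: float, cfg: HouseConfig,
                   prev_pad_state: bool) -> bool:
    """Evaporative-pad on/off decision with an anti-chatter band.

    The pad switches ON only in genuinely hot conditions — outdoor air at
    least 3*Tda above the setpoint AND indoor air more than 2*Tda + 0.5 C
    above it — and switches OFF once the house has cooled to Td + 2*Tda.
    Between the thresholds the previous state holds, so a temperature
    oscillating inside the band cannot cycle the pads.
    """
    on_off_gap = Td + 2.0 * cfg.Tda
    if prev_pad_state:
        return Ti > on_off_gap
    return To >= Td + 3.0 * cfg.Tda and Ti > on_off_gap + 0.5


def decide(env: EnvironmentState, flock: FlockState, schedule: SetpointSchedule,
           cfg: HouseConfig, prev_pad_state: bool,
           denominator_mode: DenominatorMode = "inlet_corrected",
           ) -> ControlDecision:
    """One full control tick: loads, Qv, exception clauses, stage and pad.

    Exception clauses are evaluated in numerical order and the first match
    short-circuits the rest; ``exception_fired`` records which one (or
    ``None`` when the plain VRR path ran).
    """
    Td = schedule.setpoint(flock.age_days)
    hour = (env.timestamp / 3600.0) % 24.0
    Qa, Ql = flock_heat(flock, env.Ti, hour, clamp_negative=True)
    Qd = envelope_heat(env.Ti, env.To, cfg.envelope)
    Qv = ventilation_heat_requirement(env.Ti, Td, Qa, Ql, Qd, cfg)
    vrr2 = air_exchange_rate(cfg)

    # Exception 1: house at or below the comfort band -> minimum ventilation.
    if Qv < 0.0 or env.Ti < Td + cfg.Tda:
        pad = pad_hysteresis(env.Ti, env.To, Td, cfg, prev_pad_state)
        stage, n_fans, duty = stage_from_vrr(0.0, flock.age_days, cfg)
        return ControlDecision(stage, n_fans, pad, 0.0, Qv, 1, duty)

    pad = pad_hysteresis(env.Ti, env.To, Td, cfg, prev_pad_state)
    if pad:
        # Exception 2: pads run; recompute the requirement with cooled inlet air.
        Tc = pad_temperature_drop(env.To, env.Tow, cfg.pad_efficiency, True)
        try:
            vrr = required_ventilation_rate(Qv, env.Ti, env.To, Tc, cfg,
                                            denominator_mode)
        except DegenerateDenominator:
            vrr = vrr2
        stage, n_fans, duty = stage_from_vrr(vrr, flock.age_days, cfg)
        return ControlDecision(stage, n_fans, True, vrr, Qv, 2, duty)

    if env.To >= Td + cfg.Tda:
        # Exception 3: hot outside, pads off -> cap at one air exchange per horizon.
        try:
            vrr = required_ventilation_rate(Qv, env.Ti, env.To, 0.0, cfg,
                                            denominator_mode)
        except DegenerateDenominator:
            vrr = vrr2
        vrr = min(vrr, vrr2)
        stage, n_fans, duty = stage_from_vrr(vrr, flock.age_days, cfg)
        return ControlDecision(stage, n_fans, False, vrr, Qv, 3, duty)

    # Plain path: cool outdoor air, ventilate at the computed requirement.
    try:
        vrr = required_ventilation_rate(Qv, env.Ti, env.To, 0.0, cfg,
                                        denominator_mode)
    except DegenerateDenominator:
        vrr = vrr2
    stage, n_fans, duty = stage_from_vrr(vrr, flock.age_days, cfg)
    return ControlDecision(stage, n_fans, False, vrr, Qv, None, duty)
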