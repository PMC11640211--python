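"""Threshold-based baseline controller.

This is the conventional farm controller used for head-to-head comparison:
the operator programs, per bird age, a start temperature for each fan stage
and a pad threshold. The running stage is simply the highest stage whose
start temperature the indoor air has reached; the pad runs with a fixed
intermittent duty (default 60 s per 300 s) whenever the indoor temperature
is at or above its threshold. No heat balance, no outdoor-temperature
dependence.
"""

from __future__ import annotations

from .config import HouseConfig, StageThresholdTable
from .controller import ControlDecision

#: Default intermittent pad duty: 60 s per 5 min cycle (midpoint of the
#: 40-80 s range typical of threshold controllers).
DEFAULT_PAD_DUTY = 60.0 / 300.0


def decide_baseline(Ti: float, age_days: float, table: StageThresholdTable,
                    cfg: HouseConfig, prev_pad_state: bool,
                    pad_duty: float = DEFAULT_PAD_DUTY) -> ControlDecision:
    """Stage and pad decision from indoor temperature alone.

    The stage comparison is ``Ti >= start`` (activation when the indoor
    temperature *reaches* the programmed value); no deadband is applied on
    the way down, matching a memoryless thermostat ladder. Raises if
    ``age_days`` is outside the threshold table's range.
    """
    starts = table.stage_starts(age_days)
    stage = 0
    for k, start in enumerate(starts, start=1):
        if Ti >= start:
            stage = k
    if stage == 0:
        pair = cfg.stage_fans[0]
        duty = min(cfg.min_vent(age_days) / (pair * cfg.fan_capacity), 1.0)
        n_fans = pair
    else:
        duty = 0.0
        n_fans = cfg.stage_fans[min(stage, cfg.top_stage)]
    pad = Ti >= table.pad_threshold(age_days)
    return ControlDecision(stage=min(stage, cfg.top_stage), n_fans_running=n_fans,
                           pad_command=pad, vrr=0.0, qv=0.0, exception_fired=None,
                           stage0_duty=duty, pad_duty=pad_duty if pad else 1.0)
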