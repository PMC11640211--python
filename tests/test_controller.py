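"""Heat-balance VRR controller: Qv, VRR, stage mapping, pad hysteresis,
and the exception-clause decision logic."""

import math

import numpy as np
import pytest

from broilervent import (DegenerateDenominator, EnvironmentState, FlockState,
                         air_exchange_rate, decide, pad_hysteresis,
                         required_ventilation_rate, stage_from_vrr,
                         ventilation_heat_requirement)
from broilervent.controller import effective_delta_t

from conftest import constant_setpoints
from _oracles import first_matching_exception


class TestVentilationHeatRequirement:
    def test_balanced_house_needs_nothing(self, cfg):
        assert ventilation_heat_requirement(25, 25, 0, 0, 0, cfg) == 0.0

    def test_air_mass_term(self, cfg):
        # 1.2 * 1006 * 5176.5 * 2 / 150
        expected = 1.2 * 1006 * 5176.5 * 2 / 150
        assert ventilation_heat_requirement(27, 25, 0, 0, 0, cfg) == pytest.approx(
            expected, rel=1e-9)
        assert expected == pytest.approx(83321, abs=1)

    def test_additive_in_loads(self, cfg):
        base = ventilation_heat_requirement(27, 25, 1000, 2000, -500, cfg)
        bumped = ventilation_heat_requirement(27, 25, 1000 + 777, 2000, -500, cfg)
        assert bumped - base == pytest.approx(777.0)


class TestRequiredVentilationRate:
    def test_zero_load_zero_flow(self, cfg):
        assert required_ventilation_rate(0, 28, 24, 0, cfg) == 0.0

    def test_reference_value(self, cfg):
        qv = 1.2 * 1006 * 5176.5 * 2 / 150
        vrr = required_ventilation_rate(qv, 28, 24, 0, cfg)
        assert vrr == pytest.approx(qv / (1.2 * 1006 * 4), rel=1e-9)
        assert vrr == pytest.approx(17.26, abs=0.01)

    def test_inverse_in_temperature_difference(self, cfg):
        qv = 50_000.0
        v4 = required_ventilation_rate(qv, 28, 24, 0, cfg)
        v2 = required_ventilation_rate(qv, 26, 24, 0, cfg)
        assert v2 == pytest.approx(2 * v4)

    def test_negative_requirement_clamped(self, cfg):
        assert required_ventilation_rate(-10_000, 28, 24, 0, cfg) == 0.0

    def test_degenerate_denominator_signalled(self, cfg):
        with pytest.raises(DegenerateDenominator):
            required_ventilation_rate(50_000, 25.05, 25.0, 0, cfg)

    def test_denominator_modes_differ_with_pad_running(self, cfg):
        # pads cool the inlet: corrected mode grows the denominator,
        # as-printed shrinks it
        qv, ti, to, tc = 100_000.0, 30.0, 33.0, 5.0
        corrected = required_ventilation_rate(qv, ti, to, tc, cfg, "inlet_corrected")
        printed = required_ventilation_rate(qv, ti, to, tc, cfg, "as_printed")
        assert effective_delta_t(ti, to, tc, "inlet_corrected") == pytest.approx(2.0)
        assert effective_delta_t(ti, to, tc, "as_printed") == pytest.approx(-8.0)
        assert corrected > 0
        assert printed == 0.0  # negative as-printed denominator clamps to zero

    def test_monotone_in_indoor_temperature(self, cfg):
        # VRR(Ti) = (c*(Ti-Td) + L) / (rho*cp*(Ti-To)) is non-decreasing in Ti
        # whenever c*(Td-To) >= L, i.e. the outdoor air is cold enough for the
        # air-mass term to dominate the fixed loads
        td, to, load = 25.0, 20.0, 100_000.0
        c = cfg.rho * cfg.cp * cfg.Vb / cfg.delta_t
        assert c * (td - to) >= load  # regime of the invariant
        vals = []
        for ti in np.linspace(26.5, 34.0, 40):
            qv = ventilation_heat_requirement(ti, td, load, 0, 0, cfg)
            vals.append(required_ventilation_rate(qv, ti, to, 0.0, cfg))
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestStageFromVrr:
    def test_paper_scale_stage_one(self, cfg):
        # 148,000 m3/h needs exactly 4 fans of 37,000 -> stage 1
        stage, n_fans, duty = stage_from_vrr(148_000 / 3600.0, 25, cfg)
        assert (stage, n_fans) == (1, 4)

    def test_five_fans_need_stage_two(self, cfg):
        stage, n_fans, _ = stage_from_vrr(5 * cfg.fan_capacity_m3s, 25, cfg)
        assert (stage, n_fans) == (2, 6)

    def test_zero_requirement_is_minimum_ventilation(self, cfg):
        stage, n_fans, duty = stage_from_vrr(0.0, 0, cfg)
        assert stage == 0 and n_fans == 2
        assert duty == pytest.approx(1233.0 / (2 * 37000.0))

    def test_requirement_below_minimum_maps_to_stage_zero(self, cfg):
        min_m3s = cfg.min_vent(35) / 3600.0
        stage, _, duty = stage_from_vrr(min_m3s * 0.9, 35, cfg)
        assert stage == 0
        assert duty == pytest.approx(22611.0 / (2 * 37000.0))

    def test_capped_at_top_stage(self, cfg):
        stage, n_fans, _ = stage_from_vrr(100 * cfg.fan_capacity_m3s, 25, cfg)
        assert (stage, n_fans) == (5, 14)

    def test_monotone_in_requirement(self, cfg):
        stages = [stage_from_vrr(v, 25, cfg)[0]
                  for v in np.linspace(0, 160, 400)]
        assert all(b >= a for a, b in zip(stages, stages[1:]))

    def test_air_exchange_rate_maps_to_stage_one(self, cfg):
        # Vb/delta_t = 5176.5/150 = 34.51 m3/s ~ 124,236 m3/h -> 4 fans
        vrr2 = air_exchange_rate(cfg)
        assert vrr2 == pytest.approx(34.51, abs=0.01)
        stage, n_fans, _ = stage_from_vrr(vrr2, 25, cfg)
        assert (stage, n_fans) == (1, 4)


class TestPadHysteresis:
    def test_turns_on_in_hot_conditions(self, cfg):
        assert pad_hysteresis(29.0, 30.0, 25.0, cfg, prev_pad_state=False)

    def test_holds_inside_band(self, cfg):
        assert pad_hysteresis(28.2, 30.0, 25.0, cfg, prev_pad_state=True)
        assert not pad_hysteresis(28.2, 30.0, 25.0, cfg, prev_pad_state=False)

    def test_turns_off_below_band(self, cfg):
        assert not pad_hysteresis(27.9, 30.0, 25.0, cfg, prev_pad_state=True)
        assert not pad_hysteresis(28.0, 30.0, 25.0, cfg, prev_pad_state=True)

    def test_cool_outdoor_air_blocks_turn_on(self, cfg):
        # outdoor below Td + 3*Tda: pads never engage from off
        assert not pad_hysteresis(30.0, 28.0, 25.0, cfg, prev_pad_state=False)

    def test_no_chattering_on_sinusoidal_sweep(self, cfg):
        # Ti oscillates through the whole band: exactly one transition per
        # half-cycle crossing, never more
        td, to = 25.0, 31.0
        t = np.linspace(0, 4 * math.pi, 4000)
        ti = 28.25 + 1.0 * np.sin(t)  # sweeps 27.25..29.25 across both thresholds
        state = False
        transitions = 0
        for x in ti:
            new = pad_hysteresis(float(x), to, td, cfg, state)
            transitions += int(new != state)
            state = new
        # two full periods -> two on and two off switches
        assert transitions == 4


class TestDecide:
    def test_exception_one_below_band(self, cfg, flock, setpoints):
        sched = constant_setpoints(25.0)
        env = EnvironmentState(Ti=26.0, To=20.0, RHo=50)  # Ti < Td + 1.5
        d = decide(env, flock, sched, cfg, prev_pad_state=False)
        assert d.exception_fired == 1
        assert d.stage == 0
        assert d.stage0_duty > 0

    def test_exception_two_runs_pads_and_recomputes(self, cfg, flock):
        sched = constant_setpoints(25.0)
        env = EnvironmentState(Ti=30.0, To=33.0, RHo=50)
        d = decide(env, flock, sched, cfg, prev_pad_state=False)
        assert d.exception_fired == 2
        assert d.pad_command
        assert d.vrr > 0

    def test_exception_three_caps_at_air_exchange(self, cfg, flock):
        sched = constant_setpoints(25.0)
        # warm outside, indoor close to outdoor, pads not triggered
        env = EnvironmentState(Ti=27.0, To=27.0, RHo=50)
        d = decide(env, flock, sched, cfg, prev_pad_state=False)
        assert d.exception_fired == 3
        assert not d.pad_command
        assert d.vrr <= air_exchange_rate(cfg) + 1e-9
        # the degenerate Ti == To denominator was absorbed by the VRR2 cap
        assert d.stage >= 1

    def test_plain_path_cool_outdoor(self, cfg, flock):
        sched = constant_setpoints(25.0)
        env = EnvironmentState(Ti=28.0, To=20.0, RHo=50)
        d = decide(env, flock, sched, cfg, prev_pad_state=False)
        assert d.exception_fired is None
        assert d.vrr > 0
        assert d.stage >= 1

    def test_at_most_one_exception_and_first_match_wins(self, cfg):
        """Exhaustive sweep against a brute-force first-match rule
        interpreter over a (Ti, To, Td) grid."""
        flock = FlockState(28, 28120, 1.5)
        for td in (22.0, 25.0, 28.0):
            sched = constant_setpoints(td)
            for ti in np.linspace(td - 4, td + 8, 25):
                for to in np.linspace(td - 6, td + 8, 25):
                    env = EnvironmentState(Ti=float(ti), To=float(to), RHo=60)
                    d = decide(env, flock, sched, cfg, prev_pad_state=False)
                    expected = first_matching_exception(d.qv, float(ti), float(to),
                                                        td, cfg.Tda)
                    assert d.exception_fired == expected, (ti, to, td)

    def test_zero_flock_at_setpoint_is_minimum_ventilation(self, cfg):
        sched = constant_setpoints(25.0)
        flock = FlockState(28, 0, 1.5)
        env = EnvironmentState(Ti=25.0, To=25.0, RHo=50)
        d = decide(env, flock, sched, cfg, prev_pad_state=False)
        assert d.exception_fired == 1 and d.stage == 0
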