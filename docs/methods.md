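# Methods

This note documents the models, parameter choices and numerical decisions
behind `broilervent`, and what the synthetic closed-loop experiments can
and cannot say about real broiler houses.

## Zone model and its assumptions

The house is a single well-mixed air zone. With indoor temperature `Ti`,
delivered airflow `q` (m³ s⁻¹) entering at the inlet temperature
`Ta = To − Tc`, envelope conductance `UA = Uw·Aw + Uf·Af` and flock loads
`Qa + Ql`, the zone obeys

```
ρ·Cp·Vb · dTi/dt = Qa + Ql + UA·(To − Ti) + ρ·Cp·q·(Ta − Ti).
```

Assumptions worth keeping in mind:

- **Complete mixing.** No longitudinal gradient along the tunnel, although
  in a real 87 m house the air warms as it travels toward the fans. The
  audit's "anomalous" quadrant (over-ventilated yet hot) is in part a
  signature of such unmodelled lags.
- **Air mass only.** No thermal mass for walls, litter or the birds
  themselves; the only heat capacity is `ρ·Cp·Vb`. Time constants are
  therefore optimistic (minutes rather than tens of minutes).
- **No moisture balance.** Outdoor humidity is generated (the pad model
  needs the wet-bulb temperature) but indoor RH is not simulated; the
  mechanisms that set nighttime indoor humidity in real houses are poorly
  characterised, and simulated logs carry no indoor-RH channel.
- **Floor term as printed.** The floor conductance is driven by
  `Ti − To` like the walls, although real slabs couple to ground
  temperature. With `Uf = 2.75 W m⁻² K⁻¹` over 1218 m² this term
  dominates envelope exchange; treat absolute envelope losses as rough.

## Flock bioenergetics

Per-bird sensible heat is `m^0.75 · (307.87 − 15.63·Ti + 0.3105·Ti²)`
kcal·kg⁻⁰·⁷⁵·day⁻¹ and latent heat is
`0.4 · (583.5 − 17.1·Ti + 25.25·m)` kcal·day⁻¹ (40% of daily water intake
evaporating indoors), both converted to watts by 4184/86400 and modulated
by the circadian factor `Sc = 1 − a·sin(2π(h + 6 − hmin)/24)`
(a = 0.21/0.46, hmin = 0.38/0.67 h for sensible/latent). `Sc` has mean 1
over a day, so daily heat totals are unaffected by the modulation.

Two unit decisions deserve prominence:

- **Growth curve in grams.** The quadratic
  `−35.783 + 19.098·d + 0.6008·d²` evaluates to ≈1369 at d = 35 — a
  plausible broiler mass only in grams — so the implementation divides by
  1000. The curve is negative for d ≤ 1; `broiler_mass` raises there
  unless `floor_mass=True` substitutes a 42 g hatch weight (the control
  algorithm is intended for use from about day 20, so this edge is
  outside its envelope).
- **Latent heat is positive.** `Ql` is defined as heat the birds add to
  the indoor air (it appears as a load in `Qv`), and the intake
  polynomial is clamped: above ≈35 °C for small birds it goes negative,
  which is a fit-envelope artefact, not negative evaporation. Library
  calls raise by default; the closed-loop paths pass
  `clamp_negative=True` so a transient excursion degrades to `Ql = 0`
  rather than crashing an episode.

## Controller numerics

- **Denominator mode.** The default `inlet_corrected` mode uses
  `Ti − (To − Tc)`: running pads cool the inlet, widening the effective
  temperature difference and *reducing* the required airflow.
  The alternative `as_printed` mode subtracts both terms (`Ti − To − Tc`),
  so pad operation shrinks the denominator and *raises* the requirement;
  it is physically inverted and kept selectable only for replicating
  controllers programmed that way.
- **Degenerate denominator.** When `|Ti − inlet| < 0.2 °C` the quotient
  is meaningless; every decision path absorbs the condition by falling
  back to the air-exchange bound `VRR₂ = Vb/Δt`. The 0.2 °C tolerance is
  configurable (`degenerate_dT_tol`).
- **Stage mapping.** Fan requirement is `ceil(VRR / per-fan capacity)`
  (guaranteeing capacity rather than rounding to nearest), with a 1e-9
  relative fuzz so that an exact integer multiple of the fan capacity is
  not pushed to the next fan; the stage is the smallest whose fan count
  covers the requirement, capped at the top stage.
- **Stage 0 as a duty fraction.** The intermittent two-fan minimum
  ventilation is modelled as a continuous duty
  `min_vent/(2 × fan capacity)` rather than explicit on/off cycling —
  cycle times are installation-specific, and only the delivered average
  matters at the zone level. Minimum ventilation interpolates linearly in
  age between 1233 m³ h⁻¹ (day 0) and 22,611 m³ h⁻¹ (day 35), flat
  beyond; any table can be configured.
- **Pad hysteresis.** On only when `To ≥ Td + 4.5` **and** `Ti > Td + 4.0`
  (with Tda = 1.5); off at `Ti ≤ Td + 3.0`; hold in between. The
  asymmetric on/off thresholds are what prevents chattering, verified by
  sinusoidal-sweep tests counting transitions.
- **Two clocks.** Decisions are re-taken every `control_interval` = 10 s;
  `Δt` = 150 s is only the energy-balance horizon inside `Qv` and `VRR₂`.

## Baseline controller defaults

Real installations program the stage thresholds empirically and rarely
publish them. The default `StageThresholdTable` is therefore synthetic
and clearly labelled as such: set temperature declining linearly from
32 °C (day 0) to 24 °C (day 28, flat after), stage k starting at
`Td + k × 1 °C`, pad threshold `Td + 5 °C`, pad duty 60 s per 300 s when
engaged. These reproduce the qualitative behaviour of a threshold ladder
(all fans by `Td + 5`, pads intermittent), not any specific farm.

## Synthetic weather

`weather_generate` produces a pure 24 h sinusoid between `night_min_T`
and `day_max_T` peaking at `peak_hour` (15:00 default), RH in exact
anti-phase, plus seeded i.i.d. Gaussian noise on temperature. The
`hot_spell` preset (37/26 °C, RH 52/90%) emulates an extreme summer
regime: daytime outdoor temperature inside 33–37 °C and nights above
26 °C, i.e. above a 24 °C set temperature around the clock. Real weather
has day-to-day trends, autocorrelated noise, cloud transients and
humidity excursions; none are modelled. Consequently the closed-loop
comparisons show *directional* effects (which controller is cooler, which
uses fewer fan-hours) under controlled conditions — they do not predict
the magnitude of savings on any particular farm or season.

"Daytime" in summaries means within ±4 h of the temperature peak, where
the noiseless hot-spell sinusoid sits in the 33–37 °C band.

## Integration accuracy

Explicit Euler at the 10 s control interval is first-order; against the
closed-form solution of the linear zone ODE the observed order is ≈1
(error halves from dt = 10 → 5 → 2.5 s) and the absolute error over one
150 s horizon is a few hundredths of a degree — far below sensor
resolution. `run_episode(substeps=n)` subdivides the interval if a
configuration with much higher airflow-to-volume ratio makes the explicit
step stiff (stability requires roughly `dt < Vb/q`; the default plant is
comfortably inside).

## The one-horizon restoration property

The VRR construction removes, at the *initial* removal rate, exactly the
excess air heat plus one horizon of loads. Along the trajectory the
removal rate decays as `Ti` falls, so integrating the zone at a fixed
`q = VRR` for Δt closes the gap to `Td` only approximately: for small
loads the relative shortfall is ≈ `(Ti − Td) / (2(Ti − Ta))`. The ≥95%
restoration check therefore runs in the regime where the construction is
accurate — a cold inlet (To = 5 °C), the minimal 1.5 °C gap and a small
flock (2000 one-kg birds) with a near-adiabatic envelope — with the
closed-form exponential as the oracle. In warm weather the controller
compensates for the per-horizon shortfall by re-planning every 10 s.

## Audit conventions

- Default audit cadence 10 min (any uniform cadence accepted); the PLC
  JSON dialect resamples 10 s records by bin means (continuous channels)
  and ≥50% duty (pad state).
- The quadrant summary excludes pad-on records by default, computes
  percentages by exact rational arithmetic on counts (they always sum to
  100), and classifies sign-boundary records (`vr_disc = 0` outside the
  proper band) with the non-negative, i.e. under-ventilated, side.
- Fan-hours can be computed from the logged fan count or, when the
  per-fan capacity is supplied, from delivered airflow — the latter
  correctly duty-weights the intermittent minimum-ventilation stage.
- Reported kWh are rounded to integers for display; raw values are kept
  in machine-readable output.

## Problem sizes

The closed-loop comparison runs 5-day episodes at the 10 s control
interval (43,200 ticks per controller) over ten seeds; the
exception-precedence check sweeps a 10,404-point (Ti, To, Td) grid; the
convergence study uses one 150 s horizon at three step sizes. These sizes
give stable statistics for every property tested while keeping a full
test-plus-acceptance run around half a minute.

## Known limitations

- Absolute energy figures inherit the single-zone and constant-fan-power
  idealisations; only relative comparisons between controllers under
  identical weather are meaningful.
- Pad effectiveness is a constant ε = 0.65; real pads vary with
  saturation state and water distribution.
- Static-pressure inlet control is out of scope (inlets are assumed
  regulated independently), as are humidity/gas setpoints, bird-level
  heterogeneity, and disease or mortality dynamics.
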