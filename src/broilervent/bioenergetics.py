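"""Broiler heat production and growth.

Per-bird sensible and latent heat output are empirical functions of indoor
temperature and body mass, modulated over the 24 h day by a sine term that
captures the circadian swing in metabolic activity. Body mass follows a
quadratic growth curve in bird age fitted to weekly reference weights for
commercial broilers.

Unit conventions
----------------
The heat-production polynomials are daily metabolic rates expressed in
kcal per day (per kg^0.75 of metabolic mass for the sensible term); they
are converted to watts with the factor 4184 J/kcal / 86400 s/day. The
growth polynomial evaluates in grams and is returned in kg. Both latent
and sensible heat are positive quantities: heat the birds add to the
indoor air.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

#: kcal/day -> W
KCAL_PER_DAY_TO_W = 4184.0 / (24.0 * 3600.0)

#: Circadian modulation constants for sensible heat: amplitude and phase (h).
QA_ACTIVITY = (0.21, 0.38)
#: Circadian modulation constants for latent heat.
QL_ACTIVITY = (0.46, 0.67)

#: Typical day-old chick mass (kg), used as an optional floor for the growth
#: curve whose quadratic fit is negative below ~2 days of age.
HATCH_MASS_KG = 0.042


@dataclass(frozen=True, slots=True)
class ActivityParams:
    """Amplitude ``a`` (dimensionless, 0 <= a < 1) and phase ``hmin`` (hours)."""

    amplitude: float
    phase_const: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError(f"amplitude must be in [0, 1), got {self.amplitude}")


QA_PARAMS = ActivityParams(*QA_ACTIVITY)
QL_PARAMS = ActivityParams(*QL_ACTIVITY)


@dataclass(frozen=True, slots=True)
class FlockState:
    """Age, head count and per-bird mass of the flock."""

    age_days: int
    bird_count: int
    mass_per_bird: float

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise ValueError("age_days must be >= 0")
        if self.bird_count < 0:
            raise ValueError("bird_count must be >= 0")
        if self.mass_per_bird <= 0:
            raise ValueError("mass_per_bird must be > 0")

    @classmethod
    def at_age(cls, age_days: int, bird_count: int, *,
               floor_mass: bool = False) -> "FlockState":
        """Build a flock with mass taken from the growth curve at ``age_days``."""
        return cls(age_days, bird_count,
                   broiler_mass(age_days, floor_mass=floor_mass))


def broiler_mass(age_days: float, *, floor_mass: bool = False) -> float:
    """Mean body mass (kg) of a broiler at ``age_days`` days of age.

    Quadratic growth curve evaluated in grams and converted to kg. The fit
    is negative for the first ~2 days of life, which is outside its useful
    envelope; by default this raises, but ``floor_mass=True`` substitutes a
    day-old chick weight so simulations may start at stocking.
    """
    if age_days < 0:
        raise ValueError("age_days must be >= 0")
    grams = -35.783 + 19.098 * age_days + 0.6008 * age_days**2
    if grams <= 0.0:
        if floor_mass:
            return HATCH_MASS_KG
        raise ValueError(
            f"growth curve is non-positive at age {age_days} d; "
            "pass floor_mass=True to clamp to hatch weight"
        )
    return grams / 1000.0


def activity_modulation(hour_of_day: float, params: ActivityParams) -> float:
    """Circadian activity factor Sc = 1 - a*sin(2*pi*(h + 6 - hmin)/24).

    Dimensionless, bounded in [1-a, 1+a], period 24 h, mean 1 over a day.
    """
    if not 0.0 <= hour_of_day < 24.0:
        raise ValueError(f"hour_of_day must be in [0, 24), got {hour_of_day}")
    arg = 2.0 * math.pi * (hour_of_day + 6.0 - params.phase_const) / 24.0
    return 1.0 - params.amplitude * math.sin(arg)


def _sensible_poly(Ti: float) -> float:
    # kcal kg^-0.75 day^-1; positive for all real Ti (negative discriminant)
    return 307.87 - 15.63 * Ti + 0.3105 * Ti**2


def _latent_poly(Ti: float, mass_kg: float) -> float:
    # kcal day^-1 before the 40%-evaporation factor
    return 583.5 - 17.1 * Ti + 25.25 * mass_kg


def sensible_heat_per_bird(Ti: float, mass_per_bird: float, hour_of_day: float,
                           *, Sc: float | None = None) -> float:
    """Sensible heat output of one bird (W).

    ``m^0.75 * (307.87 - 15.63*Ti + 0.3105*Ti^2) * 4184/86400 * Sc`` where the
    polynomial is a daily metabolic rate per unit metabolic mass and Sc is the
    circadian factor (overridable for testing and steady-state analysis).
    """
    if mass_per_bird < 0:
        raise ValueError("mass_per_bird must be >= 0")
    if Sc is None:
        Sc = activity_modulation(hour_of_day, QA_PARAMS)
    return mass_per_bird**0.75 * _sensible_poly(Ti) * KCAL_PER_DAY_TO_W * Sc


def latent_heat_per_bird(Ti: float, mass_per_bird: float, hour_of_day: float,
                         *, Sc: float | None = None,
                         clamp_negative: bool = False) -> float:
    """Latent heat one bird adds to the air (W), assuming 40% of daily water
    intake evaporates indoors.

    The underlying intake polynomial turns negative above roughly 35 C for
    small birds — outside the envelope of the fit. By default that raises;
    ``clamp_negative=True`` returns 0 instead, which closed-loop callers use
    so a transient hot excursion degrades gracefully.
    """
    if mass_per_bird < 0:
        raise ValueError("mass_per_bird must be >= 0")
    if Sc is None:
        Sc = activity_modulation(hour_of_day, QL_PARAMS)
    poly = _latent_poly(Ti, mass_per_bird)
    if poly < 0.0:
        if clamp_negative:
            return 0.0
        raise ValueError(
            f"latent-heat polynomial negative at Ti={Ti} C, m={mass_per_bird} kg "
            "(evaporation cannot be negative); pass clamp_negative=True to floor at 0"
        )
    return 0.4 * poly * KCAL_PER_DAY_TO_W * Sc


def flock_heat(flock: FlockState, Ti: float, hour_of_day: float,
               *, clamp_negative: bool = False) -> tuple[float, float]:
    """Total (sensible, latent) heat of the flock in W: per-bird values x head count."""
    qa = flock.bird_count * sensible_heat_per_bird(Ti, flock.mass_per_bird, hour_of_day)
    ql = flock.bird_count * latent_heat_per_bird(Ti, flock.mass_per_bird, hour_of_day,
                                                 clamp_negative=clamp_negative)
    return qa, ql
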