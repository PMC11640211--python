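"""Psychrometrics, evaporative-pad cooling, and envelope heat transfer."""

from __future__ import annotations

from dataclasses import dataclass
import math

from .config import EnvelopeSpec


@dataclass(slots=True)
class EnvironmentState:
    """One time point of indoor/outdoor temperature and humidity.

    ``Tow`` (outdoor wet-bulb) is derived from ``To`` and ``RHo`` on
    construction when not supplied.
    """

    Ti: float
    To: float
    RHo: float
    RHi: float | None = None   # indoor moisture is not always measured/modelled
    Tow: float | None = None
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.RHi is not None and not 0.0 < self.RHi <= 100.0:
            raise ValueError(f"RHi must be in (0, 100], got {self.RHi}")
        if not 0.0 < self.RHo <= 100.0:
            raise ValueError(f"RHo must be in (0, 100], got {self.RHo}")
        if self.Tow is None:
            self.Tow = wet_bulb(self.To, self.RHo)
        if self.Tow > self.To + 1e-9:
            raise ValueError("wet-bulb temperature cannot exceed dry-bulb")


def wet_bulb(T: float, RH: float) -> float:
    """Wet-bulb temperature (C) from dry-bulb T (C) and relative humidity RH (%).

    Stull's empirical one-line approximation, valid for roughly
    5% <= RH <= 99% and -20 C <= T <= 50 C at standard pressure; accurate to
    a few tenths of a degree over most of that box. Raises outside it.
    """
    if not 5.0 <= RH <= 99.0:
        raise ValueError(f"RH={RH}% outside the approximation's validity range [5, 99]")
    if not -20.0 <= T <= 50.0:
        raise ValueError(f"T={T} C outside the approximation's validity range [-20, 50]")
    tw = (
        T * math.atan(0.151977 * math.sqrt(RH + 8.313659))
        + math.atan(T + RH)
        - math.atan(RH - 1.676331)
        + 0.00391838 * RH**1.5 * math.atan(0.023101 * RH)
        - 4.686035
    )
    return min(tw, T)


def pad_temperature_drop(To: float, Tow: float, efficiency: float,
                         pad_on: bool) -> float:
    """Air temperature drop Tc (C) across the evaporative cooling pad.

    Tc = (To - Tow) * efficiency while the pad runs; an idle pad drops
    nothing (efficiency effectively zero). The wet-bulb depression bounds
    the achievable cooling, so 0 <= Tc <= To - Tow.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("pad efficiency must be in [0, 1]")
    if Tow > To + 1e-9:
        raise ValueError("Tow must not exceed To")
    if not pad_on:
        return 0.0
    return max(To - Tow, 0.0) * efficiency


def envelope_heat(Ti: float, To: float, spec: EnvelopeSpec) -> float:
    """Conductive heat flow through walls/roof and floor (W).

    Qd = -(Uw*Aw + Uf*Af) * (Ti - To): negative when the house is warmer
    than outdoors, i.e. the envelope sheds heat and reduces the load the
    ventilation must remove. The floor term uses the same indoor-outdoor
    difference as the walls (no separate ground temperature).
    """
    ua = spec.Uw * spec.Aw + spec.Uf * spec.Af
    return -ua * (Ti - To)
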