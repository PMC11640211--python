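"""Independent oracles used by several test modules.

These deliberately re-derive behaviour from first principles (rule text,
closed-form ODE solutions) rather than calling the implementation paths
they are used to check.
"""

from __future__ import annotations

import math


def first_matching_exception(Qv: float, Ti: float, To: float, Td: float,
                             Tda: float) -> int | None:
    """Brute-force rule interpreter: the exception clauses as literal
    first-match rules (pad previously off)."""
    rules = [
        (1, Qv < 0 or Ti < Td + Tda),
        (2, To >= Td + 3 * Tda and Ti > Td + 2 * Tda + 0.5),
        (3, To >= Td + Tda),
    ]
    for idx, hit in rules:
        if hit:
            return idx
    return None


def closed_form_zone_temperature(t: float, Ti0: float, To: float, Ta: float,
                                 q: float, ua: float, load_w: float,
                                 rho: float, cp: float, vb: float) -> float:
    """Exact solution of the linear single-zone ODE

        rho*cp*vb * dTi/dt = load + ua*(To - Ti) + rho*cp*q*(Ta - Ti)

    with constant load, envelope conductance ``ua`` to outdoor air at To,
    and ventilation ``q`` delivering inlet air at Ta.
    """
    rc = rho * cp
    b = (ua + rc * q) / (rc * vb)
    ti_inf = (load_w + ua * To + rc * q * Ta) / (ua + rc * q)
    return ti_inf + (Ti0 - ti_inf) * math.exp(-b * t)
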