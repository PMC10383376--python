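"""Concentration-addition (CA) mixture potency mathematics.

The CA model treats mixture components as dilutions of one another: the
mixture's median-effect concentration follows from the components' toxic
units, TU_i = C_i / TD50_i, and TU_A + TU_B = 1 denotes simple addition. At
the equitoxic ratio each component contributes half a toxic unit,
C_i = 0.5 * TD50_i, so the mixture TD50 is the plain average of the
component TD50s:

    TD50_mix = C_A + C_B = 0.5 * TD50_A + 0.5 * TD50_B

Concentration fractions p_i = C_i / C_M then recover the component
concentrations from TD50_mix. With TD50 weights, p_A = TD50_A / (TD50_A + TD50_B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Relative tolerance for fraction and toxic-unit identities.
TOL = 1e-9


def toxic_unit(c: float, td50: float) -> float:
    """Toxic unit of one component: its concentration over its own TD50."""
    if not td50 > 0:
        raise ValueError("td50 must be positive")
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return c / td50


def equitoxic_mixture_td50(td50_a: float, td50_b: float) -> float:
    """Mixture TD50 under the equitoxic CA construction: the component average."""
    if not (td50_a > 0 and td50_b > 0):
        raise ValueError("TD50 values must be positive")
    return 0.5 * td50_a + 0.5 * td50_b


def concentration_fractions(weight_a: float, weight_b: float) -> tuple[float, float]:
    """Normalize two positive weights into concentration fractions summing to 1.

    With TD50 weights this reproduces the equitoxic construction
    (``C_i = 0.5 * TD50_i``), i.e. ``p_a = td50_a / (td50_a + td50_b)``.
    """
    if not (weight_a > 0 and weight_b > 0):
        raise ValueError("weights must be positive")
    p_a = weight_a / (weight_a + weight_b)
    return p_a, 1.0 - p_a


def component_concentrations(p_a: float, p_b: float, td50_mix: float) -> tuple[float, float]:
    """Recover component concentrations from fractions and the mixture TD50."""
    if abs((p_a + p_b) - 1.0) > TOL:
        raise ValueError(f"fractions must sum to 1, got {p_a + p_b!r}")
    if not td50_mix > 0:
        raise ValueError("td50_mix must be positive")
    return p_a * td50_mix, p_b * td50_mix


def regression_target(td50_mix: float, mol_weight_mix: float | None = None) -> float:
    """Potency target: -log10 of the mixture TD50.

    By default the dose stays in its native mg/kg/day units. When a mixture
    molecular weight (g/mol) is supplied, the dose is first converted to a
    molar-equivalent rate (mol/kg/day) before the log — the convention must
    be applied identically at train and predict time, so fitted models record
    it in their manifest.
    """
    if not td50_mix > 0:
        raise ValueError("td50_mix must be positive")
    value = td50_mix
    if mol_weight_mix is not None:
        if not mol_weight_mix > 0:
            raise ValueError("mol_weight_mix must be positive")
        value = (td50_mix / 1000.0) / mol_weight_mix  # mg -> g -> mol
    return -math.log10(value)


def inverse_regression_target(y: float, mol_weight_mix: float | None = None) -> float:
    """Invert :func:`regression_target` back to a dose in mg/kg/day."""
    value = 10.0 ** (-y)
    if mol_weight_mix is not None:
        value = value * mol_weight_mix * 1000.0
    return value


@dataclass(frozen=True)
class CAMixture:
    """Full equitoxic CA chain for one binary mixture."""

    td50_a: float
    td50_b: float
    td50_mix: float
    p_a: float
    p_b: float
    c_a: float
    c_b: float
    c_m: float
    tu_a: float
    tu_b: float


def ca_chain(td50_a: float, td50_b: float) -> CAMixture:
    """Run the whole equitoxic construction from two component TD50s.

    Fractions from TD50 weights, the averaged mixture TD50, component
    concentrations, and the component toxic units (which sum to 1 under
    simple addition).
    """
    td50_mix = equitoxic_mixture_td50(td50_a, td50_b)
    p_a, p_b = concentration_fractions(td50_a, td50_b)
    c_a, c_b = component_concentrations(p_a, p_b, td50_mix)
    return CAMixture(
        td50_a=td50_a,
        td50_b=td50_b,
        td50_mix=td50_mix,
        p_a=p_a,
        p_b=p_b,
        c_a=c_a,
        c_b=c_b,
        c_m=c_a + c_b,
        tu_a=toxic_unit(c_a, td50_a),
        tu_b=toxic_unit(c_b, td50_b),
    )
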