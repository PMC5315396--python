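"""Unit handling for the (g, cm, day) internal system.

Concentrations and densities are carried in g/cm^3, lengths in cm, time in
days.  Mechanical quantities (moduli, pressures, stresses) are carried in
N/cm^2 because the literature sources quote them that way; the conversion to
the strict g/cm/day^2 system is provided for completeness and for checking
dimensional consistency, but never needs to be applied inside the solver
since the equilibrium equation is homogeneous in the stress unit.
"""

from __future__ import annotations

#: 1 mmHg in Pa (SI definition).
MMHG_TO_PA = 133.322
#: 1 Pa = 1e-4 N/cm^2.
PA_TO_N_PER_CM2 = 1.0e-4
#: 1 N = 1e5 g cm / s^2; 1 day = 86400 s, so
#: 1 N/cm^2 = 1e5 * 86400^2 g / (cm day^2).
N_PER_CM2_TO_G_CM_DAY2 = 1.0e5 * 86400.0**2

SECONDS_PER_DAY = 86400.0

#: cell-count to mass convention: 1e6 cells/ml corresponds to 1e-3 g/cm^3.
#: This is the only convention consistent with both IL-6 assay derivations.
GRAMS_PER_CELL = 1.0e-3 / 1.0e6

#: supported pressure units and their value in N/cm^2.
_PRESSURE_IN_N_CM2 = {
    "mmHg": MMHG_TO_PA * PA_TO_N_PER_CM2,
    "N/cm^2": 1.0,
    "N/mm^2": 100.0,
    "g/cm/day^2": 1.0 / N_PER_CM2_TO_G_CM_DAY2,
}


class UnitError(ValueError):
    """Raised for an unsupported unit name or unit pair."""


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure/stress value between the supported units.

    Units: ``mmHg``, ``N/cm^2``, ``N/mm^2``, ``g/cm/day^2``.
    Round-trips are exact to floating point (a single multiply/divide pair).
    """
    try:
        f = _PRESSURE_IN_N_CM2[from_unit]
    except KeyError:
        raise UnitError(f"unsupported pressure unit {from_unit!r}") from None
    try:
        t = _PRESSURE_IN_N_CM2[to_unit]
    except KeyError:
        raise UnitError(f"unsupported pressure unit {to_unit!r}") from None
    return value * (f / t)


def cells_per_ml_to_g_per_cm3(n: float) -> float:
    """Convert a cell count density (cells/ml) to mass density (g/cm^3)."""
    return n * GRAMS_PER_CELL


def ng_per_ml_to_g_per_cm3(c: float) -> float:
    """1 ng/ml = 1e-9 g/cm^3 (1 ml = 1 cm^3)."""
    return c * 1.0e-9
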