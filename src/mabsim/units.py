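"""Unit conversions used throughout the package.

Internally everything runs in hours / litres / µM / µmol; these helpers
convert to and from the units clinical papers print (mg doses, µg/mL
concentrations, mL/day/kg clearances).
"""

from __future__ import annotations

from .errors import UnitError

#: canonical spellings of the supported units
_UNITS = {"mg", "umol", "ug_per_ml", "uM", "L_per_h", "ml_per_day_per_kg"}


def convert_units(value: float, from_unit: str, to_unit: str,
                  mw: float | None = None,
                  weight_kg: float | None = None) -> float:
    """Convert ``value`` between supported unit pairs.

    Supported pairs: mg <-> umol (needs ``mw`` in g/mol), ug_per_ml <-> uM
    (needs ``mw``), L_per_h <-> ml_per_day_per_kg (needs ``weight_kg``).
    Conversions are exact arithmetic: µM = (µg/mL)*1000/MW,
    µmol = mg/MW*1000, mL/day/kg = (L/h)*1000*24/weight.
    """
    if from_unit not in _UNITS or to_unit not in _UNITS:
        raise UnitError(f"unsupported unit in pair ({from_unit!r}, {to_unit!r})")
    if from_unit == to_unit:
        return value

    pair = (from_unit, to_unit)
    if pair in (("mg", "umol"), ("umol", "mg"),
                ("ug_per_ml", "uM"), ("uM", "ug_per_ml")):
        if mw is None or mw <= 0:
            raise UnitError(f"conversion {pair} requires a positive mw")
        factor = 1000.0 / mw
        return value * factor if from_unit in ("mg", "ug_per_ml") else value / factor
    if pair in (("L_per_h", "ml_per_day_per_kg"), ("ml_per_day_per_kg", "L_per_h")):
        if weight_kg is None or weight_kg <= 0:
            raise UnitError(f"conversion {pair} requires a positive weight_kg")
        factor = 1000.0 * 24.0 / weight_kg
        return value * factor if from_unit == "L_per_h" else value / factor
    raise UnitError(f"unsupported conversion pair ({from_unit!r}, {to_unit!r})")
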