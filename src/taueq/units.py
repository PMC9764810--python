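"""Unit parsing and conversion helpers.

Internally every quantity is SI (m, s, Pa, Pa·s, m³, kg/m³).  Lab units
(µm, mm, cm, mbar, mPa·s, mL, …) are accepted only at I/O boundaries —
config files, CLI flags — through :func:`parse_quantity`, and converted
exactly once.  1 mbar = 100 Pa.
"""

from __future__ import annotations

import re

__all__ = [
    "parse_quantity",
    "si_quantity",
    "MBAR",
    "UM",
    "MM",
    "CM",
    "ML",
]

MBAR = 100.0  # Pa
UM = 1e-6  # m
MM = 1e-3  # m
CM = 1e-2  # m
ML = 1e-6  # m³

# multiplicative factor to SI, keyed by lower-cased suffix
_FACTORS = {
    # length
    "m": 1.0,
    "cm": CM,
    "mm": MM,
    "um": UM,
    "µm": UM,
    "nm": 1e-9,
    # pressure
    "pa": 1.0,
    "kpa": 1e3,
    "mbar": MBAR,
    "bar": 1e5,
    # dynamic viscosity
    "pas": 1.0,
    "pa.s": 1.0,
    "pa*s": 1.0,
    "mpas": 1e-3,
    "mpa.s": 1e-3,
    "mpa*s": 1e-3,
    "cp": 1e-3,
    # time
    "s": 1.0,
    "ms": 1e-3,
    "min": 60.0,
    "h": 3600.0,
    # volume
    "m3": 1.0,
    "l": 1e-3,
    "ml": ML,
    "ul": 1e-9,
    "µl": 1e-9,
    # area
    "m2": 1.0,
    "cm2": 1e-4,
    "mm2": 1e-6,
    # flow rate
    "m3/s": 1.0,
    "ul/s": 1e-9,
    "ul/min": 1e-9 / 60.0,
    "ml/min": ML / 60.0,
    "ml/h": ML / 3600.0,
    # density
    "kg/m3": 1.0,
    "g/ml": 1e3,
    # hydraulic resistance
    "pa.s/m3": 1.0,
    "pas/m3": 1.0,
    # velocity
    "m/s": 1.0,
    "mm/s": 1e-3,
    "um/s": 1e-6,
}

_QUANTITY_RE = re.compile(
    r"^\s*([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*([a-zA-Zµ][a-zA-Zµ0-9./*]*)?\s*$"
)


def parse_quantity(value, unit_hint: str | None = None) -> float:
    """Convert ``value`` to SI.

    ``value`` may be a plain number (taken as already SI) or a string like
    ``"180 um"``, ``"1.1cm"``, ``"0.79 mPas"``, ``"345 mbar"``.

    Parameters
    ----------
    value : float | int | str
        The quantity.
    unit_hint : str, optional
        Context string used only in error messages (e.g. the config key).
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise TypeError(f"cannot parse quantity from {type(value).__name__}")
    m = _QUANTITY_RE.match(value)
    where = f" for {unit_hint!r}" if unit_hint else ""
    if m is None:
        raise ValueError(f"malformed quantity {value!r}{where}")
    number, suffix = m.groups()
    if suffix is None:
        return float(number)
    factor = _FACTORS.get(suffix.lower())
    if factor is None:
        raise ValueError(f"unknown unit {suffix!r} in {value!r}{where}")
    return float(number) * factor


def si_quantity(value: float, unit: str) -> dict:
    """A JSON-friendly quantity record with an explicit unit tag."""
    return {"value": float(value), "unit": unit}
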