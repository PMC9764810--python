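"""Conduit geometry, fluid properties and closed-form laminar-flow formulas.

All formulas assume fully developed, incompressible, Newtonian laminar
flow (Hagen–Poiseuille regime), which holds throughout the operating range
of a perfused vessel-on-chip (Re ≲ 10, entrance lengths ≪ channel length).

Key closed forms
----------------
Circular conduit of diameter ``d`` and length ``L``::

    R = 128 μ L / (π d⁴)                 hydraulic resistance, Pa·s/m³
    τ = 32 μ Q / (π d³)                  wall shear stress at flow Q, Pa
    τ = 4 μ v_max / d                    WSS from centerline velocity

Rectangular duct of width ``w`` ≥ height ``h``: the exact Fourier-series
solution of the Poisson problem for the axial velocity, giving

    R = 12 μ L / (w h³ · [1 − (h/w) Σₙ odd (192 / (π⁵ n⁵)) tanh(n π w / 2h)])

which reduces to the parallel-plate limit 12 μ L/(w h³) for w ≫ h and to
R h⁴/(μL) ≈ 28.45 for a square duct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FluidProperties",
    "CULTURE_MEDIUM",
    "CircularChannel",
    "RectangularChannel",
    "FlowState",
    "resistance_circular",
    "resistance_rectangular",
    "rectangular_shape_factor",
    "wss_circular",
    "wss_from_centerline_velocity",
    "flow_from_centerline_velocity",
    "series_resistance",
    "parallel_resistance",
]

GRAVITY = 9.81  # m/s²


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: dynamic viscosity [Pa·s] and density [kg/m³].

    Density only matters for the hydrostatic head of reservoir liquid
    columns; viscosity enters every resistance and shear formula.
    """

    viscosity: float
    density: float = 993.0  # aqueous medium at 37 °C

    def __post_init__(self) -> None:
        _require_positive(viscosity=self.viscosity, density=self.density)


#: Cell culture medium with 2% serum at 37 °C.
CULTURE_MEDIUM = FluidProperties(viscosity=0.79e-3, density=993.0)


@dataclass(frozen=True)
class CircularChannel:
    """Circular conduit (a vessel lumen or round tubing): diameter, length [m]."""

    diameter: float
    length: float

    def __post_init__(self) -> None:
        _require_positive(diameter=self.diameter, length=self.length)


@dataclass(frozen=True)
class RectangularChannel:
    """Rectangular duct (a milled channel): width, height, length [m].

    Width and height are interchangeable physically; the convention
    width ≥ height is enforced on construction.
    """

    width: float
    height: float
    length: float

    def __post_init__(self) -> None:
        _require_positive(width=self.width, height=self.height, length=self.length)
        if self.width < self.height:
            w, h = self.width, self.height
            object.__setattr__(self, "width", h)
            object.__setattr__(self, "height", w)


@dataclass(frozen=True)
class FlowState:
    """Flow rate [m³/s] and the pressure drop [Pa] it causes over one element."""

    flow_rate: float
    pressure_drop: float


def resistance_circular(geom: CircularChannel, fluid: FluidProperties) -> float:
    """Hagen–Poiseuille resistance of a circular conduit, Pa·s/m³."""
    return 128.0 * fluid.viscosity * geom.length / (math.pi * geom.diameter**4)


def rectangular_shape_factor(width: float, height: float, rel_tol: float = 1e-10) -> float:
    """Bracketed series factor in the rectangular-duct resistance.

    Evaluates ``1 − (h/w) Σ (192/(π⁵ n⁵)) tanh(n π w / 2h)`` over odd n,
    truncated when a term changes the sum by less than ``rel_tol``
    relative.  Requires width ≥ height (enforced by RectangularChannel).
    """
    w, h = (width, height) if width >= height else (height, width)
    aspect = h / w
    coeff = 192.0 / math.pi**5
    total = 0.0
    n = 1
    while True:
        # tanh saturates to 1 quickly; guard huge arguments
        arg = n * math.pi * w / (2.0 * h)
        term = coeff / n**5 * math.tanh(arg) if arg < 20 else coeff / n**5
        total += term
        if term < rel_tol * total:
            break
        n += 2
    return 1.0 - aspect * total


def resistance_rectangular(geom: RectangularChannel, fluid: FluidProperties) -> float:
    """Exact series resistance of a rectangular duct, Pa·s/m³."""
    factor = rectangular_shape_factor(geom.width, geom.height)
    return 12.0 * fluid.viscosity * geom.length / (geom.width * geom.height**3 * factor)


def wss_circular(flow_rate: float, diameter: float, fluid: FluidProperties) -> float:
    """Wall shear stress τ = 32 μ Q / (π d³) in a circular conduit, Pa."""
    _require_positive(diameter=diameter)
    return 32.0 * fluid.viscosity * flow_rate / (math.pi * diameter**3)


def wss_from_centerline_velocity(v_max: float, diameter: float, fluid: FluidProperties) -> float:
    """WSS from the parabolic-profile centerline velocity: τ = 4 μ v_max / d."""
    _require_positive(diameter=diameter)
    return 4.0 * fluid.viscosity * v_max / diameter


def flow_from_centerline_velocity(v_max: float, diameter: float) -> float:
    """Volumetric flow implied by a Poiseuille profile: Q = (v_max/2)·π d²/4."""
    _require_positive(diameter=diameter)
    return 0.5 * v_max * math.pi * diameter**2 / 4.0


def series_resistance(*resistances: float) -> float:
    return float(sum(resistances))


def parallel_resistance(*resistances: float) -> float:
    for r in resistances:
        _require_positive(resistance=r)
    return 1.0 / sum(1.0 / r for r in resistances)
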