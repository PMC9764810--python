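"""Shear-equalizing (τEQ) resistor design for multiplexed vessel perfusion.

The problem: vessels-on-chip patterned in soft hydrogel have lumen
diameters that vary sample-to-sample (here 180–300 µm by default).  Under
a shared drive, wall shear stress τ depends strongly on diameter:

* fixed flow rate per sample:      τ ∝ d⁻³   (≈ 4.6× spread over the range)
* fixed ΔP, negligible branch R:   τ ∝ d     (≈ 1.7× spread)

Placing an extra resistance R_EQ in series with each lumen and driving
all branches with one fixed ΔP gives

    τ(d) = 32 μ ΔP / (128 μ L_v / d + π R_EQ d³)

which has an interior maximum at d* = (128 μ L_v / (3 π R_EQ))^¼ and is
equal at both ends of the diameter range when

    R_EQ = 128 μ L_v (d_max − d_min) / (π d_min d_max (d_max³ − d_min³))

With this choice the spread over the whole range collapses to < 10%.
This module computes that optimum, the three regime curves, the drive
pressure needed for a target WSS, a physical realization of R_EQ as
tubing or a milled channel, and the feasible luminal-pressure envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hydraulics import (
    GRAVITY,
    CircularChannel,
    FluidProperties,
    RectangularChannel,
    resistance_circular,
    resistance_rectangular,
)

__all__ = [
    "DiameterRange",
    "WSSProfile",
    "VariationSummary",
    "TauEQDesign",
    "OperatingEnvelope",
    "EnvelopeEmptyError",
    "optimal_equalizing_resistance",
    "tau_eq_wss",
    "peak_diameter",
    "wss_profile",
    "wss_variation",
    "required_pressure",
    "resistor_realization",
    "tau_eq_design",
    "operating_envelope",
]

REGIMES = ("fixed_flow", "fixed_dp", "tau_eq")


@dataclass(frozen=True)
class DiameterRange:
    """Expected lumen-diameter range [m] the board is optimized for."""

    d_min: float
    d_max: float

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValueError(
                f"require 0 < d_min < d_max, got ({self.d_min!r}, {self.d_max!r})"
            )

    def grid(self, step: float = 1e-6) -> np.ndarray:
        """Uniform diameter grid including both endpoints (default 1 µm step)."""
        n = max(int(round((self.d_max - self.d_min) / step)), 1)
        return np.linspace(self.d_min, self.d_max, n + 1)


@dataclass
class WSSProfile:
    """WSS versus diameter under one drive regime."""

    regime: str
    diameters: np.ndarray  # m
    wss: np.ndarray  # Pa
    drive: float  # m³/s for fixed_flow, Pa otherwise

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"diameter_um": self.diameters * 1e6, "wss_pa": self.wss, "regime": self.regime}
        )


@dataclass(frozen=True)
class VariationSummary:
    """Spread metrics over a WSS profile: max/min ratio, (max−min)/max, CV = sd/mean."""

    ratio_max_min: float
    rel_difference: float
    cv: float


@dataclass
class TauEQDesign:
    """An equalizing-resistor design and its physical realization."""

    diameter_range: DiameterRange
    lumen_length: float
    fluid: FluidProperties
    equalizing_resistance: float  # Pa·s/m³
    realization: CircularChannel | RectangularChannel | None
    target_wss: float
    dp_for_target_wss: float  # Pa, at the mid-range diameter
    profile: WSSProfile
    variation: VariationSummary

    def to_dict(self) -> dict:
        real: dict | None = None
        if isinstance(self.realization, CircularChannel):
            real = {
                "kind": "tubing",
                "inner_diameter": {"value": self.realization.diameter, "unit": "m"},
                "length": {"value": self.realization.length, "unit": "m"},
            }
        elif isinstance(self.realization, RectangularChannel):
            real = {
                "kind": "channel",
                "width": {"value": self.realization.width, "unit": "m"},
                "height": {"value": self.realization.height, "unit": "m"},
                "length": {"value": self.realization.length, "unit": "m"},
            }
        return {
            "diameter_range": {
                "min": {"value": self.diameter_range.d_min, "unit": "m"},
                "max": {"value": self.diameter_range.d_max, "unit": "m"},
            },
            "lumen_length": {"value": self.lumen_length, "unit": "m"},
            "viscosity": {"value": self.fluid.viscosity, "unit": "Pa.s"},
            "equalizing_resistance": {
                "value": self.equalizing_resistance,
                "unit": "Pa.s/m3",
            },
            "realization": real,
            "target_wss": {"value": self.target_wss, "unit": "Pa"},
            "dp_for_target_wss": {"value": self.dp_for_target_wss, "unit": "Pa"},
            "wss_ratio_max_min": self.variation.ratio_max_min,
            "rel_difference": self.variation.rel_difference,
            "cv": self.variation.cv,
        }


def optimal_equalizing_resistance(
    diameter_range: DiameterRange, lumen_length: float, fluid: FluidProperties
) -> float:
    """Branch resistance that equalizes endpoint WSS at fixed ΔP, Pa·s/m³.

    The unique R_EQ with τ(d_min) = τ(d_max); WSS varies by < 10% in
    between for moderate ranges.  Degenerate (zero-width) ranges are
    rejected by :class:`DiameterRange`.
    """
    d1, d2 = diameter_range.d_min, diameter_range.d_max
    return (
        128.0 * fluid.viscosity * lumen_length * (d2 - d1)
        / (math.pi * d1 * d2 * (d2**3 - d1**3))
    )


def tau_eq_wss(d, dp: float, lumen_length: float, fluid: FluidProperties, r_eq: float):
    """τ(d) = 32 μ ΔP / (128 μ L_v / d + π R_EQ d³) for the equalized branch."""
    d = np.asarray(d, dtype=float)
    mu = fluid.viscosity
    return 32.0 * mu * dp / (128.0 * mu * lumen_length / d + math.pi * r_eq * d**3)


def peak_diameter(lumen_length: float, fluid: FluidProperties, r_eq: float) -> float:
    """Interior maximum of the equalized profile: d* = (128 μ L_v / (3 π R_EQ))^¼."""
    return (128.0 * fluid.viscosity * lumen_length / (3.0 * math.pi * r_eq)) ** 0.25


def wss_profile(
    regime: str,
    diameter_range: DiameterRange,
    lumen_length: float,
    fluid: FluidProperties,
    drive: float,
    grid_step: float = 1e-6,
    r_eq: float | None = None,
) -> WSSProfile:
    """WSS–diameter curve under one of the three drive regimes.

    regime = "fixed_flow": every sample receives flow ``drive`` [m³/s];
    τ ∝ d⁻³.  regime = "fixed_dp": drive [Pa] applied over the lumen
    alone (negligible branch resistance); τ = ΔP·d/(4 L_v), linear in d.
    regime = "tau_eq": drive [Pa] applied over lumen + equalizing
    resistor (``r_eq`` computed from the range if not given).
    """
    d = diameter_range.grid(grid_step)
    mu = fluid.viscosity
    if regime == "fixed_flow":
        wss = 32.0 * mu * drive / (math.pi * d**3)
    elif regime == "fixed_dp":
        wss = drive * d / (4.0 * lumen_length)
    elif regime == "tau_eq":
        if r_eq is None:
            r_eq = optimal_equalizing_resistance(diameter_range, lumen_length, fluid)
        wss = tau_eq_wss(d, drive, lumen_length, fluid, r_eq)
    else:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    return WSSProfile(regime, d, np.asarray(wss, dtype=float), drive)


def wss_variation(profile: WSSProfile) -> VariationSummary:
    """Spread metrics over the profile's uniform diameter grid."""
    w = profile.wss
    if w.size == 0:
        raise ValueError("empty profile")
    wmax, wmin = float(w.max()), float(w.min())
    return VariationSummary(
        ratio_max_min=wmax / wmin,
        rel_difference=(wmax - wmin) / wmax,
        cv=float(w.std() / w.mean()),
    )


def required_pressure(
    target_wss: float,
    lumen: CircularChannel,
    resistor: CircularChannel | RectangularChannel | None,
    fluid: FluidProperties,
) -> float:
    """Drive ΔP [Pa] producing ``target_wss`` in a lumen behind a resistor.

    ΔP = τ · (π d³ / 32 μ) · (R_lumen + R_resistor); the flow factor
    π d³ τ / (32 μ) is the Q that gives τ in the lumen.  With no
    resistor this reduces to the force balance ΔP = 4 τ L_v / d.
    """
    if target_wss <= 0:
        raise ValueError("target WSS must be positive")
    r_total = resistance_circular(lumen, fluid)
    if resistor is not None:
        if isinstance(resistor, RectangularChannel):
            r_total += resistance_rectangular(resistor, fluid)
        else:
            r_total += resistance_circular(resistor, fluid)
    q = target_wss * math.pi * lumen.diameter**3 / (32.0 * fluid.viscosity)
    return q * r_total


def resistor_realization(
    r_target: float,
    kind: str,
    fluid: FluidProperties,
    diameter: float | None = None,
    width: float | None = None,
    height: float | None = None,
) -> CircularChannel | RectangularChannel:
    """Physical conduit of the given cross-section realizing ``r_target``.

    kind = "tubing": solve 128 μ L / (π D⁴) = R for L (note viscosity
    cancels when realizing a resistance that itself scales with μ).
    kind = "channel": solve the rectangular-duct resistance for L.
    """
    if r_target <= 0:
        raise ValueError("target resistance must be positive")
    if kind == "tubing":
        if diameter is None:
            raise ValueError("tubing realization requires a diameter")
        length = r_target * math.pi * diameter**4 / (128.0 * fluid.viscosity)
        return CircularChannel(diameter=diameter, length=length)
    if kind == "channel":
        if width is None or height is None:
            raise ValueError("channel realization requires width and height")
        unit = resistance_rectangular(
            RectangularChannel(width=width, height=height, length=1.0), fluid
        )
        return RectangularChannel(width=width, height=height, length=r_target / unit)
    raise ValueError(f"unknown realization kind {kind!r}")


def tau_eq_design(
    diameter_range: DiameterRange,
    lumen_length: float,
    fluid: FluidProperties,
    target_wss: float = 1.0,
    realize: str | None = "tubing",
    tubing_diameter: float = 800e-6,
    channel_width: float | None = None,
    channel_height: float | None = None,
    grid_step: float = 1e-6,
) -> TauEQDesign:
    """Complete equalizing design: optimum R_EQ, realization, drive, profile."""
    r_eq = optimal_equalizing_resistance(diameter_range, lumen_length, fluid)
    realization = None
    if realize == "tubing":
        realization = resistor_realization(r_eq, "tubing", fluid, diameter=tubing_diameter)
    elif realize == "channel":
        realization = resistor_realization(
            r_eq, "channel", fluid, width=channel_width, height=channel_height
        )
    elif realize is not None:
        raise ValueError(f"unknown realization kind {realize!r}")
    d_mid = 0.5 * (diameter_range.d_min + diameter_range.d_max)
    lumen_mid = CircularChannel(diameter=d_mid, length=lumen_length)
    q_mid = target_wss * math.pi * d_mid**3 / (32.0 * fluid.viscosity)
    dp = q_mid * (resistance_circular(lumen_mid, fluid) + r_eq)
    profile = wss_profile("tau_eq", diameter_range, lumen_length, fluid, dp,
                          grid_step=grid_step, r_eq=r_eq)
    return TauEQDesign(
        diameter_range=diameter_range,
        lumen_length=lumen_length,
        fluid=fluid,
        equalizing_resistance=r_eq,
        realization=realization,
        target_wss=target_wss,
        dp_for_target_wss=dp,
        profile=profile,
        variation=wss_variation(profile),
    )


class EnvelopeEmptyError(ValueError):
    """The requested WSS cannot be reached anywhere in the pressure range."""


@dataclass(frozen=True)
class OperatingEnvelope:
    """Feasible luminal back-pressure window [Pa] at a given target WSS."""

    p_lumen_min: float
    p_lumen_max: float
    head_correction: float


def operating_envelope(
    target_wss: float,
    diameter_range: DiameterRange,
    lumen_length: float,
    fluid: FluidProperties,
    n_samples: int = 12,
    upstream_resistance: float = 0.0,
    downstream_resistance: float = 0.0,
    cracking_pressure: float = 0.0,
    full_scale: float = 34_500.0,
    liquid_height: float = 0.0,
    max_head: float | None = None,
) -> OperatingEnvelope:
    """Luminal-pressure window achievable from controllers of given full scale.

    The lower bound is what the downstream path (tubing, check valve,
    reservoir head) consumes at the total flow implied by the target WSS;
    the upper bound is the controller full scale minus the upstream
    consumption and the drive ΔP itself.  The window shrinks as the
    target WSS grows.
    """
    if target_wss <= 0:
        raise ValueError("target WSS must be positive")
    r_eq = optimal_equalizing_resistance(diameter_range, lumen_length, fluid)
    d_mid = 0.5 * (diameter_range.d_min + diameter_range.d_max)
    lumen = CircularChannel(diameter=d_mid, length=lumen_length)
    q_sample = target_wss * math.pi * d_mid**3 / (32.0 * fluid.viscosity)
    q_total = n_samples * q_sample
    dp_drive = q_sample * (resistance_circular(lumen, fluid) + r_eq)
    head = fluid.density * GRAVITY * liquid_height
    if max_head is not None:
        head = min(head, max_head)
    p_min = q_total * downstream_resistance + cracking_pressure + head
    p_max = full_scale - q_total * upstream_resistance - cracking_pressure - dp_drive
    if p_min > p_max:
        raise EnvelopeEmptyError(
            f"target WSS {target_wss} Pa infeasible: min {p_min:.0f} Pa > max {p_max:.0f} Pa"
        )
    return OperatingEnvelope(p_lumen_min=p_min, p_lumen_max=p_max, head_correction=head)
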