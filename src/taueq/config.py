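"""Board configuration: YAML round-trip with explicit units.

A :class:`BoardConfig` collects everything needed to build and simulate
a perfusion board: fluid properties, the lumen geometry and expected
diameter range, loop-segment dimensions, the equalizing-resistor
realization, valve and reservoir parameters, PID settings and the
random seed.  Quantities in the YAML carry unit suffixes (``"180 um"``,
``"1 mbar"``); everything is converted to SI on load, and dumped back
in SI, so load → dump → load is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .circuit import BoardLayout, build_board
from .design import DiameterRange, optimal_equalizing_resistance
from .hydraulics import (
    CircularChannel,
    FluidProperties,
    RectangularChannel,
    resistance_circular,
    resistance_rectangular,
)
from .units import parse_quantity

__all__ = ["BoardConfig", "ConfigError", "load_config", "dump_config", "default_config"]


class ConfigError(ValueError):
    """Invalid configuration; message names the offending key."""


@dataclass
class BoardConfig:
    # fluid
    viscosity: float = 0.79e-3  # Pa·s
    density: float = 993.0  # kg/m³
    # lumens
    lumen_length: float = 1.1e-2  # m
    d_min: float = 180e-6  # m
    d_max: float = 300e-6  # m
    sample_diameters: list[float] = field(default_factory=list)  # m; empty → spread
    n_samples: int = 4
    # loop segments (milled feeder/waste, one segment per tap)
    segment_width: float = 2e-3  # m
    segment_height: float = 1e-3  # m
    segment_length: float = 2e-2  # m
    # equalizing-resistor realization
    resistor_kind: str = "tubing"  # tubing | channel
    tubing_diameter: float = 800e-6  # m
    channel_width: float = 1e-3  # m
    channel_height: float = 0.2e-3  # m
    # valves & off-board tubing
    cracking_pressure: float = 1200.0  # Pa (12 mbar)
    valve_open_resistance: float = 1e9  # Pa·s/m³
    supply_resistance: float = 0.0  # Pa·s/m³
    # reservoirs
    reservoir_capacity: float = 15e-6  # m³
    reservoir_volume: float = 13e-6  # m³
    reservoir_area: float = 1.76e-4  # m²
    switch_threshold: float = 0.10
    # control
    kp: float = 0.6
    ki: float = 0.02
    kd: float = 0.0
    setpoint_dp: float = 100.0  # Pa (1 mbar)
    p_fcb: float = 5000.0  # Pa (50 mbar)
    full_scale: float = 34_500.0  # Pa (345 mbar)
    # misc
    target_wss: float = 1.0  # Pa
    seed: int = 0

    # -- derived quantities ---------------------------------------------------
    def fluid(self) -> FluidProperties:
        return FluidProperties(viscosity=self.viscosity, density=self.density)

    def diameter_range(self) -> DiameterRange:
        return DiameterRange(self.d_min, self.d_max)

    def diameters(self) -> list[float]:
        if self.sample_diameters:
            return list(self.sample_diameters)
        if self.n_samples == 1:
            return [0.5 * (self.d_min + self.d_max)]
        step = (self.d_max - self.d_min) / (self.n_samples - 1)
        return [self.d_min + i * step for i in range(self.n_samples)]

    def equalizing_resistance(self) -> float:
        return optimal_equalizing_resistance(
            self.diameter_range(), self.lumen_length, self.fluid()
        )

    def segment_resistance(self) -> float:
        seg = RectangularChannel(self.segment_width, self.segment_height, self.segment_length)
        return resistance_rectangular(seg, self.fluid())

    def board(self, with_valves: bool = True) -> BoardLayout:
        fluid = self.fluid()
        r_eq = self.equalizing_resistance()
        branches = [
            r_eq + resistance_circular(CircularChannel(d, self.lumen_length), fluid)
            for d in self.diameters()
        ]
        seg = self.segment_resistance()
        return build_board(
            branches,
            feeder_segment_resistance=seg,
            waste_segment_resistance=seg,
            supply_resistance=self.supply_resistance,
            with_valves=with_valves,
            cracking_pressure=self.cracking_pressure,
            valve_open_resistance=self.valve_open_resistance,
        )


# unit annotation per key for dumps; keys absent here are plain numbers
_UNITS = {
    "viscosity": "Pa.s",
    "density": "kg/m3",
    "lumen_length": "m",
    "d_min": "m",
    "d_max": "m",
    "segment_width": "m",
    "segment_height": "m",
    "segment_length": "m",
    "tubing_diameter": "m",
    "channel_width": "m",
    "channel_height": "m",
    "cracking_pressure": "Pa",
    "valve_open_resistance": "Pa.s/m3",
    "supply_resistance": "Pa.s/m3",
    "reservoir_capacity": "m3",
    "reservoir_volume": "m3",
    "reservoir_area": "m2",
    "setpoint_dp": "Pa",
    "p_fcb": "Pa",
    "full_scale": "Pa",
    "target_wss": "Pa",
}

_QUANTITY_KEYS = set(_UNITS)


def _coerce(key: str, raw) -> object:
    try:
        if key in _QUANTITY_KEYS:
            return parse_quantity(raw, unit_hint=key)
        if key == "sample_diameters":
            return [parse_quantity(v, unit_hint=key) for v in raw]
        return raw
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"config key {key!r}: {exc}") from exc


def load_config(path: str | Path) -> BoardConfig:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = set(BoardConfig.__dataclass_fields__)
    cfg = BoardConfig()
    for key, raw in data.items():
        if key not in known:
            raise ConfigError(f"{path}: unknown config key {key!r}")
        setattr(cfg, key, _coerce(key, raw))
    _validate(cfg, path)
    return cfg


def _validate(cfg: BoardConfig, path) -> None:
    checks = {
        "viscosity": cfg.viscosity > 0,
        "density": cfg.density > 0,
        "lumen_length": cfg.lumen_length > 0,
        "d_min/d_max": 0 < cfg.d_min < cfg.d_max,
        "n_samples": cfg.n_samples >= 1,
        "switch_threshold": 0 < cfg.switch_threshold < 1,
        "resistor_kind": cfg.resistor_kind in ("tubing", "channel"),
        "reservoir_volume": 0 < cfg.reservoir_volume <= cfg.reservoir_capacity,
    }
    for key, ok in checks.items():
        if not ok:
            raise ConfigError(f"{path}: invalid value for {key}")


def dump_config(cfg: BoardConfig, path: str | Path) -> None:
    data = {}
    for key, value in asdict(cfg).items():
        if key in _UNITS:
            data[key] = f"{value!r} {_UNITS[key]}"
        else:
            data[key] = value
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_config() -> BoardConfig:
    return BoardConfig()
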