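"""YAML run-configuration parsing.

A run configuration is a small key/value file, e.g.::

    dish:
      outer_nominal: 150     # or outer_mm: 134
      inner_nominal: 60      # or inner_mm: 56 / omit for a plain dish
    fill:
      height_mm: 3           # or volume_ml: 35
    shaker:
      orbit_mm: 10
      rpm: 200
    fluid:
      preset: EGM2_37C       # or density/viscosity_mPas/surface_tension
    seeding:
      density_per_cm2: 25000
    sim:
      n_r: 32
      n_theta: 64
      closure: stokes_layer
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .analytic import AIR_37C, EGM2_37C, FluidProperties, ShakerConfig
from .geometry import DishGeometry, FillSpec, from_catalog
from .solver import SimulationSettings

__all__ = ["RunConfig", "load_config", "parse_config"]

_FLUID_PRESETS = {"EGM2_37C": EGM2_37C, "AIR_37C": AIR_37C}


@dataclass
class RunConfig:
    geom: DishGeometry
    fill: FillSpec
    shaker: ShakerConfig | None
    fluid: FluidProperties
    settings: SimulationSettings
    seeding_density_per_cm2: float


def _parse_dish(d: dict) -> DishGeometry:
    if "outer_mm" in d:
        return DishGeometry.from_mm(
            d["outer_mm"], d.get("inner_mm", 0.0), d.get("label", "")
        )
    if "outer_nominal" in d:
        return from_catalog(d["outer_nominal"], d.get("inner_nominal"))
    raise ValueError("dish section needs outer_mm or outer_nominal")


def _parse_fluid(d: dict) -> FluidProperties:
    if "preset" in d:
        try:
            return _FLUID_PRESETS[d["preset"]]
        except KeyError:
            raise ValueError(
                f"unknown fluid preset {d['preset']!r}; have {sorted(_FLUID_PRESETS)}"
            ) from None
    return FluidProperties(
        density=d.get("density", 1000.0),
        dynamic_viscosity=d.get("viscosity_mPas", 0.7) * 1e-3,
        surface_tension=d.get("surface_tension", 0.072),
    )


def parse_config(raw: dict) -> RunConfig:
    geom = _parse_dish(raw.get("dish", {}))
    fill_d = raw.get("fill", {"height_mm": 3.0})
    fill = FillSpec(
        height_mm=fill_d.get("height_mm"), volume_ml=fill_d.get("volume_ml")
    )
    shaker = None
    if "shaker" in raw:
        shaker = ShakerConfig.from_rpm(raw["shaker"]["orbit_mm"], raw["shaker"]["rpm"])
    fluid = _parse_fluid(raw.get("fluid", {"preset": "EGM2_37C"}))
    settings = SimulationSettings(**raw.get("sim", {}))
    seeding = raw.get("seeding", {}).get("density_per_cm2", 25_000.0)
    return RunConfig(
        geom=geom,
        fill=fill,
        shaker=shaker,
        fluid=fluid,
        settings=settings,
        seeding_density_per_cm2=seeding,
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)
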