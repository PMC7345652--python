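"""Shared fixtures: fluid/shaker presets and a cache of surrogate runs."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from diadflow import (
    EGM2_37C,
    DishGeometry,
    FillSpec,
    ShakerConfig,
    SimulationSettings,
    simulate,
)

hyp_settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("suite")


@pytest.fixture(scope="session")
def fluid():
    return EGM2_37C


@pytest.fixture(scope="session")
def shaker_10mm_200rpm():
    return ShakerConfig.from_rpm(10, 200)


DESIGNS = {
    "35": DishGeometry.from_mm(35),
    "134": DishGeometry.from_mm(134),
    "89/56": DishGeometry.from_mm(89, 56),
    "134/89": DishGeometry.from_mm(134, 89),
    "134/56": DishGeometry.from_mm(134, 56),
}


@pytest.fixture(scope="session")
def run_cache():
    """Memoized surrogate runs keyed by (design, orbit_mm, rpm, height_mm,
    n_r, n_theta) so trend and profile tests share simulations."""
    cache = {}

    def get(design: str, orbit_mm: float, rpm: float, height_mm: float,
            n_r: int = 32, n_theta: int = 64):
        key = (design, orbit_mm, rpm, height_mm, n_r, n_theta)
        if key not in cache:
            cache[key] = simulate(
                DESIGNS[design],
                ShakerConfig.from_rpm(orbit_mm, rpm),
                EGM2_37C,
                FillSpec(height_mm=height_mm),
                SimulationSettings(n_r=n_r, n_theta=n_theta),
            )
        return cache[key]

    return get
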