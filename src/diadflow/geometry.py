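"""Dish geometry, fill-volume conversion and cell-yield planning.

Standard culture dishes are sold under nominal sizes (35, 60, 100, 150 mm)
whose actual culture-surface diameters are smaller (35, 56, 89 and 134 mm).
An annular "dish-in-a-dish" (DiaD) is built by mounting a catalog dish of
inner diameter ``d`` inside a strictly larger one of outer diameter ``D``,
leaving a donut-shaped culture channel.

Geometry is stored in SI units (metres); the planning functions below speak
the practical units a cell-culture protocol uses — mm for heights, cm² for
areas, mL for medium volumes — because those are the numbers one writes on
the dish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

__all__ = [
    "DishGeometry",
    "FillSpec",
    "CatalogError",
    "DISH_CATALOG_MM",
    "dish_catalog",
    "from_catalog",
    "annulus_area",
    "fill_volume",
    "height_from_volume",
    "cell_yield",
    "report_area_cm2",
    "report_volume_ml",
    "report_cells_millions",
]


class CatalogError(KeyError):
    """Requested nominal dish size is not in the catalog."""


#: Nominal (product-name) size -> actual culture-surface diameter, in mm.
DISH_CATALOG_MM: dict[int, float] = {35: 35.0, 60: 56.0, 100: 89.0, 150: 134.0}


@dataclass(frozen=True)
class DishGeometry:
    """A plain (``inner_diameter == 0``) or annular dish.

    Parameters
    ----------
    outer_diameter : float
        Actual outer culture diameter ``D`` in metres.
    inner_diameter : float, optional
        Actual inner-dish diameter ``d`` in metres; 0 for a plain dish.
    label : str, optional
        Free-text name; defaults to ``"D/d"`` in mm (``"D"`` for plain).
    """

    outer_diameter: float
    inner_diameter: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.outer_diameter > 0:
            raise ValueError(f"outer diameter must be positive, got {self.outer_diameter}")
        if not 0 <= self.inner_diameter < self.outer_diameter:
            raise ValueError(
                f"inner diameter must satisfy 0 <= d < D, got d={self.inner_diameter}, "
                f"D={self.outer_diameter}"
            )
        if not self.label:
            D_mm = self.outer_diameter * 1e3
            d_mm = self.inner_diameter * 1e3
            auto = f"{D_mm:g}/{d_mm:g}" if d_mm else f"{D_mm:g}"
            object.__setattr__(self, "label", auto)

    @classmethod
    def from_mm(cls, outer_mm: float, inner_mm: float = 0.0, label: str = "") -> "DishGeometry":
        return cls(outer_mm * 1e-3, inner_mm * 1e-3, label)

    @property
    def outer_radius(self) -> float:
        """Outer radius in metres."""
        return self.outer_diameter / 2

    @property
    def inner_radius(self) -> float:
        """Inner radius in metres (0 for plain dishes)."""
        return self.inner_diameter / 2

    @property
    def is_annular(self) -> bool:
        return self.inner_diameter > 0

    @property
    def area_m2(self) -> float:
        """Culture area π/4·(D² − d²) in m²."""
        return math.pi / 4 * (self.outer_diameter**2 - self.inner_diameter**2)


@dataclass(frozen=True)
class FillSpec:
    """Medium fill specified by height (mm) or volume (mL), exactly one.

    The other quantity is derived from the dish geometry at use time.
    """

    height_mm: float | None = None
    volume_ml: float | None = None

    def __post_init__(self) -> None:
        given = (self.height_mm is not None) + (self.volume_ml is not None)
        if given != 1:
            raise ValueError("exactly one of height_mm or volume_ml must be given")
        if self.height_mm is not None and not self.height_mm > 0:
            raise ValueError(f"fill height must be positive, got {self.height_mm}")
        if self.volume_ml is not None and not self.volume_ml > 0:
            raise ValueError(f"fill volume must be positive, got {self.volume_ml}")

    def resolve_height_m(self, geom: DishGeometry) -> float:
        """Initial fluid depth in metres for ``geom``."""
        if self.height_mm is not None:
            return self.height_mm * 1e-3
        return height_from_volume(geom, self.volume_ml) * 1e-3

    def resolve_volume_ml(self, geom: DishGeometry) -> float:
        if self.volume_ml is not None:
            return self.volume_ml
        return fill_volume(geom, self.height_mm)


def dish_catalog() -> dict[int, DishGeometry]:
    """Map of nominal dish size (mm) to the actual plain-dish geometry."""
    return {nom: DishGeometry.from_mm(act) for nom, act in DISH_CATALOG_MM.items()}


def from_catalog(outer_nominal: int, inner_nominal: int | None = None) -> DishGeometry:
    """Build a plain or annular dish from catalog nominal sizes.

    An annular design pairs any catalog dish as the inner wall with a strictly
    larger catalog dish as the outer; e.g. ``from_catalog(150, 100)`` is the
    134/89 DiaD.

    Raises
    ------
    CatalogError
        If a nominal size is unknown.
    ValueError
        If the inner dish is not strictly smaller than the outer.
    """
    try:
        outer_mm = DISH_CATALOG_MM[outer_nominal]
    except KeyError:
        raise CatalogError(
            f"unknown nominal dish size {outer_nominal}; catalog has {sorted(DISH_CATALOG_MM)}"
        ) from None
    inner_mm = 0.0
    if inner_nominal is not None:
        try:
            inner_mm = DISH_CATALOG_MM[inner_nominal]
        except KeyError:
            raise CatalogError(
                f"unknown nominal dish size {inner_nominal}; catalog has {sorted(DISH_CATALOG_MM)}"
            ) from None
    return DishGeometry.from_mm(outer_mm, inner_mm)


def annulus_area(geom: DishGeometry) -> float:
    """Culture area of the dish in cm²: π/4·(D² − d²)."""
    return geom.area_m2 * 1e4


def fill_volume(geom: DishGeometry, height_mm: float) -> float:
    """Medium volume (mL) giving a uniform fluid height ``height_mm``."""
    if height_mm < 0:
        raise ValueError(f"fill height must be non-negative, got {height_mm}")
    # area [m²] × height [m] = m³; 1 m³ = 1e6 mL
    return geom.area_m2 * height_mm * 1e-3 * 1e6


def height_from_volume(geom: DishGeometry, volume_ml: float) -> float:
    """Fluid height (mm) obtained from ``volume_ml`` of medium.

    Inverse of :func:`fill_volume`; the roundtrip is exact to rounding.
    """
    if volume_ml < 0:
        raise ValueError(f"fill volume must be non-negative, got {volume_ml}")
    return volume_ml * 1e-6 / geom.area_m2 * 1e3


def cell_yield(geom: DishGeometry, density_per_cm2: float) -> float:
    """Cell count at confluence for a seeding density in cells/cm²."""
    if density_per_cm2 < 0:
        raise ValueError(f"seeding density must be non-negative, got {density_per_cm2}")
    return annulus_area(geom) * density_per_cm2


# --- reporting helpers (protocol-style rounding) -----------------------------

def report_area_cm2(geom: DishGeometry) -> int:
    """Culture area rounded to the nearest cm², protocol style."""
    return round(annulus_area(geom))


def report_volume_ml(geom: DishGeometry, height_mm: float) -> int:
    """Fill volume rounded to the nearest mL, protocol style."""
    return round(fill_volume(geom, height_mm))


def report_cells_millions(geom: DishGeometry, density_per_cm2: float) -> int:
    """Cell yield rounded to the nearest million."""
    return round(cell_yield(geom, density_per_cm2) / 1e6)
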