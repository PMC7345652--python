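"""Design-space sweep and ranking for orbital-shaker dish configurations.

A sweep runs the surrogate for every combination of dish design, orbit
diameter, rotational speed and fill height, summarizing each run into one
row of shear metrics (overall τ_max, its radial coefficient of variation,
max and mean OSI) and planning metrics (culture area, expected cell yield).
Rows whose run fails — typically dry-out at low fill on a large orbit, a
regime outside the surrogate's validity — are kept with a failure status
rather than dropped.

Ranking composes a weighted score from min–max-normalized criteria: high
τ_max, low OSI, low τ_max variation, large culture area. The weighting is
explicit because "best" depends on the experiment: maximal shear, shear
homogeneity and cell yield pull in different directions.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .analytic import EGM2_37C, FluidProperties, ShakerConfig
from .geometry import DishGeometry, FillSpec, annulus_area, cell_yield
from .shear import compute_profile
from .solver import SimulationSettings, SolverError, simulate

__all__ = [
    "SCORE_COLUMNS",
    "run_sweep",
    "rank_designs",
    "viscosity_scaling",
    "paper_design_grid",
]

SCORE_COLUMNS = [
    "label",
    "orbit_mm",
    "rpm",
    "height_mm",
    "tau_max_overall",
    "tau_max_cv",
    "osi_max",
    "osi_mean",
    "area_cm2",
    "est_cells",
    "status",
]

#: Ranking criteria: column, sign (+1 maximize, -1 minimize).
_CRITERIA = {
    "tau_max": ("tau_max_overall", +1),
    "osi": ("osi_max", -1),
    "tau_cv": ("tau_max_cv", -1),
    "area": ("area_cm2", +1),
}


def paper_design_grid() -> dict:
    """The characterization grid of the study: five dishes (two plain, three
    annular), three commercial orbit sizes, four speeds, three fill heights."""
    return {
        "designs": [
            DishGeometry.from_mm(35),
            DishGeometry.from_mm(134),
            DishGeometry.from_mm(89, 56),
            DishGeometry.from_mm(134, 89),
            DishGeometry.from_mm(134, 56),
        ],
        "orbits_mm": [10.0, 19.0, 25.0],
        "rpms": [100.0, 125.0, 150.0, 200.0],
        "heights_mm": [2.0, 3.0, 4.0],
    }


def run_sweep(
    designs: list[DishGeometry],
    orbits_mm: list[float],
    rpms: list[float],
    heights_mm: list[float],
    fluid: FluidProperties = EGM2_37C,
    settings: SimulationSettings | None = None,
    seeding_density_per_cm2: float = 25_000.0,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Run the surrogate over the Cartesian design grid.

    Returns one row per (design, orbit, rpm, height) combination with the
    :data:`SCORE_COLUMNS`; shear metrics are NaN on failed rows and ``status``
    records ``"ok"`` or the failure class (``"dry_out"``, ``"cfl_error"``,
    ...). Deterministic: repeated invocation gives an identical table.
    """
    for name, lst in (
        ("designs", designs),
        ("orbits_mm", orbits_mm),
        ("rpms", rpms),
        ("heights_mm", heights_mm),
    ):
        if not lst:
            raise ValueError(f"{name} must be non-empty")
    if settings is None:
        settings = SimulationSettings()
    rows = []
    for geom, orbit, rpm, height in itertools.product(designs, orbits_mm, rpms, heights_mm):
        row = {
            "label": geom.label,
            "orbit_mm": orbit,
            "rpm": rpm,
            "height_mm": height,
            "area_cm2": annulus_area(geom),
            "est_cells": cell_yield(geom, seeding_density_per_cm2),
            "tau_max_overall": np.nan,
            "tau_max_cv": np.nan,
            "osi_max": np.nan,
            "osi_mean": np.nan,
            "status": "ok",
        }
        shaker = ShakerConfig.from_rpm(orbit, rpm)
        try:
            series = simulate(geom, shaker, fluid, FillSpec(height_mm=height), settings)
            profile = compute_profile(series, n_bins)
            row["tau_max_overall"] = float(profile.tau_max.max())
            mean_tm = float(profile.tau_max.mean())
            row["tau_max_cv"] = float(profile.tau_max.std() / mean_tm) if mean_tm > 0 else 0.0
            row["osi_max"] = float(np.nanmax(profile.osi))
            row["osi_mean"] = float(np.nanmean(profile.osi))
        except SolverError as exc:
            row["status"] = _status_of(exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def _status_of(exc: SolverError) -> str:
    name = type(exc).__name__
    return {
        "DryOutError": "dry_out",
        "CFLError": "cfl_error",
        "ConfigurationError": "config_error",
        "SamplingError": "sampling_error",
    }.get(name, "solver_error")


def rank_designs(scores: pd.DataFrame, weights: dict[str, float]) -> pd.DataFrame:
    """Order sweep rows by a weighted composite of normalized criteria.

    ``weights`` maps criterion names {"tau_max", "osi", "tau_cv", "area"} to
    non-negative weights summing to 1. Each criterion column is min–max
    normalized over the successful rows (minimized criteria are inverted so
    that 1 is always best); a constant column carries no information and
    contributes 0, with a warning. Ties break by label; failed rows sink to
    the bottom with NaN composite. The ordering is invariant to positive
    rescaling of any criterion column.
    """
    unknown = set(weights) - set(_CRITERIA)
    if unknown:
        raise ValueError(f"unknown ranking criteria {sorted(unknown)}")
    total = sum(weights.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"weights must sum to 1, got {total}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    df = scores.copy()
    ok = df["status"] == "ok"
    composite = pd.Series(np.nan, index=df.index)
    composite[ok] = 0.0
    for name, w in weights.items():
        if w == 0:
            continue
        col, sign = _CRITERIA[name]
        vals = df.loc[ok, col].astype(float)
        lo, hi = vals.min(), vals.max()
        if not np.isfinite(hi - lo) or hi == lo:
            warnings.warn(
                f"criterion {name!r} is constant over the table and contributes 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        norm = (vals - lo) / (hi - lo)
        if sign < 0:
            norm = 1.0 - norm
        composite[ok] += w * norm
    df["composite"] = composite
    df = df.sort_values(
        by=["composite", "label"], ascending=[False, True], kind="stable", na_position="last"
    )
    return df.reset_index(drop=True)


def viscosity_scaling(tau: float | np.ndarray | pd.Series, factor: float) -> dict:
    """Bounds on how wall shear responds to a viscosity change by ``factor``.

    Thickening the medium (e.g. with xanthan gum or methyl cellulose, 4–5×)
    raises the shear stress, but by how much depends on the vertical-profile
    closure: the oscillatory-boundary-layer (analytic a√(ρμω³)) route scales
    as √factor, the lubrication route (3μu/h at fixed u) linearly. The two
    are reported together as a bracket rather than a single number.
    """
    if not factor > 0:
        raise ValueError(f"viscosity factor must be positive, got {factor}")
    return {
        "factor": factor,
        "stokes_sqrt": tau * np.sqrt(factor),
        "lubrication_linear": tau * factor,
    }
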