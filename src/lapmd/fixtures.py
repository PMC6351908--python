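"""Seeded synthetic "toy city" inputs for every pipeline stage.

A real application of the toolkit needs a land-use raster, a DEM, a year of
daily meteorology, inventory parameters and a planning layer, none of which
can be redistributed here.  This module generates a structurally equivalent
toy city — a compact urban core with a few high-stack industrial key plots, a
road cross, scattered rural settlements on an agricultural plain near sea
level, a monsoon-like wind regime with a prevailing sector — fully
deterministic under a fixed seed, at the 300 m cell size typical of
city-scale strategic assessments.

The toy city does not emulate any real geography; it exists so that the whole
chain (inventory -> rasterization -> dispersion -> classification -> overlay)
can be exercised and verified without external data.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box

from lapmd.grids import Grid
from lapmd.meteorology import DailyMetRecord, N_SECTORS, SECTOR_WIDTH_DEG

__all__ = [
    "ToyCitySpec",
    "CODE_MAP",
    "DEFAULT_HEIGHTS",
    "make_landuse",
    "make_met",
    "make_inventory_params",
    "make_planning",
    "met_records",
]

#: Integer land-use codes shared by generator, configs and the CLI.
CODE_MAP: dict[int, str] = {
    1: "agricultural",
    2: "urban_residential",
    3: "rural_residential",
    4: "transportation",
    5: "key_plot",
}

#: Source heights above ground, m: chimneys for key plots, half building
#: height for residential land, ground level for fields and roads.
DEFAULT_HEIGHTS: dict[str, float] = {
    "key_plot": 30.0,
    "urban_residential": 10.0,
    "rural_residential": 3.0,
    "agricultural": 0.0,
    "transportation": 0.5,
}


@dataclass(frozen=True)
class ToyCitySpec:
    """Parameters of the synthetic city; the seed fixes all randomness."""

    nrows: int = 40
    ncols: int = 40
    cellsize: float = 300.0
    seed: int = 0
    urban_fraction: float = 0.08
    rural_fraction: float = 0.06
    n_key_plots: int = 4
    prevailing_sector: int = 2  # east, a coastal sea breeze
    prevailing_fraction: float = 0.35
    speed_mean: float = 3.2
    speed_sd: float = 1.4
    latitude_deg: float = 34.6

    def __post_init__(self) -> None:
        if self.nrows < 10 or self.ncols < 10:
            raise ValueError("toy grid must be at least 10 x 10")
        if self.urban_fraction + self.rural_fraction > 1.0:
            raise ValueError("category fractions must sum to at most 1")
        if not 0 <= self.prevailing_sector < N_SECTORS:
            raise ValueError("prevailing_sector must index one of the 8 sectors")
        if not 0.0 <= self.prevailing_fraction <= 1.0:
            raise ValueError("prevailing_fraction must be a fraction")

    @property
    def grid(self) -> Grid:
        return Grid(nrows=self.nrows, ncols=self.ncols, cellsize=self.cellsize)


def make_landuse(spec: ToyCitySpec) -> tuple[Grid, np.ndarray, np.ndarray]:
    """Generate the categorical land-use raster and a gentle near-coastal DEM.

    Agricultural land fills the background; a contiguous urban core sits at
    the centre, crossed by a road network; rural settlements are scattered
    2 x 2 patches; key plots are single cells in and around the urban core.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    landuse = np.full(grid.shape, 1, dtype=int)  # agricultural background

    n_cells = grid.nrows * grid.ncols
    side = max(2, round(np.sqrt(spec.urban_fraction * n_cells)))
    r0 = grid.nrows // 2 - side // 2
    c0 = grid.ncols // 2 - side // 2
    landuse[r0 : r0 + side, c0 : c0 + side] = 2

    # scattered 2x2 rural patches outside the core
    n_patches = max(1, round(spec.rural_fraction * n_cells / 4))
    placed = 0
    attempts = 0
    while placed < n_patches and attempts < 50 * n_patches:
        attempts += 1
        r = int(rng.integers(0, grid.nrows - 1))
        c = int(rng.integers(0, grid.ncols - 1))
        block = landuse[r : r + 2, c : c + 2]
        if np.all(block == 1):
            block[:] = 3
            placed += 1

    # road cross through the city centre
    landuse[grid.nrows // 2, :] = 4
    landuse[:, grid.ncols // 2] = 4

    # key plots: single cells inside or adjacent to the urban core
    plots: list[tuple[int, int]] = []
    attempts = 0
    while len(plots) < spec.n_key_plots and attempts < 500:
        attempts += 1
        r = int(rng.integers(max(r0 - 2, 0), min(r0 + side + 2, grid.nrows)))
        c = int(rng.integers(max(c0 - 2, 0), min(c0 + side + 2, grid.ncols)))
        if (r, c) not in plots and landuse[r, c] != 4:
            landuse[r, c] = 5
            plots.append((r, c))
    if len(plots) < spec.n_key_plots:
        raise ValueError("could not place the requested number of key plots")

    # DEM: near-sea-level plain rising gently inland (westward) + smooth bumps
    cols = np.arange(grid.ncols)
    base = 3.0 + 40.0 * (1.0 - cols / max(grid.ncols - 1, 1))
    dem = np.tile(base, (grid.nrows, 1))
    bumps = rng.normal(0.0, 1.0, size=(grid.nrows // 5 + 2, grid.ncols // 5 + 2))
    bumps = np.kron(bumps, np.ones((5, 5)))[: grid.nrows, : grid.ncols]
    dem = np.clip(dem + 2.0 * bumps, 0.0, None)
    return grid, landuse, dem


def make_met(spec: ToyCitySpec, n_days: int = 365) -> pd.DataFrame:
    """Generate a year of daily meteorology with a prevailing wind sector.

    Directions come from the prevailing sector with probability
    ``prevailing_fraction`` and uniformly from the other sectors otherwise;
    speeds are truncated-normal (mean/sd from the spec, floored at 0), cloud
    cover is Beta(2, 2).
    """
    rng = np.random.default_rng(spec.seed + 1)
    start = datetime.date(2010, 1, 1)
    dates = [start + datetime.timedelta(days=i) for i in range(n_days)]

    prevailing = rng.random(n_days) < spec.prevailing_fraction
    others = [s for s in range(N_SECTORS) if s != spec.prevailing_sector]
    sectors = np.where(
        prevailing, spec.prevailing_sector, rng.choice(others, size=n_days)
    )
    centers = sectors * SECTOR_WIDTH_DEG
    jitter = rng.uniform(-SECTOR_WIDTH_DEG / 2, SECTOR_WIDTH_DEG / 2, size=n_days)
    directions = (centers + jitter) % 360.0

    speeds = np.clip(rng.normal(spec.speed_mean, spec.speed_sd, size=n_days), 0.0, None)
    cloud = rng.beta(2.0, 2.0, size=n_days)

    return pd.DataFrame(
        {
            "date": [d.isoformat() for d in dates],
            "wind_dir_deg": np.round(directions, 1),
            "wind_speed_ms": np.round(speeds, 2),
            "cloud_frac": np.round(cloud, 3),
        }
    )


def met_records(frame: pd.DataFrame) -> list[DailyMetRecord]:
    """Convert a meteorology table to typed daily records."""
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            DailyMetRecord(
                date=datetime.date.fromisoformat(str(row.date)),
                wind_direction=float(row.wind_dir_deg),
                wind_speed=float(row.wind_speed_ms),
                cloud_cover=float(row.cloud_frac),
                solar_elevation=float(row.solar_elev_deg)
                if hasattr(row, "solar_elev_deg")
                else None,
            )
        )
    return records


def make_inventory_params(spec: ToyCitySpec, scenario: str = "reference") -> dict:
    """Generate a JSON-able inventory parameter config for one scenario.

    Reference-scenario magnitudes are drawn once from ranges typical of a
    mid-size coal-burning city; the ``"target"`` scenario applies planning-
    style adjustments to the same draws: reduced industrial fuel, a near-ban
    on crop-residue burning, cleaner vehicle emission factors with a growing
    small-car fleet, urban growth and rural decline.
    """
    if scenario not in ("reference", "target"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(spec.seed + 2)
    t = scenario == "target"

    plots = []
    for i in range(spec.n_key_plots):
        coal = float(rng.uniform(2.0e5, 8.0e5))  # ton/yr per plant
        plots.append(
            {
                "name": f"plant_{i + 1}",
                "fuel_consumption_ton": coal * (0.7 if t else 1.0),
                "sulfur_content_rate": float(rng.uniform(0.006, 0.012)),
                "conversion_rate": 0.8,
                "desulfurization_rate": 0.6,
                "pm10_ef_kg_per_ton": 2.97,
            }
        )

    urban_coal = float(rng.uniform(1.5e5, 3.0e5))
    rural_residue = float(rng.uniform(5.0e5, 1.2e6))
    ag_residue = float(rng.uniform(1.0e6, 2.0e6))

    fleet_spec = [
        # type, count range, mileage, ef_so2 g/km, ef_pm10 g/km, target count factor
        ("large_vehicle", (3e3, 8e3), 5.0e4, 0.05, 0.02, 0.7),
        ("medium_vehicle", (4e3, 9e3), 4.0e4, 0.01, 0.02, 0.7),
        ("small_car", (1.5e5, 3.0e5), 1.5e4, 0.01, 0.02, 1.4),
        ("mini_vehicle", (8e3, 2e4), 1.2e4, 0.01, 0.02, 1.4),
        ("heavy_truck", (1.5e4, 3.0e4), 6.0e4, 0.10, 0.02, 0.7),
        ("medium_truck", (8e3, 2e4), 4.0e4, 0.05, 0.02, 0.7),
        ("light_truck", (2e4, 5e4), 2.5e4, 0.01, 0.02, 0.8),
        ("mini_truck", (1e3, 3e3), 1.5e4, 0.01, 0.02, 0.8),
        ("tricar", (1e4, 4e4), 2.0e4, 0.05, 0.02, 0.6),
    ]
    ef_scale = 0.6 if t else 1.0  # fuel-quality upgrade in the target year
    fleet = []
    for name, (lo, hi), mileage, ef_s, ef_p, tfac in fleet_spec:
        count = float(rng.uniform(lo, hi))
        fleet.append(
            {
                "vehicle_type": name,
                "count": count * (tfac if t else 1.0),
                "annual_mileage_km": mileage,
                "ef_so2_g_per_km": ef_s * ef_scale,
                "ef_pm10_g_per_km": ef_p * ef_scale,
            }
        )

    return {
        "scenario": scenario,
        "year": 2020 if t else 2010,
        "key_plots": plots,
        "urban_residential": {
            "fuel_consumption_ton": urban_coal * (1.25 if t else 1.0),
            "sulfur_content_rate": 0.008,
            "conversion_rate": 0.8,
            "desulfurization_rate": 0.0,  # no control equipment on household burning
            "pm10_ef_kg_per_ton": 0.15,
        },
        "rural_residential": {
            "activity_ton": rural_residue * (0.9 if t else 1.0),
            "ef_so2_kg_per_ton": 0.4,
            "ef_pm10_kg_per_ton": 3.74,
        },
        "agricultural": {
            "activity_ton": ag_residue * (0.1 if t else 1.0),  # straw-burning ban
            "ef_so2_kg_per_ton": 0.4,
            "ef_pm10_kg_per_ton": 10.0,
        },
        "fleet": fleet,
        "heights_m": dict(DEFAULT_HEIGHTS),
        "attenuation": {"SO2": 1.0, "PM10": 1.0},
    }


def make_planning(spec: ToyCitySpec) -> list[tuple[str, "box"]]:
    """Planning polygons: newly planned urban and rural land, map units (m).

    The new urban land is a belt east of the urban core (downwind of the
    prevailing westward transport); the new rural land is a block in the
    south-western countryside.
    """
    grid = spec.grid
    side = max(2, round(np.sqrt(spec.urban_fraction * grid.nrows * grid.ncols)))
    c_urban_e = (grid.ncols // 2 + side // 2) * grid.cellsize
    r_mid = grid.nrows // 2 * grid.cellsize
    urban = box(
        c_urban_e,
        grid.yllcorner + (grid.nrows * grid.cellsize) / 2 - 4 * grid.cellsize,
        c_urban_e + 5 * grid.cellsize,
        grid.yllcorner + (grid.nrows * grid.cellsize) / 2 + 4 * grid.cellsize,
    )
    rural = box(
        grid.xllcorner + 3 * grid.cellsize,
        grid.yllcorner + 3 * grid.cellsize,
        grid.xllcorner + 9 * grid.cellsize,
        grid.yllcorner + 9 * grid.cellsize,
    )
    return [("new_urban", urban), ("new_rural", rural)]
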