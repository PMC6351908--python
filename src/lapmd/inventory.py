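"""Land-use-based annual emission inventories of SO2 and PM10.

Emissions are estimated per land-use source category rather than per industry:
key industrial plots (point sources), transportation land (line sources), and
urban/rural residential plus agricultural land (area sources).  Two estimation
methods are used:

* **mass balance** for SO2 from fuel combustion — input sulfur is carried
  through combustion and control equipment:
  ``E = (64/32) * S * omega * eps * (1 - eta) * 1e3`` kg, with sulfur content
  rate ``S``, fuel consumption ``omega`` (ton/yr), sulfur conversion rate
  ``eps`` and desulfurization rate ``eta``;
* **emission factors** for everything else — emission = activity amount x
  average emission rate per unit activity (kg/ton for stationary fuel or crop
  residue, g/km per vehicle for road traffic).

The resulting inventory is rasterized to per-cell source intensities ``Q`` by
spreading each category's annual mass uniformly over the raster cells of that
land-use type (key plots may instead be placed cell-by-cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from lapmd.grids import Grid, require_congruent
from lapmd.units import KG_PER_TON, SO2_TO_S_MOLECULAR_RATIO

__all__ = [
    "MassBalanceInput",
    "VehicleClassRecord",
    "AreaActivityRecord",
    "InventoryEntry",
    "EmissionInventory",
    "SourceField",
    "CategoryParams",
    "mass_balance_so2",
    "vehicle_emissions",
    "area_source_emissions",
    "build_inventory",
    "rasterize_emissions",
]

POLLUTANTS = ("SO2", "PM10")

#: Area/point source categories that appear in a stationary inventory table.
STATIONARY_CATEGORIES = ("key_plot", "urban_residential", "rural_residential", "agricultural")


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


def _check_pollutant(pollutant: str) -> str:
    p = pollutant.upper().replace("_", "")
    if p not in POLLUTANTS:
        raise ValueError(f"unknown pollutant {pollutant!r}; expected one of {POLLUTANTS}")
    return p


@dataclass(frozen=True)
class MassBalanceInput:
    """Fuel-combustion parameters for the SO2 mass balance.

    sulfur_content_rate
        Mass fraction of sulfur in the fuel (``S``).
    fuel_consumption
        Annual fuel burned, ton/yr (``omega``).
    conversion_rate
        Fraction of fuel sulfur converted to SO2 (``eps``); 0.8 for coal,
        1.0 for oil by default.
    desulfurization_rate
        Fraction of formed SO2 removed by control equipment (``eta``).
    molecular_ratio
        M(SO2)/M(S) = 64/32 = 2; exposed for transparency only.
    """

    sulfur_content_rate: float
    fuel_consumption: float
    conversion_rate: float = 0.8
    desulfurization_rate: float = 0.0
    molecular_ratio: float = SO2_TO_S_MOLECULAR_RATIO

    def __post_init__(self) -> None:
        _check_fraction("sulfur_content_rate", self.sulfur_content_rate)
        _check_fraction("conversion_rate", self.conversion_rate)
        _check_fraction("desulfurization_rate", self.desulfurization_rate)
        _check_nonneg("fuel_consumption", self.fuel_consumption)
        if self.molecular_ratio <= 0:
            raise ValueError("molecular_ratio must be positive")


@dataclass(frozen=True)
class VehicleClassRecord:
    """One vehicle class of the fleet inventory.

    ``count`` vehicles (``P_j``) each drive ``annual_mileage`` km/yr (``M_j``)
    and emit ``ef_so2`` / ``ef_pm10`` grams per km (``EF_ij``).
    """

    vehicle_type: str
    count: float
    annual_mileage: float
    ef_so2: float
    ef_pm10: float

    def __post_init__(self) -> None:
        _check_nonneg("count", self.count)
        _check_nonneg("annual_mileage", self.annual_mileage)
        _check_nonneg("ef_so2", self.ef_so2)
        _check_nonneg("ef_pm10", self.ef_pm10)

    def emission_factor(self, pollutant: str) -> float:
        return self.ef_so2 if _check_pollutant(pollutant) == "SO2" else self.ef_pm10


@dataclass(frozen=True)
class AreaActivityRecord:
    """Activity amount and emission factors of one area-source category.

    ``activity_amount`` is fuel burned or crop residue combusted, ton/yr;
    factors are kg pollutant per ton of activity.  A factor of ``None`` means
    the pollutant is not estimated by the emission-factor method for this
    category (SO2 of key plots and urban residential land uses the mass
    balance instead).
    """

    source_category: str
    activity_amount: float
    ef_so2: float | None = None
    ef_pm10: float | None = None

    def __post_init__(self) -> None:
        _check_nonneg("activity_amount", self.activity_amount)
        for name, ef in (("ef_so2", self.ef_so2), ("ef_pm10", self.ef_pm10)):
            if ef is not None:
                _check_nonneg(name, ef)


def mass_balance_so2(inp: MassBalanceInput) -> float:
    """Annual SO2 emission from fuel combustion, kg/yr, by sulfur mass balance."""
    return (
        inp.molecular_ratio
        * inp.sulfur_content_rate
        * inp.fuel_consumption
        * inp.conversion_rate
        * (1.0 - inp.desulfurization_rate)
        * KG_PER_TON
    )


def vehicle_emissions(
    fleet: Sequence[VehicleClassRecord], pollutant: str
) -> tuple[pd.Series, float]:
    """Per-vehicle-type annual emissions and fleet total, ton/yr.

    For each class ``j``: E = P_j * M_j * EF_ij * 1e-3 kg, reported in tons.
    """
    pollutant = _check_pollutant(pollutant)
    if not fleet:
        raise ValueError("fleet must be non-empty")
    kg = {
        rec.vehicle_type: rec.count * rec.annual_mileage * rec.emission_factor(pollutant) * 1e-3
        for rec in fleet
    }
    tons = pd.Series(kg, name=f"{pollutant}_ton") / KG_PER_TON
    return tons, float(tons.sum())


def area_source_emissions(record: AreaActivityRecord, pollutant: str) -> float:
    """Annual emission of one area source, ton/yr: activity x EF (kg/ton) / 1000."""
    pollutant = _check_pollutant(pollutant)
    ef = record.ef_so2 if pollutant == "SO2" else record.ef_pm10
    if ef is None:
        raise ValueError(
            f"no {pollutant} emission factor defined for category "
            f"{record.source_category!r}; SO2 from fuel-burning categories is "
            "estimated with mass_balance_so2 instead"
        )
    return record.activity_amount * ef / KG_PER_TON


@dataclass(frozen=True)
class InventoryEntry:
    """One row of an inventory table."""

    name: str  # source category or vehicle type
    pollutant: str
    emission_ton: float
    group: str  # "stationary" (point+area) or "transportation"

    def __post_init__(self) -> None:
        _check_nonneg("emission_ton", self.emission_ton)


@dataclass
class EmissionInventory:
    """Per-pollutant, per-source annual emissions for one calendar year.

    Percentage shares are computed within each table group (point+area sources
    versus transportation) because the two groups are reported as separate
    tables; they are kept at full precision and rounded only for display.
    """

    year: int
    entries: list[InventoryEntry] = field(default_factory=list)

    def total(self, pollutant: str, group: str | None = None) -> float:
        pollutant = _check_pollutant(pollutant)
        return sum(
            e.emission_ton
            for e in self.entries
            if e.pollutant == pollutant and (group is None or e.group == group)
        )

    def share(self, entry: InventoryEntry) -> float:
        """Percentage share of an entry within its pollutant + group table."""
        total = self.total(entry.pollutant, entry.group)
        return 100.0 * entry.emission_ton / total if total > 0 else 0.0

    def category_emission(self, pollutant: str, spatial_category: str) -> float:
        """Emission attributed to one spatial land-use category, ton/yr.

        Vehicle-class entries all belong to transportation land.
        """
        pollutant = _check_pollutant(pollutant)
        if spatial_category == "transportation":
            return self.total(pollutant, group="transportation")
        return sum(
            e.emission_ton
            for e in self.entries
            if e.pollutant == pollutant and e.group == "stationary" and e.name == spatial_category
        )

    def to_dataframe(self, decimals: int | None = 2) -> pd.DataFrame:
        """Tabulate entries with totals and shares, mirroring the report layout."""
        rows = []
        for e in self.entries:
            share = self.share(e)
            rows.append(
                {
                    "year": self.year,
                    "group": e.group,
                    "source": e.name,
                    "pollutant": e.pollutant,
                    "emission_ton": round(e.emission_ton, decimals) if decimals else e.emission_ton,
                    "share_pct": round(share, decimals) if decimals else share,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_entries(
        cls,
        year: int,
        entries: Iterable[tuple[str, str, float, str]],
    ) -> "EmissionInventory":
        """Build directly from (name, pollutant, emission_ton, group) rows."""
        inv = cls(year=year)
        for name, pollutant, emission, group in entries:
            inv.entries.append(
                InventoryEntry(name=name, pollutant=_check_pollutant(pollutant),
                               emission_ton=emission, group=group)
            )
        return inv


@dataclass(frozen=True)
class CategoryParams:
    """Estimation inputs for one stationary source category.

    SO2 comes from the mass balance when ``so2_mass_balance`` inputs are given
    (key plots, urban residential), otherwise from ``activity.ef_so2``.
    PM10 always uses the emission-factor route via ``activity``.
    """

    category: str
    activity: AreaActivityRecord | None = None
    so2_mass_balance: tuple[MassBalanceInput, ...] = ()

    def so2_tons(self) -> float:
        if self.so2_mass_balance:
            return sum(mass_balance_so2(mb) for mb in self.so2_mass_balance) / KG_PER_TON
        if self.activity is not None and self.activity.ef_so2 is not None:
            return area_source_emissions(self.activity, "SO2")
        raise ValueError(
            f"category {self.category!r} is missing SO2 inputs: provide either "
            "so2_mass_balance or an activity record with ef_so2"
        )

    def pm10_tons(self) -> float:
        if self.activity is None or self.activity.ef_pm10 is None:
            raise ValueError(
                f"category {self.category!r} is missing PM10 inputs: provide an "
                "activity record with ef_pm10"
            )
        return area_source_emissions(self.activity, "PM10")


def build_inventory(
    stationary: Sequence[CategoryParams],
    fleet: Sequence[VehicleClassRecord],
    year: int,
) -> EmissionInventory:
    """Compute the full two-table inventory for one year.

    Stationary categories contribute one SO2 and one PM10 entry each; every
    vehicle class contributes one entry per pollutant in the transportation
    group.  Totals and shares are available from the returned inventory.
    """
    inv = EmissionInventory(year=year)
    seen: set[str] = set()
    for params in stationary:
        if params.category in seen:
            raise ValueError(f"duplicate stationary category {params.category!r}")
        seen.add(params.category)
        inv.entries.append(
            InventoryEntry(params.category, "SO2", params.so2_tons(), "stationary")
        )
        inv.entries.append(
            InventoryEntry(params.category, "PM10", params.pm10_tons(), "stationary")
        )
    if fleet:
        for pollutant in POLLUTANTS:
            per_type, _ = vehicle_emissions(fleet, pollutant)
            for vtype, tons in per_type.items():
                inv.entries.append(
                    InventoryEntry(str(vtype), pollutant, float(tons), "transportation")
                )
    return inv


@dataclass
class SourceField:
    """Gridded source intensities with stack heights and ground elevation.

    q
        Per-cell annual source intensity, ton/yr.
    delta_h
        Per-cell source height above ground, m (emission-weighted mean where
        categories overlap through explicit point placements).
    elevation
        Ground elevation above sea level, m (from the DEM).
    """

    grid: Grid
    q: np.ndarray
    delta_h: np.ndarray
    elevation: np.ndarray
    pollutant: str = ""

    def __post_init__(self) -> None:
        for name, arr in (("q", self.q), ("delta_h", self.delta_h), ("elevation", self.elevation)):
            if np.asarray(arr).shape != self.grid.shape:
                raise ValueError(f"{name} shape {np.asarray(arr).shape} != grid {self.grid.shape}")
        if np.any(self.q < 0):
            raise ValueError("source intensities must be non-negative")

    @property
    def total_tons(self) -> float:
        return float(self.q.sum())


def rasterize_emissions(
    inventory: EmissionInventory,
    landuse_grid: Grid,
    landuse: np.ndarray,
    code_map: Mapping[int, str],
    heights: Mapping[str, float],
    dem: np.ndarray,
    pollutant: str,
    point_placements: Mapping[str, Sequence[tuple[int, int, float]]] | None = None,
) -> SourceField:
    """Spread inventoried emissions onto the land-use raster.

    Each spatial category's annual emission is divided equally among its raster
    cells.  Categories listed in ``point_placements`` are instead placed at the
    given ``(row, col, tonnage)`` cells (tonnages must sum to the category's
    inventoried emission).  ``delta_h`` takes the emission-weighted mean of the
    category heights wherever more than one category emits in a cell.
    """
    pollutant = _check_pollutant(pollutant)
    landuse = np.asarray(landuse)
    dem = np.asarray(dem, dtype=float)
    if landuse.shape != landuse_grid.shape or dem.shape != landuse_grid.shape:
        raise ValueError("land-use and DEM rasters must match the grid geometry")
    point_placements = dict(point_placements or {})

    category_cells = {cat: landuse == code for code, cat in code_map.items()}
    q = np.zeros(landuse_grid.shape)
    dh_weighted = np.zeros(landuse_grid.shape)

    categories = set(
        e.name if e.group == "stationary" else "transportation" for e in inventory.entries
    )
    for cat in sorted(categories):
        emission = inventory.category_emission(pollutant, cat)
        if emission == 0:
            continue
        dh = float(heights.get(cat, 0.0))
        if cat in point_placements:
            placed = point_placements[cat]
            placed_total = sum(t for _, _, t in placed)
            if not np.isclose(placed_total, emission, rtol=1e-6):
                raise ValueError(
                    f"point placements for {cat!r} sum to {placed_total} t but the "
                    f"inventory holds {emission} t"
                )
            for row, col, tons in placed:
                if not (0 <= row < landuse_grid.nrows and 0 <= col < landuse_grid.ncols):
                    raise ValueError(f"placement ({row}, {col}) outside the grid")
                q[row, col] += tons
                dh_weighted[row, col] += tons * dh
        else:
            mask = category_cells.get(cat)
            if mask is None or not mask.any():
                raise ValueError(
                    f"category {cat!r} has {emission} t of {pollutant} but no raster "
                    "cells carry its land-use code"
                )
            per_cell = emission / int(mask.sum())
            q[mask] += per_cell
            dh_weighted[mask] += per_cell * dh

    delta_h = np.divide(dh_weighted, q, out=np.zeros_like(q), where=q > 0)
    return SourceField(
        grid=landuse_grid, q=q, delta_h=delta_h, elevation=dem.copy(), pollutant=pollutant
    )
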