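"""Concentration-level classification and planning-map overlay.

Annual-mean concentration fields are binned into ordered pollution levels
(default six levels per pollutant, edges in mg/m3 following the ambient
air-quality standard breakpoints used for SO2 and PM10 reporting), tabulated
as areas in hectares, overlaid with a land-use-planning layer to give the
affected area per planning category, and compared between a reference and a
target year.

Bin convention: intervals are lower-closed, [edge_i, edge_{i+1}) — a value
exactly equal to an edge belongs to the higher level.  Level indices are
1-based; level 1 is "below the first edge".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

try:  # vectorized point-in-polygon for planning overlays
    from shapely import contains_xy as _contains_xy
    from shapely.geometry.base import BaseGeometry
except ImportError:  # pragma: no cover
    _contains_xy = None
    BaseGeometry = ()  # type: ignore[assignment]

from lapmd.grids import Grid, require_congruent
from lapmd.dispersion import ConcentrationField

__all__ = [
    "LevelScheme",
    "DEFAULT_SCHEMES",
    "classify",
    "overlay",
    "compare_scenarios",
    "rasterize_planning",
]


@dataclass(frozen=True)
class LevelScheme:
    """Ordered concentration bin edges (mg/m3) defining pollution levels."""

    pollutant: str
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 1:
            raise ValueError("a level scheme needs at least one edge (two levels)")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.edges) + 1

    def labels(self) -> list[str]:
        e = self.edges
        out = [f"<{e[0]:g}"]
        out += [f"{a:g}-{b:g}" for a, b in zip(e, e[1:])]
        out.append(f">{e[-1]:g}")
        return out


#: Six-level default schemes (five edges each) used in concentration reports.
DEFAULT_SCHEMES: dict[str, LevelScheme] = {
    "SO2": LevelScheme("SO2", (0.005, 0.01, 0.02, 0.06, 0.1)),
    "PM10": LevelScheme("PM10", (0.005, 0.02, 0.04, 0.07, 0.14)),
}

#: Three-level alternative following the two ambient-standard limit values.
AQSC_3LEVEL_SCHEMES: dict[str, LevelScheme] = {
    "SO2": LevelScheme("SO2", (0.02, 0.06)),
    "PM10": LevelScheme("PM10", (0.04, 0.07)),
}


def classify(
    field: ConcentrationField, scheme: LevelScheme
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign a level to every cell and tabulate per-level areas.

    Returns the 1-based level raster and a table with one row per level:
    label, cell count, area in hm2 and percentage of the grid, plus the field
    mean concentration in the table attrs.
    """
    if not np.all(np.isfinite(field.c)):
        raise ValueError("concentration field contains non-finite cells")
    levels = np.digitize(field.c, scheme.edges, right=False) + 1
    counts = np.bincount(levels.ravel(), minlength=scheme.n_levels + 1)[1:]
    cell_area = field.grid.cell_area_hm2
    table = pd.DataFrame(
        {
            "level": np.arange(1, scheme.n_levels + 1),
            "label": scheme.labels(),
            "cells": counts,
            "area_hm2": counts * cell_area,
            "pct": 100.0 * counts / counts.sum(),
        }
    )
    table.attrs["mean_concentration_mg_m3"] = field.mean
    table.attrs["pollutant"] = scheme.pollutant
    return levels, table


def rasterize_planning(
    grid: Grid, polygons: Sequence[tuple[str, "BaseGeometry"]]
) -> np.ndarray:
    """Rasterize (category, polygon) pairs by cell-center containment.

    Later polygons overwrite earlier ones where they overlap.  Cells covered
    by no polygon get the empty-string category.
    """
    if _contains_xy is None:  # pragma: no cover
        raise ImportError("shapely is required to rasterize planning polygons")
    x, y = grid.cell_centers()
    out = np.full(grid.shape, "", dtype=object)
    for category, geom in polygons:
        inside = _contains_xy(geom, x, y)
        out[inside] = category
    return out


def overlay(
    level_raster: np.ndarray,
    planning: np.ndarray | Sequence[tuple[str, "BaseGeometry"]],
    grid: Grid,
    scheme: LevelScheme,
) -> pd.DataFrame:
    """Cross-tabulate pollution levels against planning categories.

    ``planning`` is either a categorical raster congruent with the grid or a
    sequence of (category, shapely polygon) pairs rasterized by cell-center
    containment.  Returns one row per (category, level) with the area in hm2
    and the percentage of the category's area; categories present in the
    layer but absent from the grid intersection raise an error.
    """
    level_raster = np.asarray(level_raster)
    if level_raster.shape != grid.shape:
        raise ValueError("level raster does not match the grid geometry")
    if not isinstance(planning, np.ndarray):
        planning = rasterize_planning(grid, planning)
    if planning.shape != grid.shape:
        raise ValueError("planning raster does not match the grid geometry")

    categories = sorted({str(c) for c in np.unique(planning) if str(c) != ""})
    if not categories:
        raise ValueError("planning layer does not intersect the grid")
    cell_area = grid.cell_area_hm2
    labels = scheme.labels()
    rows = []
    for cat in categories:
        cat_mask = planning == cat
        n_cat = int(cat_mask.sum())
        for level in range(1, scheme.n_levels + 1):
            n = int(((level_raster == level) & cat_mask).sum())
            rows.append(
                {
                    "category": cat,
                    "level": level,
                    "label": labels[level - 1],
                    "cells": n,
                    "area_hm2": n * cell_area,
                    "pct": 100.0 * n / n_cat if n_cat else 0.0,
                }
            )
    return pd.DataFrame(rows)


def compare_scenarios(
    ref: ConcentrationField,
    target: ConcentrationField,
    scheme: LevelScheme,
) -> dict:
    """Reference-vs-target comparison of two congruent concentration fields.

    Returns the per-level area table of both years with the area change, the
    mean-concentration change, and the cellwise difference raster
    (target - reference).
    """
    require_congruent(ref.grid, target.grid)
    _, ref_table = classify(ref, scheme)
    _, tgt_table = classify(target, scheme)
    levels = ref_table[["level", "label"]].copy()
    levels["ref_area_hm2"] = ref_table["area_hm2"]
    levels["target_area_hm2"] = tgt_table["area_hm2"]
    levels["area_change_hm2"] = tgt_table["area_hm2"] - ref_table["area_hm2"]
    return {
        "pollutant": scheme.pollutant,
        "levels": levels,
        "ref_mean": ref.mean,
        "target_mean": target.mean,
        "mean_change": target.mean - ref.mean,
        "difference": target.c - ref.c,
    }
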