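"""Run configuration, parameter-file parsing and provenance records."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from lapmd.inventory import AreaActivityRecord, CategoryParams, MassBalanceInput, VehicleClassRecord

__all__ = ["RunConfig", "parse_inventory_params", "provenance", "config_hash"]


@dataclass
class RunConfig:
    """Paths and options of one assessment run, usually loaded from YAML."""

    landuse: Path
    dem: Path
    met: Path
    params: dict[str, Path]  # scenario label -> inventory parameter JSON
    planning: Path | None = None
    pollutants: tuple[str, ...] = ("SO2", "PM10")
    out_dir: Path = Path("outputs")
    latitude_deg: float = 34.6
    calm_threshold: float = 0.5
    height_convention: str = "absolute"
    min_distance: float | None = None

    def __post_init__(self) -> None:
        self.landuse = Path(self.landuse)
        self.dem = Path(self.dem)
        self.met = Path(self.met)
        self.params = {k: Path(v) for k, v in self.params.items()}
        self.planning = Path(self.planning) if self.planning else None
        self.out_dir = Path(self.out_dir)
        if not self.pollutants:
            raise ValueError("pollutants list must be non-empty")

    def validate_paths(self) -> None:
        missing = [
            f"{name}: {path}"
            for name, path in self.iter_paths()
            if path is not None and not Path(path).exists()
        ]
        if missing:
            raise FileNotFoundError("missing input file(s): " + "; ".join(missing))

    def iter_paths(self):
        yield "landuse", self.landuse
        yield "dem", self.dem
        yield "met", self.met
        for label, p in self.params.items():
            yield f"params[{label}]", p
        yield "planning", self.planning

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        required = ("landuse", "dem", "met", "params")
        for key in required:
            if key not in raw:
                raise ValueError(f"run config is missing required field {key!r}")
        base = Path(path).parent
        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p
        return cls(
            landuse=_resolve(raw["landuse"]),
            dem=_resolve(raw["dem"]),
            met=_resolve(raw["met"]),
            params={k: _resolve(v) for k, v in raw["params"].items()},
            planning=_resolve(raw["planning"]) if raw.get("planning") else None,
            pollutants=tuple(raw.get("pollutants", ("SO2", "PM10"))),
            out_dir=_resolve(raw.get("out_dir", "outputs")),
            latitude_deg=float(raw.get("latitude_deg", 34.6)),
            calm_threshold=float(raw.get("calm_threshold", 0.5)),
            height_convention=raw.get("height_convention", "absolute"),
            min_distance=raw.get("min_distance"),
        )


def parse_inventory_params(
    cfg: Mapping,
) -> tuple[list[CategoryParams], list[VehicleClassRecord], dict[str, float], dict[str, float]]:
    """Turn a parameter config dict into typed inventory inputs.

    Returns (stationary category params, vehicle fleet, source heights,
    per-pollutant attenuation).
    """
    stationary: list[CategoryParams] = []

    plots = cfg.get("key_plots", [])
    if plots:
        mb = tuple(
            MassBalanceInput(
                sulfur_content_rate=p["sulfur_content_rate"],
                fuel_consumption=p["fuel_consumption_ton"],
                conversion_rate=p.get("conversion_rate", 0.8),
                desulfurization_rate=p.get("desulfurization_rate", 0.0),
            )
            for p in plots
        )
        total_fuel = sum(p["fuel_consumption_ton"] for p in plots)
        ef_pm10 = plots[0].get("pm10_ef_kg_per_ton", 0.0)
        stationary.append(
            CategoryParams(
                category="key_plot",
                so2_mass_balance=mb,
                activity=AreaActivityRecord("key_plot", total_fuel, ef_pm10=ef_pm10),
            )
        )

    urb = cfg.get("urban_residential")
    if urb:
        stationary.append(
            CategoryParams(
                category="urban_residential",
                so2_mass_balance=(
                    MassBalanceInput(
                        sulfur_content_rate=urb["sulfur_content_rate"],
                        fuel_consumption=urb["fuel_consumption_ton"],
                        conversion_rate=urb.get("conversion_rate", 0.8),
                        desulfurization_rate=urb.get("desulfurization_rate", 0.0),
                    ),
                ),
                activity=AreaActivityRecord(
                    "urban_residential",
                    urb["fuel_consumption_ton"],
                    ef_pm10=urb.get("pm10_ef_kg_per_ton", 0.0),
                ),
            )
        )

    for cat in ("rural_residential", "agricultural"):
        sub = cfg.get(cat)
        if sub:
            stationary.append(
                CategoryParams(
                    category=cat,
                    activity=AreaActivityRecord(
                        cat,
                        sub["activity_ton"],
                        ef_so2=sub.get("ef_so2_kg_per_ton"),
                        ef_pm10=sub.get("ef_pm10_kg_per_ton"),
                    ),
                )
            )

    fleet = [
        VehicleClassRecord(
            vehicle_type=v["vehicle_type"],
            count=v["count"],
            annual_mileage=v["annual_mileage_km"],
            ef_so2=v["ef_so2_g_per_km"],
            ef_pm10=v["ef_pm10_g_per_km"],
        )
        for v in cfg.get("fleet", [])
    ]

    heights = {k: float(v) for k, v in cfg.get("heights_m", {}).items()}
    attenuation = {k.upper(): float(v) for k, v in cfg.get("attenuation", {}).items()}
    return stationary, fleet, heights, attenuation


def config_hash(obj) -> str:
    """Stable short hash of any JSON-able configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config_obj, extra: Mapping | None = None) -> dict:
    """Provenance sidecar contents: config hash, parameter echo, version."""
    from lapmd import __version__

    rec = {
        "software": "lapmd",
        "version": __version__,
        "config_hash": config_hash(config_obj),
        "config": config_obj,
    }
    if extra:
        rec.update(extra)
    return rec
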