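"""Wind rose and dispersion parameters from daily meteorological records.

The year of daily observations is reduced to the climatological summary the
long-term dispersion model needs: eight 45-degree wind-direction sectors, each
with an occurrence frequency and a mean wind speed, plus one representative
Pasquill stability class per sector from which the power-law dispersion
parameters sigma_y(x) and sigma_z(x) are evaluated.

Conventions (stated explicitly because they are easy to get wrong):

* sector 0 is centred on north (337.5-22.5 deg) and sectors run clockwise;
* "wind direction" is the direction the wind blows FROM; transport is toward
  the opposite bearing (handled by the dispersion engine);
* days with speed below ``calm_threshold`` (default 0.5 m/s) are excluded from
  the rose and reported as a calm fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DailyMetRecord",
    "WindRose",
    "SigmaModel",
    "DEFAULT_SIGMA_COEFFS",
    "N_SECTORS",
    "SECTOR_WIDTH_DEG",
    "build_wind_rose",
    "stability_class",
    "sector_index",
    "sigma_yz",
    "solar_elevation_noon",
]

N_SECTORS = 8
SECTOR_WIDTH_DEG = 360.0 / N_SECTORS
STABILITY_CLASSES = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class DailyMetRecord:
    """One day of surface meteorology.

    wind_direction is in degrees [0, 360), meteorological convention (blowing
    from); cloud_cover is a fraction of the sky in [0, 1]; solar_elevation
    (degrees) may be omitted and computed from the date and site latitude.
    """

    date: _date
    wind_direction: float
    wind_speed: float
    cloud_cover: float
    solar_elevation: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.wind_direction % 360.0 < 360.0:
            raise ValueError(f"wind_direction out of range: {self.wind_direction}")
        if self.wind_speed < 0:
            raise ValueError("wind_speed must be >= 0")
        if not 0.0 <= self.cloud_cover <= 1.0:
            raise ValueError("cloud_cover must be a fraction in [0, 1]")


def solar_elevation_noon(day: _date, latitude_deg: float) -> float:
    """Solar elevation at local solar noon, degrees.

    Uses the standard declination approximation
    delta = 23.45 sin(2 pi (284 + doy) / 365); elevation = 90 - |lat - delta|.
    Daily records carry no time of day, so local noon is the representative
    insolation for classifying daytime stability.
    """
    doy = day.timetuple().tm_yday
    decl = 23.45 * math.sin(2.0 * math.pi * (284 + doy) / 365.0)
    return 90.0 - abs(latitude_deg - decl)


def sector_index(direction_deg: float) -> int:
    """Sector of a wind FROM-direction; sector 0 centred on north, clockwise.

    A direction exactly on a sector boundary goes to the lower-indexed sector.
    """
    d = direction_deg % 360.0
    shifted = (d + SECTOR_WIDTH_DEG / 2.0) % 360.0
    idx = int(shifted // SECTOR_WIDTH_DEG)
    # boundary (e.g. 22.5 deg) belongs to the lower-indexed sector
    if shifted % SECTOR_WIDTH_DEG == 0.0 and d % SECTOR_WIDTH_DEG != 0.0:
        idx = (idx - 1) % N_SECTORS
    return idx % N_SECTORS


@dataclass
class WindRose:
    """Eight-sector climatological wind summary.

    ``frequency[s]`` is the fraction of non-calm days with wind from sector
    ``s``; ``mean_speed[s]`` the mean speed of those days (empty sectors carry
    the overall mean, which is never used because their frequency is zero).
    """

    frequency: np.ndarray
    mean_speed: np.ndarray
    calm_fraction: float = 0.0
    stability: tuple[str, ...] = field(default_factory=lambda: ("D",) * N_SECTORS)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.mean_speed = np.asarray(self.mean_speed, dtype=float)
        if self.frequency.shape != (N_SECTORS,) or self.mean_speed.shape != (N_SECTORS,):
            raise ValueError(f"wind rose needs exactly {N_SECTORS} sectors")
        if np.any(self.frequency < 0) or not np.isclose(self.frequency.sum(), 1.0):
            raise ValueError("sector frequencies must be non-negative and sum to 1")
        if np.any(self.mean_speed < 0):
            raise ValueError("mean speeds must be >= 0")

    def sector_bounds(self, s: int) -> tuple[float, float]:
        """Angular bounds [alpha1, alpha2] of sector s, degrees."""
        center = s * SECTOR_WIDTH_DEG
        return ((center - SECTOR_WIDTH_DEG / 2) % 360.0, (center + SECTOR_WIDTH_DEG / 2) % 360.0)

    def to_dict(self) -> dict:
        return {
            "frequency": self.frequency.tolist(),
            "mean_speed": self.mean_speed.tolist(),
            "calm_fraction": self.calm_fraction,
            "stability": list(self.stability),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WindRose":
        return cls(
            frequency=np.asarray(d["frequency"], dtype=float),
            mean_speed=np.asarray(d["mean_speed"], dtype=float),
            calm_fraction=float(d.get("calm_fraction", 0.0)),
            stability=tuple(d.get("stability", ("D",) * N_SECTORS)),
        )


def stability_class(
    record: DailyMetRecord, latitude_deg: float | None = None
) -> str:
    """Pasquill stability class (A-F) for one daily record.

    Classification follows the Pasquill scheme at daily resolution: insolation
    is banded by the noon solar elevation (strong > 60 deg, moderate 35-60,
    slight 15-35, weak below), downgraded one band when cloud cover exceeds
    1/2; overcast skies (cloud >= 7/8) give neutral class D regardless of sun
    and wind.  Night-time stable classes E/F are assigned for weak insolation
    with light winds, standing in for the stable fraction of the day.
    """
    elev = record.solar_elevation
    if elev is None:
        if latitude_deg is None:
            raise ValueError(
                "record has no solar_elevation and no latitude was given to compute it"
            )
        elev = solar_elevation_noon(record.date, latitude_deg)
    if record.cloud_cover is None:
        raise ValueError("cloud_cover is required for stability classification")

    if record.cloud_cover >= 7.0 / 8.0:
        return "D"

    if elev > 60:
        band = 0  # strong
    elif elev > 35:
        band = 1  # moderate
    elif elev > 15:
        band = 2  # slight
    else:
        band = 3  # weak
    if record.cloud_cover > 0.5:
        band = min(band + 1, 3)

    u = record.wind_speed
    # rows: speed bins (<2, 2-3, 3-5, 5-6, >=6); cols: insolation band
    table = (
        ("A", "B", "B", "F"),
        ("B", "B", "C", "E"),
        ("B", "C", "C", "D"),
        ("C", "C", "D", "D"),
        ("C", "D", "D", "D"),
    )
    if u < 2:
        row = 0
    elif u < 3:
        row = 1
    elif u < 5:
        row = 2
    elif u < 6:
        row = 3
    else:
        row = 4
    return table[row][band]


def build_wind_rose(
    records: Sequence[DailyMetRecord],
    calm_threshold: float = 0.5,
    latitude_deg: float | None = None,
    equal_frequency: bool = False,
) -> WindRose:
    """Reduce daily records to the eight-sector rose with per-sector stability.

    Sector frequency is the share of non-calm days blowing from that sector and
    the sector speed is the mean over those days.  The representative stability
    class per sector is the mode of the daily classes (ties break toward the
    more unstable class).  ``equal_frequency=True`` replaces the data-driven
    frequencies by the uniform 1/8 allocation.
    """
    if not records:
        raise ValueError("no meteorological records supplied")
    active = [r for r in records if r.wind_speed >= calm_threshold]
    if not active:
        raise ValueError(f"all {len(records)} records are calm (< {calm_threshold} m/s)")
    calm_fraction = 1.0 - len(active) / len(records)

    counts = np.zeros(N_SECTORS)
    sector_speeds: list[list[float]] = [[] for _ in range(N_SECTORS)]
    class_counts: list[dict[str, int]] = [dict() for _ in range(N_SECTORS)]
    for r in active:
        s = sector_index(r.wind_direction)
        counts[s] += 1
        sector_speeds[s].append(r.wind_speed)
        cls = stability_class(r, latitude_deg=latitude_deg)
        class_counts[s][cls] = class_counts[s].get(cls, 0) + 1

    frequency = counts / counts.sum()
    # sorted summation keeps the rose exactly permutation-invariant
    speed_sum = np.array([float(np.sum(np.sort(s))) for s in sector_speeds])
    overall_mean = float(np.sum(np.sort([r.wind_speed for r in active]))) / counts.sum()
    mean_speed = np.where(counts > 0, speed_sum / np.maximum(counts, 1), overall_mean)

    stability = []
    for s in range(N_SECTORS):
        if class_counts[s]:
            best = max(
                class_counts[s].items(),
                key=lambda kv: (kv[1], -STABILITY_CLASSES.index(kv[0])),
            )[0]
        else:
            best = "D"
        stability.append(best)

    if equal_frequency:
        frequency = np.full(N_SECTORS, 1.0 / N_SECTORS)
    return WindRose(
        frequency=frequency,
        mean_speed=mean_speed,
        calm_fraction=calm_fraction,
        stability=tuple(stability),
    )


#: Power-law dispersion coefficients sigma = a * (x/1000)^b (x in metres,
#: sigma in metres) per Pasquill class.  sigma_y uses the common 0.894
#: exponent; sigma_z uses per-class exponents from the standard power-law fits
#: to the Pasquill-Gifford curves, with the small additive offsets dropped so
#: that both parameters stay positive and monotone for all x > 0.
DEFAULT_SIGMA_COEFFS: dict[str, tuple[float, float, float, float]] = {
    #        a_y     b_y     a_z     b_z
    "A": (213.0, 0.894, 440.8, 1.941),
    "B": (156.0, 0.894, 106.6, 1.149),
    "C": (104.0, 0.894, 61.0, 0.911),
    "D": (68.0, 0.894, 33.2, 0.725),
    "E": (50.5, 0.894, 22.8, 0.678),
    "F": (34.0, 0.894, 14.35, 0.740),
}


@dataclass(frozen=True)
class SigmaModel:
    """Power-law horizontal/vertical dispersion parameters for one class."""

    stability_class: str
    a_y: float
    b_y: float
    a_z: float
    b_z: float

    def __post_init__(self) -> None:
        if min(self.a_y, self.a_z) <= 0 or min(self.b_y, self.b_z) < 0:
            raise ValueError("sigma power-law coefficients must be positive")

    @classmethod
    def for_class(
        cls,
        stability: str,
        coeffs: Mapping[str, tuple[float, float, float, float]] | None = None,
    ) -> "SigmaModel":
        coeffs = coeffs or DEFAULT_SIGMA_COEFFS
        if stability not in coeffs:
            raise KeyError(f"no sigma coefficients for stability class {stability!r}")
        a_y, b_y, a_z, b_z = coeffs[stability]
        return cls(stability, a_y, b_y, a_z, b_z)


def sigma_yz(x, model: SigmaModel):
    """Evaluate (sigma_y, sigma_z) in metres at downwind distance x metres."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("downwind distance must be positive")
    xk = x / 1000.0
    return model.a_y * xk**model.b_y, model.a_z * xk**model.b_z
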