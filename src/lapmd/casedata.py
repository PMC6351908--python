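"""Published city-scale inventory rows used as verification inputs.

Per-row annual emissions (ton/yr) of SO2 and PM10 for a coastal eastern-
Chinese city, reference year 2010 and planning target year 2020, organized in
the two table groups the toolkit reports: stationary (point + area) sources
and vehicle-based transportation sources.  The rows are inputs against which
the inventory arithmetic (group totals and percentage shares) is checked.

The printed 2010 transportation PM10 total in the source report is 8805.24 t,
while the row sum is 8805.23 t (rounding in the source); the toolkit reports
the exact sum.
"""

from __future__ import annotations

__all__ = [
    "STATIONARY_ROWS",
    "VEHICLE_ROWS",
    "PRINTED_TOTALS",
    "HEAVY_TRUCK_2010",
]

#: year -> category -> (so2_ton, pm10_ton)
STATIONARY_ROWS: dict[int, dict[str, tuple[float, float]]] = {
    2010: {
        "key_plot": (26036.38, 5864.63),
        "urban_residential": (8026.77, 42.81),
        "rural_residential": (478.5, 4476.55),
        "agricultural": (593.8, 14884.0),
    },
    2020: {
        "key_plot": (17746.32, 3997.31),
        "urban_residential": (9565.23, 51.02),
        "rural_residential": (430.65, 4028.9),
        "agricultural": (62.8, 1574.25),
    },
}

#: year -> vehicle type -> (ef_so2, so2_ton, ef_pm10, pm10_ton); EFs as listed.
VEHICLE_ROWS: dict[int, dict[str, tuple[float, float, float, float]]] = {
    2010: {
        "large_vehicle": (0.05, 786.52, 0.02, 314.61),
        "medium_vehicle": (0.01, 153.69, 0.02, 307.37),
        "small_car": (0.01, 2118.24, 0.02, 4236.48),
        "mini_vehicle": (0.01, 98.59, 0.02, 197.19),
        "heavy_truck": (0.10, 8918.00, 0.02, 1783.60),
        "medium_truck": (0.05, 1305.68, 0.02, 522.27),
        "light_truck": (0.01, 375.40, 0.02, 750.80),
        "mini_truck": (0.01, 2.18, 0.02, 4.36),
        "tricar": (0.05, 1721.37, 0.02, 688.55),
    },
    2020: {
        "large_vehicle": (0.030, 490.79, 0.012, 196.32),
        "medium_vehicle": (0.006, 95.90, 0.012, 191.80),
        "small_car": (0.006, 3029.09, 0.012, 6058.17),
        "mini_vehicle": (0.006, 140.99, 0.012, 281.98),
        "heavy_truck": (0.060, 5564.83, 0.012, 1112.97),
        "medium_truck": (0.030, 814.74, 0.012, 325.90),
        "light_truck": (0.006, 234.25, 0.012, 468.50),
        "mini_truck": (0.006, 1.36, 0.012, 2.72),
        "tricar": (0.030, 1074.13, 0.012, 429.65),
    },
}

#: (group, pollutant, year) -> printed total, ton/yr.
PRINTED_TOTALS: dict[tuple[str, str, int], float] = {
    ("stationary", "SO2", 2010): 35135.45,
    ("stationary", "PM10", 2010): 25267.99,
    ("stationary", "SO2", 2020): 27805.0,
    ("stationary", "PM10", 2020): 9651.48,
    ("transportation", "SO2", 2010): 15479.67,
    ("transportation", "SO2", 2020): 11446.08,
    ("transportation", "PM10", 2020): 9068.01,
    # transportation PM10 2010 printed as 8805.24; exact row sum is 8805.23
}

#: 2010 heavy-truck row: SO2 EF 0.10, SO2 8918.00 t, PM10 EF 0.02, PM10 1783.60 t.
HEAVY_TRUCK_2010 = {"ef_so2": 0.10, "so2_ton": 8918.00, "ef_pm10": 0.02, "pm10_ton": 1783.60}
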