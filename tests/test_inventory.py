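"""Inventory arithmetic: mass balance, emission factors, tables, rasterization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapmd.casedata import PRINTED_TOTALS, STATIONARY_ROWS, VEHICLE_ROWS
from lapmd.grids import Grid
from lapmd.inventory import (
    AreaActivityRecord,
    CategoryParams,
    EmissionInventory,
    MassBalanceInput,
    VehicleClassRecord,
    area_source_emissions,
    build_inventory,
    mass_balance_so2,
    rasterize_emissions,
    vehicle_emissions,
)


class TestMassBalance:
    def test_direct_evaluation(self):
        # 2 x 0.01 x 1000 x 0.8 x (1 - 0.6) x 1e3 = 6400 kg
        inp = MassBalanceInput(
            sulfur_content_rate=0.01,
            fuel_consumption=1000.0,
            conversion_rate=0.8,
            desulfurization_rate=0.6,
        )
        assert mass_balance_so2(inp) == pytest.approx(6400.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sulfur_content_rate=0.02, fuel_consumption=500, desulfurization_rate=1.0),
            dict(sulfur_content_rate=0.0, fuel_consumption=1000),
            dict(sulfur_content_rate=0.02, fuel_consumption=0.0),
            dict(sulfur_content_rate=0.02, fuel_consumption=1000, conversion_rate=0.0),
        ],
    )
    def test_zero_iff_factor_vanishes(self, kwargs):
        assert mass_balance_so2(MassBalanceInput(**kwargs)) == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sulfur_content_rate=1.2, fuel_consumption=1.0),
            dict(sulfur_content_rate=-0.1, fuel_consumption=1.0),
            dict(sulfur_content_rate=0.01, fuel_consumption=-5.0),
            dict(sulfur_content_rate=0.01, fuel_consumption=1.0, desulfurization_rate=1.5),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MassBalanceInput(**kwargs)

    @settings(deadline=None, max_examples=50)
    @given(
        s=st.floats(0, 0.05),
        w=st.floats(0, 1e6),
        eps=st.floats(0, 1),
        eta=st.floats(0, 1),
        k=st.floats(0.1, 10),
    )
    def test_linearity_in_fuel(self, s, w, eps, eta, k):
        base = mass_balance_so2(MassBalanceInput(s, w, eps, eta))
        scaled = mass_balance_so2(MassBalanceInput(s, w * k, eps, eta))
        assert scaled == pytest.approx(base * k, rel=1e-12, abs=1e-9)


class TestVehicleEmissions:
    def test_direct_evaluation(self):
        # 100 vehicles x 10 000 km x 0.05 g/km = 50 kg = 0.05 t
        fleet = [VehicleClassRecord("car", 100, 10_000, ef_so2=0.05, ef_pm10=0.02)]
        per_type, total = vehicle_emissions(fleet, "SO2")
        assert per_type["car"] == pytest.approx(0.05)
        assert total == pytest.approx(0.05)

    def test_zero_fleet_counts(self):
        fleet = [
            VehicleClassRecord("a", 0, 10_000, 0.05, 0.02),
            VehicleClassRecord("b", 0, 20_000, 0.10, 0.02),
        ]
        per_type, total = vehicle_emissions(fleet, "PM10")
        assert (per_type == 0).all() and total == 0.0

    def test_unknown_pollutant_rejected(self):
        fleet = [VehicleClassRecord("a", 1, 1, 0.05, 0.02)]
        with pytest.raises(ValueError, match="unknown pollutant"):
            vehicle_emissions(fleet, "NOx")

    def test_pollutant_ratio_equals_ef_ratio(self):
        """For fixed P and M, E_PM10 / E_SO2 = EF_PM10 / EF_SO2 exactly."""
        fleet = [VehicleClassRecord("heavy_truck", 23_456, 61_700, ef_so2=0.10, ef_pm10=0.02)]
        so2, _ = vehicle_emissions(fleet, "SO2")
        pm10, _ = vehicle_emissions(fleet, "PM10")
        assert pm10["heavy_truck"] / so2["heavy_truck"] == pytest.approx(0.02 / 0.10, rel=1e-14)

    def test_heavy_truck_published_row(self):
        """2010 heavy trucks: 8918.00 t SO2 at EF ratio 0.02/0.10 gives 1783.60 t PM10."""
        ef_so2, so2_t, ef_pm10, pm10_t = VEHICLE_ROWS[2010]["heavy_truck"]
        assert so2_t * ef_pm10 / ef_so2 == pytest.approx(pm10_t, abs=0.005)


class TestAreaSources:
    def test_zero_activity(self):
        rec = AreaActivityRecord("agricultural", 0.0, ef_so2=0.4, ef_pm10=10.0)
        assert area_source_emissions(rec, "SO2") == 0.0

    def test_direct_evaluation(self):
        # 1000 t residue x 10 kg/t = 10 t PM10
        rec = AreaActivityRecord("agricultural", 1000.0, ef_so2=0.4, ef_pm10=10.0)
        assert area_source_emissions(rec, "PM10") == pytest.approx(10.0)
        assert area_source_emissions(rec, "SO2") == pytest.approx(0.4)

    def test_missing_factor_directs_to_mass_balance(self):
        rec = AreaActivityRecord("key_plot", 1000.0, ef_pm10=2.97)
        with pytest.raises(ValueError, match="mass_balance_so2"):
            area_source_emissions(rec, "SO2")


class TestBuildInventory:
    def test_single_category_share_is_100(self):
        inv = build_inventory(
            [
                CategoryParams(
                    "agricultural",
                    activity=AreaActivityRecord("agricultural", 1000, ef_so2=0.4, ef_pm10=10),
                )
            ],
            fleet=[],
            year=2010,
        )
        for entry in inv.entries:
            assert inv.share(entry) == pytest.approx(100.0)

    def test_missing_parameter_named(self):
        with pytest.raises(ValueError, match="urban_residential"):
            build_inventory(
                [CategoryParams("urban_residential")], fleet=[], year=2010
            )

    @pytest.mark.parametrize("year", [2010, 2020])
    @pytest.mark.parametrize("pollutant", ["SO2", "PM10"])
    def test_published_group_totals(self, year, pollutant):
        """Row emissions reproduce the printed group totals at printed precision."""
        inv = _case_inventory(year)
        for group in ("stationary", "transportation"):
            printed = PRINTED_TOTALS.get((group, pollutant, year))
            if printed is None:
                continue
            assert inv.total(pollutant, group) == pytest.approx(printed, abs=0.005)

    def test_transport_pm10_2010_exact_row_sum(self):
        """The 2010 transport PM10 total is the exact row sum 8805.23 t."""
        inv = _case_inventory(2010)
        assert inv.total("PM10", "transportation") == pytest.approx(8805.23, abs=0.005)

    @pytest.mark.parametrize(
        "year, name, pollutant, printed_share",
        [
            (2010, "key_plot", "SO2", 74.1),
            (2010, "small_car", "SO2", 13.68),
            (2010, "agricultural", "PM10", 58.9),
            (2020, "urban_residential", "SO2", 34.4),
            (2010, "heavy_truck", "SO2", 57.61),
            (2020, "small_car", "PM10", 66.81),
        ],
    )
    def test_published_shares(self, year, name, pollutant, printed_share):
        inv = _case_inventory(year)
        entry = next(
            e for e in inv.entries if e.name == name and e.pollutant == pollutant
        )
        ndigits = len(str(printed_share).split(".")[1])
        assert round(inv.share(entry), ndigits) == pytest.approx(printed_share)

    def test_shares_sum_to_100_within_groups(self):
        inv = _case_inventory(2010)
        frame = inv.to_dataframe(decimals=None)
        sums = frame.groupby(["group", "pollutant"])["share_pct"].sum()
        assert np.allclose(sums, 100.0)


def _case_inventory(year: int) -> EmissionInventory:
    rows = []
    for cat, (so2, pm10) in STATIONARY_ROWS[year].items():
        rows.append((cat, "SO2", so2, "stationary"))
        rows.append((cat, "PM10", pm10, "stationary"))
    for vtype, (_, so2, _, pm10) in VEHICLE_ROWS[year].items():
        rows.append((vtype, "SO2", so2, "transportation"))
        rows.append((vtype, "PM10", pm10, "transportation"))
    return EmissionInventory.from_entries(year, rows)


class TestRasterize:
    def setup_method(self):
        self.grid = Grid(nrows=2, ncols=2, cellsize=300.0)
        self.dem = np.zeros((2, 2))

    def test_uniform_split(self):
        inv = EmissionInventory.from_entries(
            2010, [("agricultural", "SO2", 100.0, "stationary")]
        )
        landuse = np.full((2, 2), 1)
        field = rasterize_emissions(
            inv, self.grid, landuse, {1: "agricultural"}, {"agricultural": 0.0},
            self.dem, "SO2",
        )
        assert np.allclose(field.q, 25.0)

    def test_conservation(self, toy_city):
        from lapmd.pipeline import inventory_from_params, source_field_from_params

        inv = inventory_from_params(toy_city["params"])
        for pollutant in ("SO2", "PM10"):
            field = source_field_from_params(
                toy_city["params"], inv, toy_city["grid"], toy_city["landuse"],
                toy_city["dem"], pollutant,
            )
            assert field.total_tons == pytest.approx(inv.total(pollutant), rel=1e-9)

    def test_point_placements(self):
        inv = EmissionInventory.from_entries(2010, [("key_plot", "SO2", 30.0, "stationary")])
        landuse = np.full((2, 2), 5)
        field = rasterize_emissions(
            inv, self.grid, landuse, {5: "key_plot"}, {"key_plot": 30.0}, self.dem, "SO2",
            point_placements={"key_plot": [(0, 0, 10.0), (1, 1, 20.0)]},
        )
        assert field.q[0, 0] == 10.0 and field.q[1, 1] == 20.0
        assert field.q[0, 1] == 0.0 and field.q[1, 0] == 0.0
        assert field.delta_h[0, 0] == 30.0

    def test_placements_must_conserve_mass(self):
        inv = EmissionInventory.from_entries(2010, [("key_plot", "SO2", 30.0, "stationary")])
        landuse = np.full((2, 2), 5)
        with pytest.raises(ValueError, match="sum to"):
            rasterize_emissions(
                inv, self.grid, landuse, {5: "key_plot"}, {}, self.dem, "SO2",
                point_placements={"key_plot": [(0, 0, 10.0)]},
            )

    def test_emission_without_cells_errors(self):
        inv = EmissionInventory.from_entries(2010, [("key_plot", "SO2", 5.0, "stationary")])
        landuse = np.full((2, 2), 1)  # no key-plot cells
        with pytest.raises(ValueError, match="no raster cells"):
            rasterize_emissions(
                inv, self.grid, landuse, {1: "agricultural", 5: "key_plot"}, {},
                self.dem, "SO2",
            )

    def test_linearity_scaling_activities(self):
        """Scaling every activity by k scales every emission and q by k; shares fixed."""
        k = 3.5

        def make(scale):
            return build_inventory(
                [
                    CategoryParams(
                        "key_plot",
                        so2_mass_balance=(MassBalanceInput(0.01, 1000 * scale, 0.8, 0.6),),
                        activity=AreaActivityRecord("key_plot", 1000 * scale, ef_pm10=2.97),
                    ),
                    CategoryParams(
                        "agricultural",
                        activity=AreaActivityRecord(
                            "agricultural", 500 * scale, ef_so2=0.4, ef_pm10=10
                        ),
                    ),
                ],
                fleet=[VehicleClassRecord("car", 100 * scale, 10_000, 0.05, 0.02)],
                year=2010,
            )

        base, scaled = make(1.0), make(k)
        for e_base, e_scaled in zip(base.entries, scaled.entries):
            assert e_scaled.emission_ton == pytest.approx(e_base.emission_ton * k, rel=1e-12)
            assert scaled.share(e_scaled) == pytest.approx(base.share(e_base), rel=1e-12)
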