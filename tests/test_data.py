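"""Domain types, phenophase scoring and file round-trips."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenokrig import (
    PhenoGrid,
    Phenophase,
    PollenSeries,
    assign_phenophase,
    build_datasets,
    read_ascii_grid,
    read_observations,
    read_points,
    write_ascii_grid,
    write_observations,
    write_points,
)
from phenokrig.reference import cordoba_network

from conftest import make_dataset


class TestAssignPhenophase:
    @pytest.mark.parametrize(
        "fraction, emerged, empty, expected",
        [
            (0.0, True, False, Phenophase.BEFORE_FLOWERING),
            (0.10, True, False, Phenophase.START_FLOWERING),
            (0.25, True, False, Phenophase.START_FLOWERING),  # tie -> lower phase
            (0.50, True, False, Phenophase.FULL_FLOWERING),
            (0.75, True, False, Phenophase.FULL_FLOWERING),  # tie -> lower phase
            (0.90, True, False, Phenophase.ENDING_FLOWERING),
            (1.0, True, True, Phenophase.PAST_FLOWERING),
            (0.40, True, True, Phenophase.PAST_FLOWERING),  # empty anthers dominate
        ],
    )
    def test_stage_boundaries(self, fraction, emerged, empty, expected):
        assert assign_phenophase(fraction, emerged, empty) is expected

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_fraction_domain(self, bad):
        with pytest.raises(ValueError):
            assign_phenophase(bad)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_fraction_open(self, f1, f2):
        lo, hi = sorted([f1, f2])
        assert assign_phenophase(lo) <= assign_phenophase(hi)


class TestPointsIO:
    def test_study_network_fixture(self, network):
        assert len(network) == 10
        zones = [p.zone.value for p in network]
        assert zones.count("termomediterranean") == 5
        assert zones.count("mesomediterranean") == 5
        villares = next(p for p in network if p.id == "Los Villares")
        assert (villares.altitude, villares.x, villares.y) == (585, 341149, 4203129)

    def test_round_trip(self, tmp_path, network):
        path = tmp_path / "points.csv"
        write_points(network, path)
        again = read_points(path)
        assert again == network

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "points.csv"
        path.write_text("id,x,y,altitude,zone\n")
        assert read_points(path) == []

    def test_duplicate_id_names_row(self, tmp_path):
        path = tmp_path / "points.csv"
        path.write_text(
            "id,x,y,altitude,zone\n"
            "A,0,0,10,termomediterranean\n"
            "A,1,1,20,mesomediterranean\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_points(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "points.csv"
        path.write_text("id,x,y\nA,0,0\n")
        with pytest.raises(ValueError, match="missing column"):
            read_points(path)


class TestObservationsIO:
    def test_round_trip_identity(self, tmp_path, network):
        from phenokrig import PhenoDataset

        rng = np.random.default_rng(7)
        datasets = [
            PhenoDataset(
                date=dt.date(2004, 4, 23) + dt.timedelta(weeks=k),
                points=list(network[:7]),
                values=np.round(rng.uniform(0, 4, 7), 6),
            )
            for k in range(3)
        ]
        path = tmp_path / "obs.csv"
        write_observations(datasets, path)
        again = build_datasets(read_observations(path), network)
        assert len(again) == 3
        for a, b in zip(again, datasets):
            assert a.date == b.date
            assert [p.id for p in a.points] == [p.id for p in b.points]
            np.testing.assert_allclose(a.values, b.values, atol=1e-6)

    def test_out_of_range_phase_rejected(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text("point_id,date,phase\nA,2004-04-23,4.5\n")
        with pytest.raises(ValueError, match="row 2"):
            read_observations(path)

    def test_seven_rows_one_date(self, tmp_path, network):
        path = tmp_path / "obs.csv"
        rows = "\n".join(f"{p.id},2004-04-23,{i * 0.5}" for i, p in enumerate(network[:7]))
        path.write_text("point_id,date,phase\n" + rows + "\n")
        datasets = build_datasets(read_observations(path), network)
        assert len(datasets) == 1 and datasets[0].n == 7


class TestPollenSeries:
    def test_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            PollenSeries(dates=[dt.date(2004, 5, 2), dt.date(2004, 5, 1)], counts=[1, 2])
        with pytest.raises(ValueError, match=">= 0"):
            PollenSeries(dates=[dt.date(2004, 5, 1)], counts=[-1])


class TestAsciiGrid:
    def test_two_by_two(self, tmp_path):
        grid = PhenoGrid(xll=0, yll=0, cellsize=10, values=np.ones((2, 2)))
        path = tmp_path / "g.asc"
        write_ascii_grid(grid, path)
        text = path.read_text()
        assert "ncols 2" in text and "nrows 2" in text
        assert text.count("1 1") == 2

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 4, (5, 7))
        values[1, 2] = -9999.0
        grid = PhenoGrid(xll=343000.5, yll=4193000.25, cellsize=100, values=values)
        path = tmp_path / "g.asc"
        write_ascii_grid(grid, path)
        again = read_ascii_grid(path)
        assert (again.nrows, again.ncols) == (5, 7)
        assert again.cellsize == grid.cellsize
        np.testing.assert_allclose(again.values, grid.values, atol=1e-6)
        # NODATA cells survive as the declared sentinel
        np.testing.assert_array_equal(again.valid_mask(), grid.valid_mask())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            PhenoGrid(xll=0, yll=0, cellsize=10, values=np.empty((0, 0)))

    def test_value_at_addresses_north_up_cells(self):
        values = np.array([[1.0, 2.0], [3.0, 4.0]])  # row 0 = north
        grid = PhenoGrid(xll=0, yll=0, cellsize=10, values=values)
        assert grid.value_at(5, 5) == 3.0  # south-west cell
        assert grid.value_at(15, 15) == 2.0  # north-east cell
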