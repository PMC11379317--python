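"""Echo-integration grid: linear-domain averaging, alignment, round-trip I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tests.conftest import make_grid, make_pings
from zoosonde.echogram import (
    SvGrid,
    align_bifreq,
    db_to_linear,
    linear_to_db,
    read_survey,
    resample_to_cells,
    write_survey,
)


class TestResample:
    def test_constant_cell_preserved(self):
        g = make_grid(np.full((3, 4), -70.0))
        out = resample_to_cells(g, 3, 1.0, -80.0)
        assert np.allclose(linear_to_db(out.sv), -70.0)

    def test_mean_is_linear_domain(self):
        # -70 and -60 dB average to 10 log10((1e-7 + 1e-6)/2), not -65
        sv_db = np.array([[-70.0], [-60.0]])
        out = resample_to_cells(make_grid(sv_db), 2, 1.0, -80.0)
        expected = 10 * np.log10((1e-7 + 1e-6) / 2)
        assert linear_to_db(out.sv[0, 0]) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-62.596, abs=1e-3)

    def test_integration_threshold_drops_quiet_cells(self):
        out = resample_to_cells(make_grid(np.full((3, 2), -85.0)), 3, 1.0, -80.0)
        assert np.isnan(out.sv).all()

    def test_threshold_is_per_sample(self):
        # one loud sample among quiet ones: the cell keeps only the loud one
        sv_db = np.array([[-85.0], [-85.0], [-70.0]])
        out = resample_to_cells(make_grid(sv_db), 3, 1.0, -80.0)
        assert linear_to_db(out.sv[0, 0]) == pytest.approx(-70.0)

    def test_trailing_partial_cells_dropped(self):
        g = make_grid(np.full((7, 3), -70.0))
        out = resample_to_cells(g, 3, 1.0, -80.0)
        assert out.n_pings == 2  # 7 pings -> 2 full blocks

    def test_analysis_layer_clip(self):
        # bins from 0 m: everything above 10 m is outside the analysis layer
        g = make_grid(np.full((3, 30), -70.0), depth0=0.0)
        out = resample_to_cells(g, 3, 1.0, -80.0)
        assert out.depth_edges[0] == 10.0
        assert out.depth_edges[-1] == 30.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            resample_to_cells(make_grid(np.full((3, 2), -70.0)), 0, 1.0, -80.0)
        with pytest.raises(ValueError):
            resample_to_cells(make_grid(np.full((3, 2), -70.0)), 3, -1.0, -80.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            (6, 4),
            elements=st.floats(min_value=-79.0, max_value=-40.0),
        )
    )
    def test_cell_bounded_by_members(self, sv_db):
        """Linear averaging never leaves the [min, max] envelope in dB."""
        out = resample_to_cells(make_grid(sv_db), 3, 1.0, -80.0)
        cells = linear_to_db(out.sv)
        for b in range(2):
            block = sv_db[3 * b : 3 * b + 3]
            assert np.all(cells[b] >= block.min(axis=0) - 1e-9)
            assert np.all(cells[b] <= block.max(axis=0) + 1e-9)


class TestAlign:
    def _pair(self, m38, m120):
        return make_grid(np.asarray(m38, float), 38.0), make_grid(np.asarray(m120, float), 120.0)

    def test_sum_and_delta_definitions(self):
        g38, g120 = self._pair([[-80.0]], [[-70.0]])
        grid = align_bifreq(g38, g120)
        assert grid.sum_mvbs[0, 0] == pytest.approx(-150.0)
        assert grid.delta_mvbs[0, 0] == pytest.approx(10.0)

    def test_equal_channels_zero_delta(self):
        g38, g120 = self._pair([[-60.0]], [[-60.0]])
        grid = align_bifreq(g38, g120)
        assert grid.sum_mvbs[0, 0] == pytest.approx(-120.0)
        assert grid.delta_mvbs[0, 0] == pytest.approx(0.0)

    def test_missing_channel_excludes_cell(self):
        g38, g120 = self._pair([[-60.0, -60.0]], [[-60.0, np.nan]])
        grid = align_bifreq(g38, g120)
        assert not grid.excluded[0, 0]
        assert grid.excluded[0, 1]
        assert np.isnan(grid.mvbs38[0, 1])  # exclusion applies to both channels

    def test_lattice_mismatch_names_axis(self):
        g38 = make_grid(np.full((2, 3), -60.0), 38.0)
        g120 = make_grid(np.full((3, 3), -60.0), 120.0)
        with pytest.raises(ValueError, match="ping"):
            align_bifreq(g38, g120)
        g120b = make_grid(np.full((2, 4), -60.0), 120.0)
        with pytest.raises(ValueError, match="depth"):
            align_bifreq(g38, g120b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(float, (3, 4), elements=st.floats(-90, -50)),
        hnp.arrays(float, (3, 4), elements=st.floats(-90, -50)),
    )
    def test_channels_recoverable_from_sum_and_delta(self, m38, m120):
        grid = align_bifreq(make_grid(m38, 38.0), make_grid(m120, 120.0))
        np.testing.assert_allclose((grid.sum_mvbs - grid.delta_mvbs) / 2, grid.mvbs38)
        np.testing.assert_allclose((grid.sum_mvbs + grid.delta_mvbs) / 2, grid.mvbs120)


class TestRoundTrip:
    @pytest.fixture()
    def survey(self):
        rng = np.random.default_rng(42)
        m38 = rng.uniform(-95, -60, (10, 20))
        m120 = rng.uniform(-85, -50, (10, 20))
        m38[2, 5] = np.nan  # one EXCLUDED cell
        m120[7, 1] = np.nan
        return make_grid(m38, 38.0), make_grid(m120, 120.0)

    @pytest.mark.parametrize("dialect", ["csv", "netcdf"])
    def test_lossless_round_trip(self, survey, tmp_path, dialect):
        g38, g120 = survey
        path = tmp_path / f"survey.{dialect}"
        write_survey(g38, g120, path, dialect=dialect)
        r38, r120 = read_survey(path, dialect=dialect)
        for orig, back in ((g38, r38), (g120, r120)):
            assert np.array_equal(np.isnan(orig.sv), np.isnan(back.sv))
            good = np.isfinite(orig.sv)
            np.testing.assert_allclose(
                linear_to_db(back.sv[good]), linear_to_db(orig.sv[good]), atol=1e-9
            )
            np.testing.assert_allclose(back.depth_edges, orig.depth_edges)
        assert (r38.pings["time_utc"] == g38.pings["time_utc"]).all()

    def test_descending_depth_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "ping_index,time_utc,lat,lon,depth_m,sv38_db,sv120_db\n"
            "0,2014-03-10T12:00:00,14.5,-17.6,12,-70,-60\n"
            "0,2014-03-10T12:00:00,14.5,-17.6,11,-70,-60\n"
        )
        with pytest.raises(ValueError, match="depth"):
            read_survey(path)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "ping_index,time_utc,lat,lon,depth_m,sv38_db,sv120_db,bogus\n"
            "0,2014-03-10T12:00:00,14.5,-17.6,11,-70,-60,1\n"
        )
        with pytest.raises(ValueError, match="unknown"):
            read_survey(path)

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "ping_index,time_utc,lat,lon,depth_m,sv38_db,sv120_db\n"
            "0,2014-03-10T12:00:00,14.5,-17.6,11,-70,-60\n"
            "0,2014-03-10T12:00:00,14.5,-17.6,11,-71,-61\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_survey(path)


def test_sv_grid_invariants():
    with pytest.raises(ValueError, match="increasing"):
        SvGrid(38.0, np.ones((2, 2)), [12.0, 11.0, 10.0], make_pings(2))
    with pytest.raises(ValueError):
        SvGrid(38.0, -np.ones((2, 2)), [10.0, 11.0, 12.0], make_pings(2))
    pings = make_pings(2)
    pings.loc[1, "time_utc"] = pings.loc[0, "time_utc"] - np.timedelta64(1, "s")
    with pytest.raises(ValueError, match="time"):
        SvGrid(38.0, np.ones((2, 2)), [10.0, 11.0, 12.0], pings)
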