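import numpy as np
import pandas as pd
import pytest

from zoosonde.classify import classify_cells
from zoosonde.echogram import SvGrid, align_bifreq, resample_to_cells
from zoosonde.invert import grid_density, integrate_esu
from zoosonde.scattering import FluidSphereParams, SizeBand
from zoosonde.synthdata import SyntheticTruth, gen_survey


@pytest.fixture(scope="session")
def params() -> FluidSphereParams:
    """The survey's fluid-sphere constants: g=1.02, h=1.058, c=1508 m/s."""
    return FluidSphereParams()


@pytest.fixture(scope="session")
def band(params) -> SizeBand:
    return SizeBand.from_delta_bounds(params)


def make_pings(n, start="2014-03-10T12:00:00", lat0=14.5, lon0=-17.6, dlon=-5e-4,
               interval_s=2.0):
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "ping_index": np.arange(n),
            "time_utc": t0 + pd.to_timedelta(np.arange(n) * interval_s, unit="s"),
            "latitude": np.full(n, lat0),
            "longitude": lon0 + dlon * np.arange(n),
        }
    )


def make_grid(sv_db, freq=120.0, depth0=10.0, **kw):
    """SvGrid from a dB matrix (NaN = missing), 1 m bins from depth0."""
    sv_db = np.asarray(sv_db, dtype=float)
    sv = 10 ** (sv_db / 10.0)
    sv[~np.isfinite(sv_db)] = np.nan
    edges = depth0 + np.arange(sv_db.shape[1] + 1, dtype=float)
    return SvGrid(freq, sv, edges, make_pings(sv_db.shape[0], **kw))


def run_chain(truth: SyntheticTruth):
    """Generate a survey and run it through classification and inversion."""
    g38, g120, record = gen_survey(truth)
    c38 = resample_to_cells(g38, truth.pings_per_cell, 1.0, truth.integration_threshold_db)
    c120 = resample_to_cells(g120, truth.pings_per_cell, 1.0, truth.integration_threshold_db)
    grid = align_bifreq(c38, c120)
    mask = classify_cells(grid)
    density = grid_density(grid, mask, truth.params)
    esus = integrate_esu(density)
    return record, grid, mask, density, esus
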