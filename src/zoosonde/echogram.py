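"""Two-frequency echo-integration grids: data model, resampling, I/O.

Volume backscatter is carried in the linear domain (volume
backscattering coefficient sv, m^-1) with NaN as the missing flag;
MVBS = 10*log10(sv) is derived.  All averaging happens on linear sv,
all thresholds are expressed in dB — mixing the two is the classic
echo-integration bug this module exists to prevent.

Depth is positive down with half-open bins [top, bottom).  The analysis
layer is the epipelagic 10-200 m band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SvGrid",
    "BiFreqCellGrid",
    "db_to_linear",
    "linear_to_db",
    "resample_to_cells",
    "align_bifreq",
    "read_survey",
    "write_survey",
    "DEPTH_MIN_M",
    "DEPTH_MAX_M",
]

DEPTH_MIN_M = 10.0
DEPTH_MAX_M = 200.0

PING_COLUMNS = ["ping_index", "time_utc", "latitude", "longitude"]
CSV_COLUMNS = ["ping_index", "time_utc", "lat", "lon", "depth_m", "sv38_db", "sv120_db"]


def db_to_linear(db):
    return 10.0 ** (np.asarray(db, dtype=float) / 10.0)


def linear_to_db(linear):
    with np.errstate(divide="ignore", invalid="ignore"):
        return 10.0 * np.log10(np.asarray(linear, dtype=float))


def _validate_pings(pings: pd.DataFrame) -> pd.DataFrame:
    missing = set(PING_COLUMNS) - set(pings.columns)
    if missing:
        raise ValueError(f"ping table missing columns: {sorted(missing)}")
    pings = pings.reset_index(drop=True)
    t = pd.to_datetime(pings["time_utc"])
    if len(t) > 1 and not t.is_monotonic_increasing:
        raise ValueError("ping times must increase with ping_index")
    if (pings["latitude"].abs() > 90).any() or (pings["longitude"].abs() > 180).any():
        raise ValueError("latitude/longitude out of range")
    return pings.assign(time_utc=t)


@dataclass
class SvGrid:
    """A (ping, depth-bin) lattice of linear sv at one frequency.

    sv : 2D float array, shape (n_pings, n_bins); NaN = missing.
    depth_edges : 1D array of n_bins+1 strictly increasing edges, m.
    pings : DataFrame with ping_index, time_utc, latitude, longitude.
    """

    frequency_khz: float
    sv: np.ndarray
    depth_edges: np.ndarray
    pings: pd.DataFrame

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv, dtype=float)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        if self.sv.ndim != 2:
            raise ValueError("sv must be 2-D (ping, depth)")
        if np.any(np.diff(self.depth_edges) <= 0):
            raise ValueError("depth_edges must be strictly increasing")
        if self.sv.shape[1] != self.depth_edges.size - 1:
            raise ValueError("sv depth dimension does not match depth_edges")
        self.pings = _validate_pings(self.pings)
        if self.sv.shape[0] != len(self.pings):
            raise ValueError("sv ping dimension does not match ping table")
        finite = self.sv[np.isfinite(self.sv)]
        if np.any(finite < 0):
            raise ValueError("linear sv must be >= 0 or missing")

    @property
    def n_pings(self) -> int:
        return self.sv.shape[0]

    @property
    def n_bins(self) -> int:
        return self.sv.shape[1]

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    @property
    def mvbs(self) -> np.ndarray:
        """MVBS in dB re 1 m^-1; -inf/NaN where sv is 0/missing."""
        return linear_to_db(self.sv)


@dataclass
class BiFreqCellGrid:
    """Co-registered 38/120 kHz MVBS cells with dB sum and difference.

    mvbs38/mvbs120 are dB with NaN wherever a cell is EXCLUDED (missing
    in either channel); sum/delta are derived, never stored out of sync.
    """

    mvbs38: np.ndarray
    mvbs120: np.ndarray
    depth_edges: np.ndarray
    pings: pd.DataFrame

    def __post_init__(self) -> None:
        self.mvbs38 = np.asarray(self.mvbs38, dtype=float)
        self.mvbs120 = np.asarray(self.mvbs120, dtype=float)
        if self.mvbs38.shape != self.mvbs120.shape:
            raise ValueError("channel shapes differ")
        # a cell is either complete or excluded in both channels
        excl = ~np.isfinite(self.mvbs38) | ~np.isfinite(self.mvbs120)
        self.mvbs38 = np.where(excl, np.nan, self.mvbs38)
        self.mvbs120 = np.where(excl, np.nan, self.mvbs120)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        self.pings = _validate_pings(self.pings)

    @property
    def excluded(self) -> np.ndarray:
        return ~np.isfinite(self.mvbs38)

    @property
    def sum_mvbs(self) -> np.ndarray:
        return self.mvbs120 + self.mvbs38

    @property
    def delta_mvbs(self) -> np.ndarray:
        return self.mvbs120 - self.mvbs38

    @property
    def shape(self) -> tuple[int, int]:
        return self.mvbs38.shape

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    @property
    def bin_heights(self) -> np.ndarray:
        return np.diff(self.depth_edges)


def resample_to_cells(
    grid: SvGrid,
    pings_per_cell: int = 3,
    meters_per_cell: float = 1.0,
    lower_threshold_db: float = -80.0,
    depth_min_m: float = DEPTH_MIN_M,
    depth_max_m: float = DEPTH_MAX_M,
) -> SvGrid:
    """Echo-integrate raw sv into analysis cells.

    Cells are ``pings_per_cell`` pings wide and ``meters_per_cell`` tall,
    anchored at the first ping and at ``depth_min_m``.  The integration
    threshold is applied per raw sample in dB; a cell is the arithmetic
    mean of its qualifying samples in the linear domain, and missing if
    none qualify.  Trailing partial cells are dropped, not padded.
    """
    if pings_per_cell < 1:
        raise ValueError("pings_per_cell must be >= 1")
    if meters_per_cell <= 0:
        raise ValueError("meters_per_cell must be positive")
    if grid.n_pings == 0 or grid.n_bins == 0:
        raise ValueError("empty grid")

    n_blocks = grid.n_pings // pings_per_cell
    if n_blocks == 0:
        raise ValueError("fewer pings than one cell")

    top = max(depth_min_m, grid.depth_edges[0])
    bottom = min(depth_max_m, grid.depth_edges[-1])
    n_cells_z = int(np.floor((bottom - top) / meters_per_cell + 1e-9))
    if n_cells_z == 0:
        raise ValueError("no full depth cell inside the analysis layer")
    cell_edges = top + meters_per_cell * np.arange(n_cells_z + 1)

    sv = np.where(
        linear_to_db(np.where(grid.sv > 0, grid.sv, np.nan)) >= lower_threshold_db,
        grid.sv,
        np.nan,
    )

    centers = grid.depth_centers
    out = np.full((n_blocks, n_cells_z), np.nan)
    zi = np.searchsorted(cell_edges, centers, side="right") - 1
    in_layer = (zi >= 0) & (zi < n_cells_z) & (centers >= top) & (centers < cell_edges[-1])
    for b in range(n_blocks):
        rows = sv[b * pings_per_cell : (b + 1) * pings_per_cell]
        for z in range(n_cells_z):
            members = rows[:, in_layer & (zi == z)]
            vals = members[np.isfinite(members)]
            if vals.size:
                out[b, z] = vals.mean()

    blocks = grid.pings.iloc[: n_blocks * pings_per_cell]
    grp = blocks.groupby(np.arange(len(blocks)) // pings_per_cell)
    cell_pings = pd.DataFrame(
        {
            "ping_index": np.arange(n_blocks),
            "time_utc": grp["time_utc"].apply(lambda s: s.iloc[len(s) // 2]),
            "latitude": grp["latitude"].mean(),
            "longitude": grp["longitude"].mean(),
        }
    )
    return SvGrid(grid.frequency_khz, out, cell_edges, cell_pings)


def align_bifreq(grid38: SvGrid, grid120: SvGrid) -> BiFreqCellGrid:
    """Join the two channels on an identical cell lattice.

    Cells missing in either channel become EXCLUDED.
    """
    if grid38.sv.shape[0] != grid120.sv.shape[0]:
        raise ValueError("lattice mismatch on axis 'ping'")
    if grid38.depth_edges.size != grid120.depth_edges.size or not np.allclose(
        grid38.depth_edges, grid120.depth_edges
    ):
        raise ValueError("lattice mismatch on axis 'depth'")
    m38 = linear_to_db(np.where(grid38.sv > 0, grid38.sv, np.nan))
    m120 = linear_to_db(np.where(grid120.sv > 0, grid120.sv, np.nan))
    return BiFreqCellGrid(m38, m120, grid38.depth_edges.copy(), grid38.pings.copy())


# ---------------------------------------------------------------------------
# I/O


def _grids_to_frame(grid38: SvGrid, grid120: SvGrid) -> pd.DataFrame:
    tops = grid38.depth_edges[:-1]
    recs = []
    for i, ping in grid38.pings.iterrows():
        for j, top in enumerate(tops):
            recs.append(
                (
                    int(ping["ping_index"]),
                    ping["time_utc"].isoformat(),
                    ping["latitude"],
                    ping["longitude"],
                    top,
                    grid38.sv[i, j],
                    grid120.sv[i, j],
                )
            )
    df = pd.DataFrame(recs, columns=CSV_COLUMNS)
    df["sv38_db"] = linear_to_db(np.where(df["sv38_db"] > 0, df["sv38_db"], np.nan))
    df["sv120_db"] = linear_to_db(np.where(df["sv120_db"] > 0, df["sv120_db"], np.nan))
    return df


def write_survey(grid38: SvGrid, grid120: SvGrid, path, dialect: str = "csv") -> None:
    """Serialize a 38/120 kHz grid pair; dialect 'csv' (long) or 'netcdf'."""
    if dialect == "csv":
        _grids_to_frame(grid38, grid120).to_csv(path, index=False, float_format="%.10f")
    elif dialect == "netcdf":
        import xarray as xr

        ds = xr.Dataset(
            {
                "sv38": (("ping", "depth"), grid38.sv),
                "sv120": (("ping", "depth"), grid120.sv),
            },
            coords={
                "ping": grid38.pings["ping_index"].to_numpy(),
                "depth": grid38.depth_centers,
                "depth_edges": ("depth_edge", grid38.depth_edges),
                "time_utc": ("ping", grid38.pings["time_utc"].astype("datetime64[ns]").to_numpy()),
                "latitude": ("ping", grid38.pings["latitude"].to_numpy()),
                "longitude": ("ping", grid38.pings["longitude"].to_numpy()),
            },
            attrs={
                "convention": "sv linear m-1, NaN missing, depth positive down",
                "units": "m-1",
                "frequencies_khz": f"{grid38.frequency_khz},{grid120.frequency_khz}",
            },
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_survey(path, dialect: str = "csv") -> tuple[SvGrid, SvGrid]:
    """Read a survey written by :func:`write_survey` (or hand-built CSV)."""
    if dialect == "csv":
        df = pd.read_csv(path)
        unknown = set(df.columns) - set(CSV_COLUMNS)
        if unknown:
            raise ValueError(f"unknown columns: {sorted(unknown)}")
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if df.duplicated(["ping_index", "depth_m"]).any():
            raise ValueError("duplicate (ping, depth) keys")
        pings = (
            df.groupby("ping_index", sort=True)
            .agg(time_utc=("time_utc", "first"), latitude=("lat", "first"), longitude=("lon", "first"))
            .reset_index()
        )
        tops = np.array(sorted(df["depth_m"].unique()))
        for _, sub in df.groupby("ping_index"):
            d = sub["depth_m"].to_numpy()
            if np.any(np.diff(d) <= 0):
                raise ValueError("depth column must be strictly increasing within a ping")
        if tops.size > 1:
            steps = np.diff(tops)
            edges = np.append(tops, tops[-1] + steps[-1])
        else:
            edges = np.array([tops[0], tops[0] + 1.0])
        pivot38 = df.pivot(index="ping_index", columns="depth_m", values="sv38_db")
        pivot120 = df.pivot(index="ping_index", columns="depth_m", values="sv120_db")
        sv38 = db_to_linear(pivot38.to_numpy())
        sv120 = db_to_linear(pivot120.to_numpy())
        sv38[~np.isfinite(sv38)] = np.nan
        sv120[~np.isfinite(sv120)] = np.nan
        return (
            SvGrid(38.0, sv38, edges, pings),
            SvGrid(120.0, sv120, edges, pings.copy()),
        )
    elif dialect == "netcdf":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        f38, f120 = (float(x) for x in ds.attrs["frequencies_khz"].split(","))
        pings = pd.DataFrame(
            {
                "ping_index": ds["ping"].to_numpy(),
                "time_utc": pd.to_datetime(ds["time_utc"].to_numpy()),
                "latitude": ds["latitude"].to_numpy(),
                "longitude": ds["longitude"].to_numpy(),
            }
        )
        edges = ds["depth_edges"].to_numpy()
        return (
            SvGrid(f38, ds["sv38"].to_numpy(), edges, pings),
            SvGrid(f120, ds["sv120"].to_numpy(), edges, pings.copy()),
        )
    raise ValueError(f"unknown dialect {dialect!r}")
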