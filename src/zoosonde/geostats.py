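"""Spatial statistics for biomass mapping.

Empirical (Matheron) variogram on great-circle distances, weighted
least-squares fit of a spherical/exponential model, ordinary kriging of
areal biomass onto a 0.05 degree lattice, aggregation to a total-biomass
figure with an approximate CV, and Moran's I as an autocorrelation
screen.

Kriging solves, per grid node, the standard ordinary-kriging system in
semivariogram form with the unbiasedness (weights-sum-to-one)
constraint, using the 16 nearest observations.  With a zero nugget the
predictor is exact at data locations.  The CV of the total treats the
per-cell kriging variances as independent — an approximation that
understates covariance between neighbouring cells and is documented as
such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "VariogramModel",
    "KrigedField",
    "empirical_variogram",
    "fit_variogram",
    "ordinary_krige",
    "krige_at",
    "total_biomass",
    "morans_i",
    "great_circle_km",
]

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine distance in km; accepts scalars or arrays."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    h = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic variogram: gamma(h) = nugget + psill * f(h/range)."""

    model: str = "spherical"        # or "exponential"
    nugget: float = 0.0
    psill: float = 1.0
    range_km: float = 10.0
    flagged_flat: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("spherical", "exponential"):
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.psill <= 0 or self.range_km <= 0:
            raise ValueError("variogram parameters must be non-negative (psill, range > 0)")

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        if self.model == "spherical":
            r = np.clip(h / self.range_km, 0.0, 1.0)
            structural = self.psill * (1.5 * r - 0.5 * r**3)
        else:
            structural = self.psill * (1.0 - np.exp(-3.0 * h / self.range_km))
        return np.where(h > 0, self.nugget + structural, 0.0)


def empirical_variogram(
    points: pd.DataFrame, n_bins: int = 12, max_dist_km: float | None = None
) -> pd.DataFrame:
    """Matheron estimator gamma(h) = mean(0.5*(z_i - z_j)^2) per distance bin.

    ``points`` needs columns lon, lat, value.  Returns a frame with bin
    centre distance, semivariance and pair count (empty bins dropped).
    """
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    z = points["value"].to_numpy(dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 points")
    i, j = np.triu_indices(n, k=1)
    d = great_circle_km(lon[i], lat[i], lon[j], lat[j])
    if np.all(d == 0):
        raise ValueError("all points coincident")
    if max_dist_km is None:
        max_dist_km = 0.5 * d.max()
    keep = (d > 0) & (d <= max_dist_km)
    d, sq = d[keep], 0.5 * (z[i[keep]] - z[j[keep]]) ** 2
    edges = np.linspace(0.0, max_dist_km, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        rows.append(
            {
                "dist_km": float(d[m].mean()),
                "semivariance": float(sq[m].mean()),
                "n_pairs": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)


def fit_variogram(empirical: pd.DataFrame, model: str = "spherical") -> VariogramModel:
    """Weighted least squares (weights = n_pairs / h^2) fit of the model.

    A structureless (flat) empirical variogram collapses the range to
    its lower bound and is flagged rather than rejected.
    """
    if len(empirical) < 4:
        raise ValueError("need at least 4 non-empty bins")
    h = empirical["dist_km"].to_numpy(dtype=float)
    g = empirical["semivariance"].to_numpy(dtype=float)
    npairs = empirical["n_pairs"].to_numpy(dtype=float)
    if np.any(g < 0) or np.any(h < 0):
        raise ValueError("negative distances or semivariances")
    w = np.sqrt(npairs) / np.maximum(h, h[h > 0].min() if np.any(h > 0) else 1.0)

    sill0 = max(g.mean(), 1e-12)
    range0 = h.max() / 2.0
    lo = [0.0, 1e-12 * sill0, h.max() * 1e-3]
    hi = [g.max() * 2 + 1e-12, g.max() * 4 + 1e-9, h.max() * 10]

    def resid(theta):
        nug, ps, rng = theta
        vgm = VariogramModel(model, nug, max(ps, 1e-300), rng)
        return w * (vgm(h) - g)

    sol = least_squares(resid, x0=[0.0 + 1e-9, sill0, range0], bounds=(lo, hi))
    if not sol.success:
        raise RuntimeError(f"variogram fit did not converge: {sol.message}")
    nug, ps, rng = sol.x
    # a range inside the first distance bin is sub-resolution structure:
    # indistinguishable from pure nugget, i.e. a flat variogram
    flat = rng <= h.min() * 1.001 or ps < 1e-6 * (nug + ps)
    return VariogramModel(model, float(nug), float(max(ps, 1e-12)), float(rng), flagged_flat=bool(flat))


@dataclass
class KrigedField:
    """Ordinary-kriging predictions on a regular lon/lat lattice."""

    lon: np.ndarray            # node centres, 1-D (flattened grid)
    lat: np.ndarray
    prediction: np.ndarray     # biomass, mg m^-2
    variance: np.ndarray       # kriging variance, (mg m^-2)^2
    area_m2: np.ndarray        # cell area, varies with cos(latitude)
    weight_sums: np.ndarray    # sum of kriging weights per node (== 1)
    negative_weight_nodes: int # diagnostics: nodes with any negative weight

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lon": self.lon,
                "lat": self.lat,
                "B_mg_m2": self.prediction,
                "kriging_variance": self.variance,
                "area_m2": self.area_m2,
            }
        )


def _krige_solve(lon, lat, z, vgm, t_lon, t_lat, n_neighbors=16):
    """Solve the OK system at each target; returns pred, var, wsum, neg count."""
    n = len(z)
    k = min(n_neighbors, n)
    pred = np.empty(len(t_lon))
    var = np.empty(len(t_lon))
    wsum = np.empty(len(t_lon))
    n_neg = 0
    for t in range(len(t_lon)):
        d0_all = great_circle_km(lon, lat, t_lon[t], t_lat[t])
        idx = np.argsort(d0_all)[:k]
        sl_lon, sl_lat, sl_z = lon[idx], lat[idx], z[idx]
        d0 = d0_all[idx]
        dmat = great_circle_km(
            sl_lon[:, None], sl_lat[:, None], sl_lon[None, :], sl_lat[None, :]
        )
        gamma = vgm(dmat)
        a = np.empty((k + 1, k + 1))
        a[:k, :k] = gamma
        a[k, :k] = 1.0
        a[:k, k] = 1.0
        a[k, k] = 0.0
        b = np.empty(k + 1)
        b[:k] = vgm(d0)
        b[k] = 1.0
        try:
            sol = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            a[:k, :k] += np.eye(k) * max(vgm.psill, 1.0) * 1e-9  # jitter retry once
            sol = np.linalg.solve(a, b)
        lam, mu = sol[:k], sol[k]
        if np.any(lam < -1e-9):
            n_neg += 1
        pred[t] = lam @ sl_z
        var[t] = max(lam @ b[:k] + mu, 0.0)
        wsum[t] = lam.sum()
    return pred, var, wsum, n_neg


def krige_at(points: pd.DataFrame, vgm: VariogramModel, t_lon, t_lat, n_neighbors: int = 16):
    """Kriging prediction and variance at arbitrary target locations."""
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    z = points["value"].to_numpy(dtype=float)
    if len(z) < 1:
        raise ValueError("no data points")
    t_lon = np.atleast_1d(np.asarray(t_lon, dtype=float))
    t_lat = np.atleast_1d(np.asarray(t_lat, dtype=float))
    pred, var, wsum, _ = _krige_solve(lon, lat, z, vgm, t_lon, t_lat, n_neighbors)
    return pred, var


def _cell_area_m2(lat_deg, step_deg):
    r = EARTH_RADIUS_KM * 1e3
    rad = np.pi / 180.0
    return (step_deg * rad * r) ** 2 * np.cos(np.radians(lat_deg))


def ordinary_krige(
    points: pd.DataFrame,
    vgm: VariogramModel,
    grid_step_deg: float = 0.05,
    n_neighbors: int = 16,
    clip_to_hull: bool = True,
) -> KrigedField:
    """Krige point values onto a regular ``grid_step_deg`` lattice.

    Nodes outside the convex hull of the data are dropped when
    ``clip_to_hull`` (extrapolation beyond the survey polygon is not
    meaningful); with near-collinear data the hull clip degrades to the
    bounding box.
    """
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    z = points["value"].to_numpy(dtype=float)
    n = len(z)
    if n < 5 and n != 1:
        raise ValueError("need at least 5 points (or exactly 1 for a constant field)")

    gx = np.arange(lon.min(), lon.max() + grid_step_deg, grid_step_deg)
    gy = np.arange(lat.min(), lat.max() + grid_step_deg, grid_step_deg)
    if gx.size == 0 or gy.size == 0:
        gx, gy = np.array([lon.mean()]), np.array([lat.mean()])
    mx, my = np.meshgrid(gx, gy)
    t_lon, t_lat = mx.ravel(), my.ravel()

    if clip_to_hull and n >= 3:
        try:
            from scipy.spatial import Delaunay

            tri = Delaunay(np.column_stack([lon, lat]))
            inside = tri.find_simplex(np.column_stack([t_lon, t_lat])) >= 0
            if inside.any():
                t_lon, t_lat = t_lon[inside], t_lat[inside]
        except Exception:
            pass  # degenerate geometry: keep the bounding box

    pred, var, wsum, n_neg = _krige_solve(lon, lat, z, vgm, t_lon, t_lat, n_neighbors)
    return KrigedField(
        lon=t_lon,
        lat=t_lat,
        prediction=pred,
        variance=var,
        area_m2=_cell_area_m2(t_lat, grid_step_deg),
        weight_sums=wsum,
        negative_weight_nodes=n_neg,
    )


def total_biomass(field: KrigedField) -> dict:
    """Aggregate a kriged biomass field to total tons and an approximate CV.

    B_t = sum(B_i * A_i) with mg -> tons; negative predictions are
    clipped to zero (count reported).  CV treats cell kriging variances
    as independent: CV = sqrt(sum(var_i * A_i^2)) / B_t * 100.
    """
    pred = field.prediction.copy()
    n_clipped = int((pred < 0).sum())
    pred[pred < 0] = 0.0
    bt_mg = float(np.sum(pred * field.area_m2))
    bt_tons = bt_mg * 1e-9
    if bt_mg > 0:
        cv = float(np.sqrt(np.sum(field.variance * field.area_m2**2)) / bt_mg * 100.0)
    else:
        cv = float("nan")
    return {"B_t_tons": bt_tons, "cv_percent": cv, "n_clipped": n_clipped}


def morans_i(values, coords=None, weights=None) -> float:
    """Global Moran's I.

    ``weights`` may be an explicit (n, n) matrix (e.g. rook adjacency);
    otherwise inverse great-circle-distance weights are built from
    ``coords`` (lon, lat pairs).  Rows are standardised to sum to one;
    the diagonal is zero.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 locations")
    dev = z - z.mean()
    if np.allclose(dev, 0):
        raise ValueError("constant values: Moran's I undefined")
    if weights is None:
        if coords is None:
            raise ValueError("need coords or an explicit weight matrix")
        c = np.asarray(coords, dtype=float)
        d = great_circle_km(c[:, None, 0], c[:, None, 1], c[None, :, 0], c[None, :, 1])
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
        w[~np.isfinite(w)] = 0.0
    else:
        w = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    w = w / rs
    s0 = w.sum()
    return float(n / s0 * (dev @ w @ dev) / (dev @ dev))
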