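"""ZooScan measurement tables and net-sample summaries.

Scanned object areas (pixels) convert to mm^2 at 0.0106 mm/pixel, to an
area-equivalent spherical radius ESR = sqrt(S/pi), and to dry mass via
the allometry DM = a * S^b.  The allometric coefficients are *not*
universal constants: the defaults (a = 45.25 ug, b = 1.59) are
literature values for subtropical mesozooplankton and are mandatory,
documented configuration — any biomass number inherits them.

Station summaries deliver per-stratum abundance (ind m^-3), biomass
(ug m^-3) and the mean individual dry mass DM_m that scales the
acoustic biomass estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PIXEL_MM",
    "AllometricModel",
    "NetStation",
    "px_to_mm2",
    "esr_from_area",
    "dry_mass",
    "station_summary",
    "spearman_compare",
    "ZOOSCAN_COLUMNS",
]

PIXEL_MM = 0.0106

ZOOSCAN_COLUMNS = [
    "station",
    "net",
    "stratum_top_m",
    "stratum_bottom_m",
    "taxon",
    "area_px",
    "split_factor",
]


@dataclass(frozen=True)
class AllometricModel:
    """DM = dm_intercept * S^dm_exponent, with S in mm^2 and DM in ug."""

    dm_intercept: float = 45.25
    dm_exponent: float = 1.59

    def __post_init__(self) -> None:
        if self.dm_intercept <= 0 or self.dm_exponent <= 0:
            raise ValueError("allometric coefficients must be positive")


@dataclass(frozen=True)
class NetStation:
    """Net-station metadata; per-net filtered volumes in m^3."""

    station: str
    latitude: float
    longitude: float
    time_utc: pd.Timestamp
    volumes_m3: dict  # (stratum_top_m, stratum_bottom_m) -> filtered volume
    mouth_area_m2: float = 0.25

    def volume(self, stratum: tuple[float, float]) -> float:
        try:
            v = self.volumes_m3[stratum]
        except KeyError:
            raise ValueError(f"no filtered volume recorded for stratum {stratum}") from None
        if v <= 0:
            raise ValueError(f"non-positive filtered volume for stratum {stratum}")
        return v

    @classmethod
    def from_wire_distance(cls, station, latitude, longitude, time_utc, strata,
                           mouth_area_m2: float = 0.25):
        """Fallback when no flowmeter reading exists: volume = mouth area x wire distance."""
        vols = {(t, b): mouth_area_m2 * (b - t) for t, b in strata}
        return cls(station, latitude, longitude, pd.Timestamp(time_utc), vols, mouth_area_m2)


def px_to_mm2(area_px) -> float | np.ndarray:
    """Object area from pixels to mm^2 (pixel pitch 0.0106 mm)."""
    a = np.asarray(area_px, dtype=float)
    if np.any(a <= 0):
        raise ValueError("pixel area must be positive")
    out = a * PIXEL_MM * PIXEL_MM
    return float(out) if np.isscalar(area_px) else out


def esr_from_area(area_mm2) -> float | np.ndarray:
    """Area-equivalent circle radius, mm: ESR = sqrt(S/pi)."""
    s = np.asarray(area_mm2, dtype=float)
    if np.any(s <= 0):
        raise ValueError("area must be positive")
    out = np.sqrt(s / math.pi)
    return float(out) if np.isscalar(area_mm2) else out


def dry_mass(area_mm2, model: AllometricModel | None = None) -> float | np.ndarray:
    """Individual dry mass in ug from scanned body area."""
    model = model or AllometricModel()
    s = np.asarray(area_mm2, dtype=float)
    if np.any(s <= 0):
        raise ValueError("area must be positive")
    out = model.dm_intercept * s**model.dm_exponent
    return float(out) if np.isscalar(area_mm2) else out


def station_summary(
    items: pd.DataFrame,
    station: NetStation,
    esr_min_mm: float = 0.5,
    model: AllometricModel | None = None,
    taxa: list[str] | None = None,
) -> dict:
    """Per-stratum abundance/biomass and the mean individual dry mass.

    ``items`` is an EcoTaxa-export-like flat table (see ZOOSCAN_COLUMNS);
    ``split_factor`` multiplies each scanned object into the individuals
    it represents after Motoda splitting.  Organisms at or below
    ``esr_min_mm`` ESR are excluded before any aggregation.
    """
    model = model or AllometricModel()
    missing = set(ZOOSCAN_COLUMNS) - set(items.columns)
    if missing:
        raise ValueError(f"zooscan table missing columns: {sorted(missing)}")
    df = items[items["station"] == station.station].copy()
    if taxa is not None:
        df = df[df["taxon"].isin(taxa)]
    df["area_mm2"] = px_to_mm2(df["area_px"].to_numpy())
    df["esr_mm"] = esr_from_area(df["area_mm2"].to_numpy())
    df = df[df["esr_mm"] > esr_min_mm]
    df["dm_ug"] = dry_mass(df["area_mm2"].to_numpy(), model)

    strata: dict[tuple[float, float], dict] = {}
    for (top, bot), sub in df.groupby(["stratum_top_m", "stratum_bottom_m"]):
        vol = station.volume((top, bot))
        count = float(sub["split_factor"].sum())
        dm_total = float((sub["dm_ug"] * sub["split_factor"]).sum())
        strata[(float(top), float(bot))] = {
            "abundance_ind_m3": count / vol,
            "biomass_ug_m3": dm_total / vol,
            "count": count,
        }
    total_count = float(df["split_factor"].sum())
    total_dm = float((df["dm_ug"] * df["split_factor"]).sum())
    return {
        "strata": strata,
        "mean_dm_ug": total_dm / total_count if total_count > 0 else float("nan"),
        "n_items": int(len(df)),
    }


def spearman_compare(paired) -> dict:
    """Spearman rank correlation of paired acoustic/net values.

    Mid-rank ties; two-sided p from the t-approximation
    t = rho*sqrt((n-2)/(1-rho^2)).
    """
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("paired must be an (n, 2) array-like")
    if arr.shape[0] < 5:
        raise ValueError("need at least 5 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "n": int(arr.shape[0])}
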