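"""Solar altitude and diel labelling.

Zooplankton migrate vertically at dawn and dusk, so along-track records
taken during the light transition mix day and night population states.
Records with solar altitude in the open band (-18, +18) degrees
(astronomical twilight through low sun) are labelled ``transition`` and
dropped from day/night contrasts; altitude >= +18 is ``day``, <= -18 is
``night``.

The altitude comes from the NOAA low-accuracy solar position algorithm
(geometric, no atmospheric refraction), good to a few tenths of a
degree for 1990-2040 — far tighter than the +/-18 degree band needs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["solar_altitude", "diel_label", "diel_aggregate", "TRANSITION_BAND_DEG"]

TRANSITION_BAND_DEG = 18.0


def _julian_day(ts: pd.Timestamp) -> float:
    y, m = ts.year, ts.month
    d = ts.day + (ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9) / 24.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def solar_altitude(time_utc, latitude_deg: float, longitude_deg: float) -> float:
    """Geometric solar altitude in degrees at a UTC instant and position."""
    ts = pd.Timestamp(time_utc)
    if ts is pd.NaT:
        raise ValueError("invalid timestamp")
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    if not (abs(latitude_deg) <= 90 and abs(longitude_deg) <= 180):
        raise ValueError("coordinates out of range")

    jd = _julian_day(ts)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000

    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    obliq0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = obliq0 + 0.00256 * math.cos(math.radians(omega))

    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )

    vary = math.tan(math.radians(obliq / 2.0)) ** 2
    l0r, mr = math.radians(l0), mrad
    eq_time_min = 4.0 * math.degrees(
        vary * math.sin(2 * l0r)
        - 2 * e * math.sin(mr)
        + 4 * e * vary * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * vary * vary * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mr)
    )

    minutes = ts.hour * 60.0 + ts.minute + ts.second / 60.0 + ts.microsecond / 6e7
    true_solar_min = (minutes + eq_time_min + 4.0 * longitude_deg) % 1440.0
    hour_angle = true_solar_min / 4.0 - 180.0
    if hour_angle < -180.0:
        hour_angle += 360.0

    latr, declr, har = map(math.radians, (latitude_deg, decl, hour_angle))
    cos_zenith = math.sin(latr) * math.sin(declr) + math.cos(latr) * math.cos(declr) * math.cos(har)
    cos_zenith = min(1.0, max(-1.0, cos_zenith))
    return 90.0 - math.degrees(math.acos(cos_zenith))


def diel_label(altitude_deg: float) -> str:
    """'day' (>= +18), 'night' (<= -18) or 'transition' (open band)."""
    if not np.isfinite(altitude_deg):
        raise ValueError("altitude must be finite")
    if altitude_deg >= TRANSITION_BAND_DEG:
        return "day"
    if altitude_deg <= -TRANSITION_BAND_DEG:
        return "night"
    return "transition"


def label_esus(esus: pd.DataFrame) -> pd.DataFrame:
    """Attach solar altitude and diel label columns to an ESU table."""
    alts = [
        solar_altitude(row.time_utc, row.latitude, row.longitude)
        for row in esus.itertuples()
    ]
    out = esus.copy()
    out["solar_altitude_deg"] = alts
    out["diel"] = [diel_label(a) for a in alts]
    return out


def diel_aggregate(esus: pd.DataFrame, value_col: str = "B_mg_m2") -> dict:
    """Day/night summaries of ESU biomass, transitions excluded.

    Returns per-period mean, SD, median, quartiles and count; a period
    with no ESUs is flagged empty.
    """
    if "diel" not in esus.columns:
        esus = label_esus(esus)
    out = {}
    for period in ("day", "night"):
        vals = esus.loc[esus["diel"] == period, value_col].to_numpy(dtype=float)
        if vals.size == 0:
            out[period] = {"empty": True, "n": 0}
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[period] = {
            "empty": False,
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
        }
    return out
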