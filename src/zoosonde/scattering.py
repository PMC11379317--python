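"""High-pass fluid-sphere scattering model for fluid-like zooplankton.

The model treats a copepod as a weakly scattering fluid sphere of
equivalent spherical radius (ESR) ``a`` with density contrast ``g`` and
sound-speed contrast ``h`` relative to seawater.  Its backscattering
cross-section

    sigma_bs = a^2 (ka)^4 alpha_pis^2 / (1 + 4 (ka)^4 alpha_pis^2 / R^2)

interpolates between Rayleigh scattering (sigma_bs ~ a^2 (ka)^4
alpha_pis^2 for ka << 1) and a geometric plateau (a^2 R^2 / 4 for
ka >> 1), where R = (gh - 1)/(gh + 1) is the plane-interface reflection
coefficient and alpha_pis combines the compressibility and density
contrasts.

Because the cross-section rolls off earlier at 38 kHz than at 120 kHz,
the target-strength difference dTS = TS(120) - TS(38) decreases
monotonically with size from the Rayleigh ceiling 40*log10(120/38)
= 19.98 dB, which makes dTS (measured acoustically as dMVBS) invertible
to an equivalent spherical radius over a bounded size band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FluidSphereParams",
    "SizeBand",
    "sound_speed",
    "reflection_coefficient",
    "alpha_pis",
    "sigma_bs",
    "target_strength",
    "delta_ts",
    "ka",
    "invert_size",
    "InvertedSize",
]


@dataclass(frozen=True)
class FluidSphereParams:
    """Physical constants of the fluid-sphere model.

    g, h : density and sound-speed contrasts of the animal body relative
        to seawater (dimensionless, near 1 for fluid-like plankton).
    c : seawater sound speed, m/s.
    f_low_khz, f_high_khz : the two echosounder frequencies, kHz.
    """

    g: float = 1.02
    h: float = 1.058
    c: float = 1508.0
    f_low_khz: float = 38.0
    f_high_khz: float = 120.0

    def __post_init__(self) -> None:
        if not (self.g > 0 and self.h > 0):
            raise ValueError("contrasts g and h must be positive")
        if not (0.9 < self.g < 1.2 and 0.9 < self.h < 1.2):
            raise ValueError(
                "g and h outside (0.9, 1.2): not fluid-like plankton contrasts"
            )
        if not (1400.0 < self.c < 1600.0):
            raise ValueError("sound speed outside plausible seawater range")
        if not (self.f_high_khz > self.f_low_khz > 0):
            raise ValueError("need f_high > f_low > 0")

    @property
    def f_geometric_khz(self) -> float:
        """Geometric-mean frequency, used for the ka axis."""
        return math.sqrt(self.f_low_khz * self.f_high_khz)

    def wavenumber(self, f_khz: float) -> float:
        """Acoustic wavenumber k = 2*pi*f/c in rad/m."""
        return 2.0 * math.pi * f_khz * 1e3 / self.c


# ---------------------------------------------------------------------------
# sound speed

_MACKENZIE_RANGES = ((-2.0, 35.0), (0.0, 42.0), (0.0, 8000.0))


def sound_speed(temperature_c: float, salinity_psu: float, depth_m: float = 50.0) -> float:
    """Mackenzie (1981) nine-term seawater sound speed, m/s.

    Parameters are temperature (deg C), practical salinity (PSU) and
    depth (m, positive down).
    """
    for value, (lo, hi), name in zip(
        (temperature_c, salinity_psu, depth_m),
        _MACKENZIE_RANGES,
        ("temperature", "salinity", "depth"),
    ):
        if not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside valid range [{lo}, {hi}]")
    t, s, d = temperature_c, salinity_psu, depth_m
    return (
        1448.96
        + 4.591 * t
        - 5.304e-2 * t**2
        + 2.374e-4 * t**3
        + 1.340 * (s - 35.0)
        + 1.630e-2 * d
        + 1.675e-7 * d**2
        - 1.025e-2 * t * (s - 35.0)
        - 7.139e-13 * t * d**3
    )


# ---------------------------------------------------------------------------
# model terms


def reflection_coefficient(params: FluidSphereParams) -> float:
    """Plane-interface reflection coefficient R = (gh - 1)/(gh + 1)."""
    gh = params.g * params.h
    return (gh - 1.0) / (gh + 1.0)


def alpha_pis(params: FluidSphereParams) -> float:
    """Combined compressibility/density contrast term of the Rayleigh limit.

    alpha_pis = (1 - g h^2) / (3 g h^2) + (1 - g) / (1 + 2 g)
    """
    g, h = params.g, params.h
    return (1.0 - g * h * h) / (3.0 * g * h * h) + (1.0 - g) / (1.0 + 2.0 * g)


def ka(esr_mm, params: FluidSphereParams, f_khz: float | None = None):
    """Dimensionless size ka; by default at the geometric-mean frequency."""
    if f_khz is None:
        f_khz = params.f_geometric_khz
    a_m = np.asarray(esr_mm, dtype=float) * 1e-3
    out = params.wavenumber(f_khz) * a_m
    return float(out) if np.isscalar(esr_mm) else out


def sigma_bs(esr_mm, f_khz: float, params: FluidSphereParams):
    """Backscattering cross-section (m^2) of a fluid sphere of given ESR (mm).

    Accepts scalars or arrays of ESR.  Raises if the model is undefined
    (zero reflection coefficient with a non-zero Rayleigh term).
    """
    a_m = np.asarray(esr_mm, dtype=float) * 1e-3
    if np.any(a_m <= 0):
        raise ValueError("esr must be positive")
    if f_khz <= 0:
        raise ValueError("frequency must be positive")
    alpha = alpha_pis(params)
    refl = reflection_coefficient(params)
    if refl == 0.0:
        if alpha != 0.0:
            raise ValueError("R = 0 with alpha_pis != 0: high-pass model undefined")
        return np.zeros_like(a_m) if a_m.ndim else 0.0
    kav = params.wavenumber(f_khz) * a_m
    num = a_m**2 * kav**4 * alpha**2
    den = 1.0 + 4.0 * kav**4 * alpha**2 / refl**2
    out = num / den
    return float(out) if np.isscalar(esr_mm) else out


def target_strength(esr_mm, f_khz: float, params: FluidSphereParams):
    """Target strength TS = 10*log10(sigma_bs), dB re 1 m^2."""
    s = sigma_bs(esr_mm, f_khz, params)
    if np.any(np.asarray(s) <= 0):
        raise ValueError("sigma_bs = 0: TS undefined in dB")
    out = 10.0 * np.log10(s)
    return float(out) if np.isscalar(esr_mm) else out


def delta_ts(esr_mm, params: FluidSphereParams):
    """TS difference between the high and low frequency, dB.

    Tends to 40*log10(f_high/f_low) as esr -> 0 and decreases
    monotonically with size while ka at the high frequency stays below
    about 2, which is the invertible band.
    """
    return target_strength(esr_mm, params.f_high_khz, params) - target_strength(
        esr_mm, params.f_low_khz, params
    )


# ---------------------------------------------------------------------------
# size band and inversion


def _solve_esr(delta_db: float, params: FluidSphereParams, lo: float, hi: float) -> float:
    return brentq(lambda a: delta_ts(a, params) - delta_db, lo, hi, xtol=1e-6)


@dataclass(frozen=True)
class SizeBand:
    """The invertible dTS window and its ESR image under the model.

    Constructed from dTS bounds with :meth:`from_delta_bounds`; the ESR
    edges are computed from the model (not hard-coded) so that
    ``delta_ts`` and ``invert_size`` are exact mutual inverses on the
    band.
    """

    esr_min_mm: float
    esr_max_mm: float
    delta_db_at_min: float
    delta_db_at_max: float
    ka_min: float = field(default=float("nan"))
    ka_max: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not self.esr_min_mm < self.esr_max_mm:
            raise ValueError("esr_min must be < esr_max")
        if not self.delta_db_at_min > self.delta_db_at_max:
            raise ValueError("delta_ts must decrease across the band (non-monotone band)")

    @classmethod
    def from_delta_bounds(
        cls,
        params: FluidSphereParams,
        delta_db_hi: float = 19.7,
        delta_db_lo: float = 7.0,
        search_mm: tuple[float, float] = (0.05, 8.0),
    ) -> "SizeBand":
        """Map a [lo, hi] dB window to its ESR band under the model.

        Defaults are the copepod detection window 7.0-19.7 dB.
        """
        if delta_db_hi <= delta_db_lo:
            raise ValueError("need delta_db_hi > delta_db_lo")
        ceiling = 40.0 * math.log10(params.f_high_khz / params.f_low_khz)
        if delta_db_hi >= ceiling:
            raise ValueError(
                f"upper bound {delta_db_hi} dB at or above the Rayleigh ceiling {ceiling:.2f} dB"
            )
        esr_min = _solve_esr(delta_db_hi, params, *search_mm)
        esr_max = _solve_esr(delta_db_lo, params, *search_mm)
        return cls(
            esr_min_mm=esr_min,
            esr_max_mm=esr_max,
            delta_db_at_min=delta_db_hi,
            delta_db_at_max=delta_db_lo,
            ka_min=ka(esr_min, params),
            ka_max=ka(esr_max, params),
        )


@dataclass(frozen=True)
class InvertedSize:
    esr_mm: float
    clamped: bool


def invert_size(
    delta_db: float, params: FluidSphereParams, band: SizeBand
) -> InvertedSize:
    """Invert a dB difference to ESR (mm) on the monotone band.

    Bisection to 1e-4 mm.  Differences outside the band clamp to the
    nearest band edge and are flagged ``clamped``.
    """
    if delta_ts(band.esr_min_mm, params) <= delta_ts(band.esr_max_mm, params):
        raise ValueError("band is not monotone decreasing under these parameters")
    if delta_db > band.delta_db_at_min:
        return InvertedSize(band.esr_min_mm, True)
    if delta_db < band.delta_db_at_max:
        return InvertedSize(band.esr_max_mm, True)
    lo, hi = band.esr_min_mm, band.esr_max_mm
    f_lo = delta_ts(lo, params) - delta_db   # >= 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if delta_ts(mid, params) - delta_db >= 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    del f_lo
    return InvertedSize(0.5 * (lo + hi), False)
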