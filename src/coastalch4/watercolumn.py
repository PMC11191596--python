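"""Water-column computations: redox classification, sea-air gas exchange,
floating-chamber fluxes, and oxycline location.

The diffusive sea-air flux is

    F_atm = k * (C_W - C_O),

with k the gas transfer velocity (m d^-1), C_W the dissolved methane
concentration at 1 m depth and C_O the concentration in equilibrium with
the atmosphere (both mmol m^-3).  Positive F_atm is emission to the
atmosphere.  Defaults: Wanninkhof (2014) quadratic wind-speed relation
k = 0.251 u10^2 (Sc/660)^-1/2 (cm h^-1) and the Wiesenburg & Guinasso
(1979) methane solubility function for C_O; both are the community
standards for coastal flux estimates and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DataError,
    ExtrapolationWarning,
    NonLinearSeriesWarning,
    ParameterError,
    ValidationError,
)
from .io_formats import ProfileTable

__all__ = [
    "GasExchangeEnv",
    "SeaAirFlux",
    "RedoxClass",
    "ChamberSeries",
    "ChamberFluxResult",
    "classify_redox",
    "schmidt_number",
    "gas_transfer_velocity",
    "equilibrium_concentration",
    "sea_air_flux",
    "chamber_flux",
    "average_chamber_fluxes",
    "find_oxycline",
    "surface_concentration",
]

#: Hypoxia threshold, mmol m^-3 (= umol L^-1): waters with O2 below this
#: are hypoxic; euxinic waters have (near-)zero O2 and free sulfide.
HYPOXIA_THRESHOLD = 63.0

# CH4 Schmidt-number polynomials in t (degC), Wanninkhof (2014) Table 1.
_SC_CH4_SEAWATER = (2101.2, -131.54, 4.4931, -0.08676, 0.00070663)   # S = 35
_SC_CH4_FRESHWATER = (1909.4, -120.78, 4.1555, -0.080578, 0.00065777)  # S = 0

# Wiesenburg & Guinasso (1979) methane solubility from moist air at 1 atm,
# C in nmol L^-1, T in kelvin, S practical.
_WG79_A = (-415.2807, 596.8104, 379.2599, -62.0757)
_WG79_B = (-0.059160, 0.032174, -0.0048198)

R_GAS = 8.314462618  # J mol^-1 K^-1
ATM_PA = 101325.0


@dataclass(frozen=True)
class GasExchangeEnv:
    """Inputs for a sea-air flux calculation.

    u10 m s^-1; temperature degC; salinity practical; C_W mmol m^-3
    (dissolved CH4 at 1 m depth); atmospheric mixing ratio ppb (dry-air
    mole fraction); pressure atm.
    """

    u10: float
    temperature: float
    salinity: float
    C_W: float
    atm_mixing_ratio: float = 1900.0
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if self.u10 < 0:
            raise ParameterError(f"u10 must be >= 0, got {self.u10}")
        if self.C_W < 0:
            raise ParameterError(f"C_W must be >= 0, got {self.C_W}")


@dataclass(frozen=True)
class SeaAirFlux:
    """Sea-air flux and its ingredients; F_atm = k * (C_W - C_O) exactly."""

    F_atm: float       # mmol m^-2 d^-1, positive = emission
    k: float           # m d^-1
    C_W: float         # mmol m^-3
    C_O: float         # mmol m^-3
    Sc: float          # dimensionless
    k_model: str = "wanninkhof2014"
    solubility_model: str = "wiesenburg_guinasso1979"


@dataclass(frozen=True)
class RedoxClass:
    """Bottom-water redox state: oxic / hypoxic / euxinic (+ anoxic edge case)."""

    label: str
    bottom_O2: float
    bottom_sulfide: float


@dataclass
class ChamberSeries:
    """A floating-chamber headspace time series.

    time_s strictly increasing; concentration in ppb (dry mole fraction);
    geometry in m^3 / m^2.  Deployments outside the 3-10 min protocol
    window raise a warning, not an error.
    """

    time_s: np.ndarray
    ch4_ppb: np.ndarray
    chamber_volume: float
    chamber_area: float
    air_T: float = 15.0
    pressure: float = 1.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ch4_ppb = np.asarray(self.ch4_ppb, dtype=float)
        if self.time_s.shape != self.ch4_ppb.shape:
            raise ValidationError("time and concentration arrays differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("chamber times must be strictly increasing")
        if self.chamber_area <= 0 or self.chamber_volume <= 0:
            raise ParameterError("chamber area and volume must be > 0")
        duration = self.time_s[-1] - self.time_s[0]
        if not 180.0 <= duration <= 600.0:
            warnings.warn(f"chamber deployment of {duration:.0f} s is outside the "
                          "3-10 min protocol window", ExtrapolationWarning,
                          stacklevel=2)


@dataclass(frozen=True)
class ChamberFluxResult:
    flux: float          # mmol m^-2 d^-1
    slope_ppb_s: float
    r_squared: float
    nonlinear: bool


def classify_redox(bottom_O2: float, bottom_sulfide: float,
                   o2_zero_tol: float = 1.0) -> RedoxClass:
    """Classify bottom water as oxic / hypoxic / euxinic.

    Euxinic: O2 at or below the sensor zero tolerance (default 1 mmol m^-3)
    with free sulfide present.  Hypoxic: O2 below 63 mmol m^-3.  Oxic
    otherwise.  Anoxic water without sulfide is labelled
    ``anoxic_non_euxinic`` with a warning (not observed in this system).
    """
    if bottom_O2 < 0 or bottom_sulfide < 0:
        raise ParameterError("concentrations must be >= 0")
    if bottom_O2 <= o2_zero_tol:
        if bottom_sulfide > 0:
            label = "euxinic"
        else:
            label = "anoxic_non_euxinic"
            warnings.warn("anoxic bottom water without sulfide; no such site "
                          "class in the study system", ExtrapolationWarning,
                          stacklevel=2)
    elif bottom_O2 < HYPOXIA_THRESHOLD:
        label = "hypoxic"
    else:
        label = "oxic"
    return RedoxClass(label=label, bottom_O2=float(bottom_O2),
                      bottom_sulfide=float(bottom_sulfide))


def _sc_poly(coeffs: tuple[float, ...], t: float) -> float:
    return sum(c * t**i for i, c in enumerate(coeffs))


def schmidt_number(temperature: float, salinity: float) -> float:
    """CH4 Schmidt number, 4th-order polynomial in T, linear in salinity.

    Interpolates between the published freshwater (S=0) and seawater (S=35)
    polynomials; outside 0-30 degC the polynomials are extrapolated with a
    warning.
    """
    t = float(temperature)
    if not 0.0 <= t <= 30.0:
        warnings.warn(f"Schmidt-number polynomial extrapolated at T={t} degC",
                      ExtrapolationWarning, stacklevel=2)
    sc_fresh = _sc_poly(_SC_CH4_FRESHWATER, t)
    sc_sea = _sc_poly(_SC_CH4_SEAWATER, t)
    w = np.clip(salinity / 35.0, 0.0, None)
    return float(sc_fresh + w * (sc_sea - sc_fresh))


def gas_transfer_velocity(u10: float, Sc: float, coefficient: float = 0.251) -> float:
    """Gas transfer velocity k in m d^-1 (quadratic wind-speed relation).

    k = coefficient * u10^2 * (Sc/660)^-1/2 with the coefficient in
    cm h^-1 (m s^-1)^-2 (default 0.251, Wanninkhof 2014), converted to m d^-1.
    """
    if u10 < 0:
        raise ParameterError(f"u10 must be >= 0, got {u10}")
    k_cm_h = coefficient * u10**2 * (Sc / 660.0) ** -0.5
    return k_cm_h * 0.24  # 1 cm h^-1 = 0.24 m d^-1


def equilibrium_concentration(temperature: float, salinity: float,
                              mixing_ratio: float = 1900.0,
                              pressure: float = 1.0) -> float:
    """Dissolved CH4 in equilibrium with the atmosphere, mmol m^-3.

    Wiesenburg & Guinasso (1979) solubility of methane from moist air at
    1 atm total pressure, scaled linearly to the given dry-air mixing ratio
    (ppb) and total pressure (atm).
    """
    t_k = float(temperature) + 273.15
    f_g = mixing_ratio * 1e-9  # dry-air mole fraction
    a1, a2, a3, a4 = _WG79_A
    b1, b2, b3 = _WG79_B
    ln_c = (np.log(f_g) + a1 + a2 * (100.0 / t_k) + a3 * np.log(t_k / 100.0)
            + a4 * (t_k / 100.0)
            + salinity * (b1 + b2 * (t_k / 100.0) + b3 * (t_k / 100.0) ** 2))
    c_nmol_l = np.exp(ln_c) * pressure
    return float(c_nmol_l * 1e-3)  # nmol L^-1 -> mmol m^-3


def sea_air_flux(env: GasExchangeEnv) -> SeaAirFlux:
    """Diffusive sea-air methane flux F_atm = k (C_W - C_O), mmol m^-2 d^-1."""
    sc = schmidt_number(env.temperature, env.salinity)
    k = gas_transfer_velocity(env.u10, sc)
    c_o = equilibrium_concentration(env.temperature, env.salinity,
                                    env.atm_mixing_ratio, env.pressure)
    return SeaAirFlux(F_atm=k * (env.C_W - c_o), k=k, C_W=env.C_W, C_O=c_o, Sc=sc)


def chamber_flux(series: ChamberSeries, r2_threshold: float = 0.9) -> ChamberFluxResult:
    """Sea-air flux from a floating-chamber series, mmol m^-2 d^-1.

    Least-squares slope of headspace mixing ratio vs time, converted to a
    molar accumulation rate with the ideal gas law (n = pV/RT) and divided
    by the chamber footprint.  Series with R^2 below ``r2_threshold`` are
    flagged non-linear (value still returned).
    """
    if series.time_s.size < 4:
        raise DataError(f"chamber series needs >= 4 points, got {series.time_s.size}")
    res = stats.linregress(series.time_s, series.ch4_ppb)
    slope = float(res.slope)  # ppb s^-1
    r2 = float(res.rvalue**2) if np.std(series.ch4_ppb) > 0 else 1.0
    n_air = series.pressure * ATM_PA * series.chamber_volume / (R_GAS * (series.air_T + 273.15))
    # ppb s^-1 -> mol mol^-1 s^-1; * mol air -> mol s^-1; -> mmol d^-1 m^-2
    flux = slope * 1e-9 * n_air / series.chamber_area * 86400.0 * 1e3
    nonlinear = r2 < r2_threshold
    if nonlinear:
        warnings.warn(f"chamber series R^2 = {r2:.3f} < {r2_threshold}; "
                      "flux flagged non-linear", NonLinearSeriesWarning,
                      stacklevel=2)
    return ChamberFluxResult(flux=float(flux), slope_ppb_s=slope,
                             r_squared=r2, nonlinear=nonlinear)


def average_chamber_fluxes(results: list[ChamberFluxResult]) -> tuple[float, float]:
    """Mean and standard deviation of replicate chamber fluxes."""
    fluxes = np.array([r.flux for r in results], dtype=float)
    return float(fluxes.mean()), float(fluxes.std(ddof=1)) if fluxes.size > 1 else 0.0


def find_oxycline(profile: ProfileTable, threshold: float = HYPOXIA_THRESHOLD,
                  o2_column: str = "o2") -> float | None:
    """Shallowest depth (m) at which O2 falls below ``threshold``, or None.

    Linear interpolation between samples; None when the whole profile stays
    at or above the threshold.
    """
    z = profile.depth
    o2 = profile.column(o2_column)
    ok = np.isfinite(o2)
    z, o2 = z[ok], o2[ok]
    if z.size == 0:
        raise DataError("no finite oxygen values in profile")
    if o2[0] < threshold:
        return float(z[0])
    for i in range(len(z) - 1):
        if o2[i] >= threshold > o2[i + 1]:
            frac = (o2[i] - threshold) / (o2[i] - o2[i + 1])
            return float(z[i] + frac * (z[i + 1] - z[i]))
    return None


def surface_concentration(profile: ProfileTable, column: str = "ch4",
                          target_depth: float = 1.0,
                          tolerance: float = 1.0) -> float:
    """Dissolved concentration at the reference (1 m) depth.

    Exact 1 m sample if present, else the nearest sample within
    ``target_depth +/- tolerance`` (default 0-2 m) with a warning.
    """
    z = profile.depth
    c = profile.column(column)
    exact = np.flatnonzero(z == target_depth)
    if exact.size:
        return float(c[exact[0]])
    dist = np.abs(z - target_depth)
    i = int(np.argmin(dist))
    if dist[i] > tolerance:
        raise DataError(f"no sample within {tolerance} m of {target_depth} m depth")
    warnings.warn(f"no {target_depth} m sample; using nearest at {z[i]} m",
                  ExtrapolationWarning, stacklevel=2)
    return float(c[i])
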