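"""Sediment-side computations: diffusion coefficients, interfacial
gradients, Fickian benthic fluxes, and SMTZ depth detection.

The benthic diffusive flux follows Fick's first law for sediments,

    J = -phi * Ds * dC/dz,

with phi the porosity, Ds the sediment diffusion coefficient and z the
sediment depth.  Because this package stores depth positive *downward*
from the sediment-water interface (SWI), a solute accumulating with depth
(dC/d(depth) > 0) diffuses upward out of the sediment; the returned flux
uses the convention positive J = efflux from sediment to water, i.e.
``J = phi * Ds * dC/d(depth)``.

Free-solution diffusion coefficients D0(T, S) come from the standard
compilation of molecular diffusivities in water (Boudreau 1997): a
quadratic fit in temperature for dissolved methane (Wise & Houghton data)
and linear fits for the sulfate and bisulfide ions (Li & Gregory data),
with salinity handled through a Stokes-Einstein dynamic-viscosity ratio.
Tortuosity uses theta^2 = 1 - 2 ln(phi), so Ds = D0 / theta^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateDataWarning, ParameterError, ValidationError
from .io_formats import ProfileTable

__all__ = [
    "SedimentContext",
    "BenthicFlux",
    "diffusion_coefficient",
    "free_solution_diffusivity",
    "dynamic_viscosity",
    "tortuosity_theta2",
    "interfacial_gradient",
    "fickian_flux",
    "find_smtz",
]

# D0 fits at S=0, 1 atm, in 1e-6 cm^2 s^-1 with t in degC (Boudreau 1997).
# methane: quadratic (Wise & Houghton); ions: linear (Li & Gregory).
_GAS_QUADRATIC = {"methane": (9.798, 0.3975, 0.00437)}
_ION_LINEAR = {"sulfate": (4.88, 0.232), "sulfide": (10.4, 0.273)}

_CM2_S_TO_M2_D = 1.0e-4 * 86400.0  # cm^2 s^-1 -> m^2 d^-1


@dataclass(frozen=True)
class SedimentContext:
    """Physical context for a sediment diffusion calculation.

    porosity : dimensionless fraction, 0 < phi < 1
    temperature : degC, within -2..40
    salinity : practical salinity, >= 0
    solute : "methane", "sulfate" or "sulfide"
    """

    porosity: float
    temperature: float
    salinity: float
    solute: str = "methane"

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ParameterError(f"porosity must be in (0, 1), got {self.porosity}")
        if not -2.0 <= self.temperature <= 40.0:
            raise ParameterError(f"temperature {self.temperature} degC outside -2..40")
        if self.salinity < 0:
            raise ParameterError(f"salinity must be >= 0, got {self.salinity}")
        if self.solute not in ("methane", "sulfate", "sulfide"):
            raise ParameterError(f"unsupported solute {self.solute!r}")


@dataclass(frozen=True)
class BenthicFlux:
    """A benthic diffusive flux and the quantities that produced it.

    ``J`` is in mmol m^-2 d^-1, positive for efflux from sediment to water.
    The identity J = porosity * Ds * gradient_dCdz holds exactly for the
    stored fields (gradient with depth positive downward).
    """

    J: float
    gradient_dCdz: float
    Ds: float
    D0: float
    porosity: float
    method: str = "two_point"
    lower_bound: bool = False


def dynamic_viscosity(temperature: float, salinity: float) -> float:
    """Dynamic viscosity of (sea)water in centipoise at 1 atm.

    Polynomial fit in temperature (degC) and salinity used by the standard
    aquatic-chemistry toolboxes; pressure terms dropped (surface sediments).
    """
    t, s = float(temperature), float(salinity)
    return (1.7910
            - t * (6.144e-02 - t * (1.4510e-03 - t * 1.6826e-05))
            + 2.4727e-03 * s
            + s * (4.8429e-05 * t - 4.7172e-06 * t**2 + 7.5986e-08 * t**3))


def free_solution_diffusivity(solute: str, temperature: float, salinity: float) -> float:
    """Free-solution diffusion coefficient D0 in m^2 d^-1 at (T, S)."""
    t = float(temperature)
    if solute in _GAS_QUADRATIC:
        a, b, c = _GAS_QUADRATIC[solute]
        d0 = (a + b * t + c * t * t) * 1e-6  # cm^2 s^-1, S=0
    elif solute in _ION_LINEAR:
        a, b = _ION_LINEAR[solute]
        d0 = (a + b * t) * 1e-6
    else:
        raise ParameterError(f"unsupported solute {solute!r}")
    # Stokes-Einstein: D * mu ~ const at fixed T -> scale by viscosity ratio.
    d0 *= dynamic_viscosity(t, 0.0) / dynamic_viscosity(t, salinity)
    return d0 * _CM2_S_TO_M2_D


def tortuosity_theta2(porosity: float) -> float:
    """Tortuosity squared, theta^2 = 1 - 2 ln(phi) (Boudreau relation)."""
    if not 0.0 < porosity <= 1.0:
        raise ParameterError(f"porosity must be in (0, 1], got {porosity}")
    return 1.0 - 2.0 * np.log(porosity)


def diffusion_coefficient(ctx: SedimentContext) -> tuple[float, float]:
    """Return (D0, Ds) in m^2 d^-1 for the given sediment context."""
    d0 = free_solution_diffusivity(ctx.solute, ctx.temperature, ctx.salinity)
    ds = d0 / tortuosity_theta2(ctx.porosity)
    return d0, ds


def interfacial_gradient(profile: ProfileTable, solute: str,
                         method: str = "two_point",
                         bottom_water_conc: float = 0.0,
                         window: tuple[float, float] = (0.0, 0.05)) -> float:
    """Concentration gradient dC/dz at the SWI in mmol m^-4, z positive downward.

    ``two_point`` (default) uses the bottom-water concentration at z = 0 and
    the shallowest porewater sample: (C1 - C_bw) / z1.  ``linear_fit`` is a
    least-squares slope over the uppermost window (default 0-5 cm), with the
    bottom-water point included at z = 0.
    """
    z = profile.depth
    c = profile.column(solute)
    ok = np.isfinite(c)
    z, c = z[ok], c[ok]
    # a z=0 row in the profile *is* the bottom-water point
    if z.size and z[0] == 0.0:
        bottom_water_conc = c[0]
        z, c = z[1:], c[1:]
    if method == "two_point":
        if z.size < 1:
            raise DataError(f"no porewater samples for solute {solute!r}")
        return (c[0] - bottom_water_conc) / z[0]
    if method == "linear_fit":
        lo, hi = window
        sel = (z > lo) & (z <= hi)
        zz = np.concatenate([[0.0], z[sel]])
        cc = np.concatenate([[bottom_water_conc], c[sel]])
        if zz.size < 3:
            raise DataError(f"linear_fit needs >= 3 points in window {window}, "
                            f"got {zz.size}")
        slope, _ = np.polyfit(zz, cc, 1)
        return float(slope)
    raise ParameterError(f"unknown gradient method {method!r}")


def fickian_flux(ctx: SedimentContext, gradient: float,
                 method: str = "two_point",
                 max_porewater_conc: float | None = None,
                 saturation_threshold: float = 2000.0) -> BenthicFlux:
    """Fick's-first-law benthic flux, positive = efflux to the water column.

    With depth positive downward, J = phi * Ds * dC/d(depth); a positive
    downward-increasing methane gradient yields a positive (upward) efflux.

    If ``max_porewater_conc`` exceeds ``saturation_threshold`` (mmol m^-3)
    the flux is flagged ``lower_bound``: porewater methane may have degassed
    during core retrieval, so the measured gradient understates the flux.
    """
    d0, ds = diffusion_coefficient(ctx)
    j = ctx.porosity * ds * gradient
    lower = bool(max_porewater_conc is not None
                 and max_porewater_conc > saturation_threshold)
    return BenthicFlux(J=float(j), gradient_dCdz=float(gradient), Ds=ds, D0=d0,
                       porosity=ctx.porosity, method=method, lower_bound=lower)


def _as_depth_series(obj, profile: ProfileTable | None, name: str):
    if profile is not None:
        return profile.depth, profile.column(obj)
    z, c = obj
    return np.asarray(z, dtype=float), np.asarray(c, dtype=float)


def find_smtz(methane, sulfate,
              profile: ProfileTable | None = None) -> float | None:
    """Depth (m) of equimolar sulfate and methane concentrations.

    ``methane``/``sulfate`` are either ``(depth, conc)`` array pairs or, if
    ``profile`` is given, column names in that profile.  Both series are
    resampled onto their common depth range by linear interpolation; the
    crossing is located by interpolation between the bracketing grid points.
    Returns the shallowest crossing (deeper ones raise a warning), or None
    when the profiles never cross.
    """
    z1, c1 = _as_depth_series(methane, profile, "methane")
    z2, c2 = _as_depth_series(sulfate, profile, "sulfate")
    ok1, ok2 = np.isfinite(c1), np.isfinite(c2)
    z1, c1, z2, c2 = z1[ok1], c1[ok1], z2[ok2], c2[ok2]
    lo, hi = max(z1.min(), z2.min()), min(z1.max(), z2.max())
    if lo >= hi:
        raise DataError("methane and sulfate profiles have disjoint depth ranges")
    grid = np.unique(np.concatenate([z1, z2]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    ch4 = np.interp(grid, z1, c1)
    so4 = np.interp(grid, z2, c2)
    diff = ch4 - so4
    crossings: list[float] = []
    for i in range(len(grid) - 1):
        if diff[i] == 0.0:
            crossings.append(float(grid[i]))
        elif diff[i] * diff[i + 1] < 0.0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            crossings.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    if diff[-1] == 0.0:
        crossings.append(float(grid[-1]))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(f"multiple equimolar crossings at {crossings}; "
                      "reporting the shallowest", DegenerateDataWarning,
                      stacklevel=2)
    return crossings[0]
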