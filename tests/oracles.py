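"""Independently coded oracles used to cross-check the implementation.

Each function here re-derives a published parameterization or closed-form
result directly from its printed coefficients, written without reference
to the package internals, so agreement is a genuine dual-route check.
"""

import math


def oracle_viscosity_cp(t, s):
    """Dynamic viscosity of seawater, centipoise, 1 atm (polynomial fit)."""
    return (1.7910 - 6.144e-2 * t + 1.4510e-3 * t ** 2 - 1.6826e-5 * t ** 3
            + 2.4727e-3 * s
            + 4.8429e-5 * s * t - 4.7172e-6 * s * t ** 2 + 7.5986e-8 * s * t ** 3)


def oracle_d0_ch4_m2d(t, s):
    """Free-solution CH4 diffusivity, m^2 d^-1: Boudreau-compilation quadratic
    (9.798 + 0.3975 t + 0.00437 t^2) 1e-6 cm^2 s^-1 at S=0, viscosity-scaled."""
    d0_cm2s = (9.798 + 0.3975 * t + 0.00437 * t * t) * 1e-6
    d0_cm2s *= oracle_viscosity_cp(t, 0.0) / oracle_viscosity_cp(t, s)
    return d0_cm2s * 1e-4 * 86400.0


def oracle_ds_m2d(t, s, phi):
    """Sediment diffusivity with tortuosity theta^2 = 1 - 2 ln(phi)."""
    return oracle_d0_ch4_m2d(t, s) / (1.0 - 2.0 * math.log(phi))


def oracle_schmidt_ch4(t, s):
    """CH4 Schmidt number: published 4th-order polynomials at S=0 and S=35,
    linear interpolation in salinity."""
    fresh = (1909.4 - 120.78 * t + 4.1555 * t ** 2 - 0.080578 * t ** 3
             + 0.00065777 * t ** 4)
    sea = (2101.2 - 131.54 * t + 4.4931 * t ** 2 - 0.08676 * t ** 3
           + 0.00070663 * t ** 4)
    return fresh + (s / 35.0) * (sea - fresh)


def oracle_k_m_d(u10, sc):
    """Quadratic gas transfer velocity, 0.251 cm h^-1 (m s^-1)^-2, m d^-1."""
    return 0.251 * u10 ** 2 * math.sqrt(660.0 / sc) * 24.0 / 100.0


def oracle_co_mmol_m3(t_c, s, ppb, pressure=1.0):
    """Atmospheric-equilibrium dissolved CH4 (solubility-function fit),
    mmol m^-3; coefficients for nmol L^-1, moist air, 1 atm."""
    tk = t_c + 273.15
    ln_c = (math.log(ppb * 1e-9)
            - 415.2807 + 596.8104 * (100.0 / tk) + 379.2599 * math.log(tk / 100.0)
            - 62.0757 * (tk / 100.0)
            + s * (-0.059160 + 0.032174 * (tk / 100.0)
                   - 0.0048198 * (tk / 100.0) ** 2))
    return math.exp(ln_c) * pressure * 1e-3


def oracle_rayleigh_delta(f, alpha, delta0):
    """Closed-system Rayleigh residual delta at remaining fraction f."""
    return (delta0 + 1000.0) * f ** (1.0 / alpha - 1.0) - 1000.0


def oracle_mix_delta(f_bubble, delta_source, delta_residual):
    """Concentration-weighted delta of a two-endmember mixture."""
    return f_bubble * delta_source + (1.0 - f_bubble) * delta_residual


def oracle_fick_flux(phi, ds, dcdz_downward):
    """Fick's first law with depth positive downward, positive = efflux."""
    return phi * ds * dcdz_downward


def oracle_seaair_flux(u10, t, s, c_w, ppb=1900.0):
    """Full gas-exchange chain composed from the oracles above."""
    k = oracle_k_m_d(u10, oracle_schmidt_ch4(t, s))
    return k * (c_w - oracle_co_mmol_m3(t, s, ppb))
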