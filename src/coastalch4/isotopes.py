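"""Methane stable-isotope systematics.

Two pieces of isotope machinery drive the water-column interpretation:

* **Rayleigh fractionation** of the residual methane pool during microbial
  oxidation.  For a closed system,

      delta + 1000 = (delta_0 + 1000) * f^(1/alpha - 1),

  so ln(delta + 1000) is linear in ln(C) (C proportional to the remaining
  fraction f) with slope s = 1/alpha - 1, giving alpha = 1/(1 + s) and
  epsilon = (alpha - 1) * 1000 per mil.  Fractionation factors of
  1.002-1.035 are typical of aerobic and anaerobic methane oxidation.

* **Two-endmember mixing** between a maximally oxidized diffusive pool
  (delta_residual) and methane dissolved out of rising bubbles that carry
  the sediment source signature (delta_source, e.g. -58.7 permil for
  delta13C and -262 permil for deltaD):

      f_bubble = (delta_mix - delta_residual) / (delta_source - delta_residual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateDataWarning, InverseFractionationWarning, ParameterError
from .io_formats import ProfileTable

__all__ = [
    "IsotopeValue",
    "RayleighFit",
    "IsotopePartition",
    "rayleigh_alpha",
    "rayleigh_alpha_profile",
    "forward_rayleigh",
    "mixing_fractions",
    "forward_mix",
    "bubble_contribution",
    "residual_endmember",
    "dual_isotope_check",
]

#: Plausibility window for methane-oxidation fractionation factors.
ALPHA_PLAUSIBLE = (1.002, 1.035)


@dataclass(frozen=True)
class IsotopeValue:
    """A delta value in permil vs the conventional standard (VPDB / VSMOW)."""

    delta: float
    isotope: str = "C13"  # or "D"

    def __post_init__(self) -> None:
        if self.delta <= -1000.0:
            raise ParameterError(f"delta {self.delta} permil is below -1000 (unphysical)")


@dataclass(frozen=True)
class RayleighFit:
    """Result of a Rayleigh fractionation-factor fit.

    alpha >= 1 for a normal kinetic isotope effect; epsilon = (alpha-1)*1000.
    """

    alpha: float
    epsilon: float
    intercept: float
    n_points: int
    fit_window: tuple[float, float] | None = None
    model: str = "closed"
    r_squared: float = float("nan")

    @property
    def in_plausible_range(self) -> bool:
        lo, hi = ALPHA_PLAUSIBLE
        return lo <= self.alpha <= hi


@dataclass(frozen=True)
class IsotopePartition:
    """Bubble/diffusion partition of dissolved methane at a reference depth.

    Invariants: 0 <= f_bubble <= 1; C_bubble + C_diff = C_total; the
    concentration-weighted delta of the two pools reproduces delta_mix.
    """

    delta_mix: float
    delta_source: float
    delta_residual: float
    f_bubble: float
    C_total: float
    C_bubble: float
    C_diff: float

    @property
    def percent_bubble(self) -> int:
        """Bubble contribution rounded to integer percent (report format)."""
        return int(round(100.0 * self.f_bubble))


def forward_rayleigh(f, alpha: float, delta0: float):
    """Closed-system Rayleigh residual delta for remaining fraction(s) f.

    This is the forward model inverted by :func:`rayleigh_alpha`; it also
    serves as the generator for synthetic enrichment profiles.
    """
    f = np.asarray(f, dtype=float)
    return (delta0 + 1000.0) * f ** (1.0 / alpha - 1.0) - 1000.0


def rayleigh_alpha(pairs, model: str = "closed") -> RayleighFit:
    """Fit a fractionation factor to (concentration, delta) pairs.

    closed (default): least-squares of ln(delta+1000) on ln(C); the slope s
    estimates 1/alpha - 1, so alpha = 1/(1+s) and epsilon ~ -1000*s.

    open: steady-state approximation delta = delta_0 + epsilon*(1 - f) with
    f = C / max(C); fits epsilon directly.  Documented alternative for
    systems flushed on the oxidation timescale.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DataError("need >= 3 (concentration, delta) pairs")
    c, d = arr[:, 0], arr[:, 1]
    if np.any(c <= 0):
        raise DataError("all concentrations must be > 0 for a Rayleigh fit")
    if np.any(d <= -1000):
        raise DataError("delta values must exceed -1000 permil")
    if model == "closed":
        x, y = np.log(c), np.log(d + 1000.0)
        slope, intercept = np.polyfit(x, y, 1)
        alpha = 1.0 / (1.0 + slope)
        yhat = slope * x + intercept
    elif model == "open":
        f = c / c.max()
        slope, intercept = np.polyfit(1.0 - f, d, 1)  # slope = epsilon (permil)
        alpha = 1.0 + slope / 1000.0
        x, y = 1.0 - f, d
        yhat = slope * x + intercept
    else:
        raise ParameterError(f"unknown Rayleigh model {model!r}")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if alpha < 1.0:
        warnings.warn(f"fitted alpha = {alpha:.5f} < 1: inverse fractionation",
                      InverseFractionationWarning, stacklevel=2)
    return RayleighFit(alpha=float(alpha), epsilon=float((alpha - 1.0) * 1000.0),
                       intercept=float(intercept), n_points=len(c),
                       model=model, r_squared=r2)


def rayleigh_alpha_profile(profile: ProfileTable,
                           window: tuple[float, float],
                           conc_column: str = "ch4",
                           delta_column: str = "d13c",
                           model: str = "closed") -> RayleighFit:
    """Rayleigh fit over a depth window of a water-column profile.

    The window should span the zone where isotopic enrichment of the
    residual pool is observed (typically between the surface mixed layer
    and the oxycline); it is a user/site choice, not auto-detected.
    """
    z = profile.depth
    lo, hi = window
    sel = (z >= lo) & (z <= hi)
    c = profile.column(conc_column)[sel]
    d = profile.column(delta_column)[sel]
    ok = np.isfinite(c) & np.isfinite(d)
    fit = rayleigh_alpha(np.column_stack([c[ok], d[ok]]), model=model)
    return RayleighFit(alpha=fit.alpha, epsilon=fit.epsilon, intercept=fit.intercept,
                       n_points=fit.n_points, fit_window=(float(lo), float(hi)),
                       model=fit.model, r_squared=fit.r_squared)


def forward_mix(f_bubble: float, delta_source: float, delta_residual: float) -> float:
    """Concentration-weighted delta of a two-endmember mixture (oracle inverse
    of :func:`mixing_fractions`)."""
    return f_bubble * delta_source + (1.0 - f_bubble) * delta_residual


def mixing_fractions(delta_mix: float, delta_residual: float,
                     delta_source: float, clip_tolerance: float = 0.02) -> float:
    """Bubble-derived fraction from a two-endmember isotope mass balance.

    f_bubble = (delta_mix - delta_residual) / (delta_source - delta_residual),
    clipped to [0, 1]; exceedances beyond ``clip_tolerance`` warn (endmember
    choice is then suspect).
    """
    if delta_residual == delta_source:
        raise DataError("degenerate endmembers: delta_residual == delta_source")
    f = (delta_mix - delta_residual) / (delta_source - delta_residual)
    if f < -clip_tolerance or f > 1.0 + clip_tolerance:
        warnings.warn(f"mixing fraction {f:.3f} outside [0, 1] by more than "
                      f"{clip_tolerance}; check endmembers", DegenerateDataWarning,
                      stacklevel=2)
    return float(np.clip(f, 0.0, 1.0))


def bubble_contribution(C_total: float, f_bubble: float,
                        delta_mix: float = float("nan"),
                        delta_source: float = float("nan"),
                        delta_residual: float = float("nan")) -> IsotopePartition:
    """Concentration split of dissolved methane into bubble and diffusive pools.

    C_bubble = f_bubble * C_total and C_diff is the remainder; the integer
    report percentage is available as ``percent_bubble``.  The delta fields
    are carried for provenance when the fraction came from
    :func:`mixing_fractions`.
    """
    if C_total < 0 or not 0.0 <= f_bubble <= 1.0:
        raise ParameterError("need C_total >= 0 and f_bubble in [0, 1]")
    c_bub = f_bubble * C_total
    return IsotopePartition(delta_mix=delta_mix, delta_source=delta_source,
                            delta_residual=delta_residual, f_bubble=float(f_bubble),
                            C_total=float(C_total), C_bubble=float(c_bub),
                            C_diff=float(C_total - c_bub))


def residual_endmember(profile: ProfileTable, delta_column: str = "d13c",
                       min_depth: float = 0.0,
                       max_depth: float | None = None) -> float:
    """Default residual (diffusive-pool) endmember delta for a profile.

    The most 13C-enriched delta observed between ``min_depth`` and
    ``max_depth`` (typically: below the bubble-influenced surface band and
    at/above the oxycline), on the rationale that it represents the most
    oxidized methane.  Overridable per site.
    """
    z = profile.depth
    d = profile.column(delta_column)
    hi = max_depth if max_depth is not None else float(z.max())
    sel = (z >= min_depth) & (z <= hi) & np.isfinite(d)
    if not np.any(sel):
        raise DataError(f"no delta values in depth window [{min_depth}, {hi}] m")
    return float(d[sel].max())


def dual_isotope_check(delta13c_mix: float, delta13c_residual: float,
                       delta13c_source: float,
                       deltaD_mix: float, deltaD_residual: float,
                       deltaD_source: float) -> tuple[float, float]:
    """Mixing fractions predicted independently by delta13C and deltaD.

    Agreement of the two supports the two-endmember interpretation; the
    partition itself remains carbon-based.
    """
    f_c = mixing_fractions(delta13c_mix, delta13c_residual, delta13c_source)
    f_d = mixing_fractions(deltaD_mix, deltaD_residual, deltaD_source)
    return f_c, f_d
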