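"""Site-level methane budgets: removal efficiency, escape fraction, and
cross-site flux/SMTZ relationships.

The removal efficiency treats the diffusive benthic flux as the sole
methane source to the water column and the sea-air flux as the only loss
other than microbial oxidation:

    efficiency = 100 * (F_sed - F_atm) / F_sed      (percent oxidized)
    escape     = 100 * F_atm / F_sed                (percent emitted)

The two always sum to exactly 100.  Bubble dissolution or lateral inputs
can push F_atm above F_sed; the efficiency is then negative and flagged
rather than clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, DegenerateDataWarning, ParameterError
from .watercolumn import RedoxClass

__all__ = ["SiteBudget", "removal_efficiency", "flux_vs_smtz", "assemble_budget"]


@dataclass
class SiteBudget:
    """Per-site roll-up of the pipeline's headline quantities.

    Fluxes in mmol m^-2 d^-1; efficiencies in percent (unrounded; use
    :meth:`report_row` for the integer-rounded presentation).  Missing
    components are None, never silently zero.
    """

    site_id: str
    redox: RedoxClass | None = None
    smtz_depth: float | None = None
    F_sed: float | None = None
    F_atm_calc: float | None = None
    F_atm_insitu: float | None = None
    removal_efficiency: float | None = None
    escape_fraction: float | None = None
    f_bubble_5m: float | None = None
    warnings: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def report_row(self) -> dict:
        """Presentation dict with integer-rounded percentages."""
        def r(x):
            return None if x is None else int(round(x))
        return {
            "site_id": self.site_id,
            "redox": self.redox.label if self.redox else None,
            "smtz_depth_m": self.smtz_depth,
            "F_sed": self.F_sed,
            "F_atm_calc": self.F_atm_calc,
            "F_atm_insitu": self.F_atm_insitu,
            "removal_efficiency_pct": r(self.removal_efficiency),
            "escape_fraction_pct": r(self.escape_fraction),
            "f_bubble_5m_pct": r(None if self.f_bubble_5m is None
                                 else 100.0 * self.f_bubble_5m),
        }


def removal_efficiency(F_sed: float, F_atm: float) -> tuple[float, float]:
    """Water-column methane removal efficiency and escape fraction, percent.

    Returns unrounded values; efficiency + escape = 100 exactly.  F_atm
    exceeding F_sed yields a negative efficiency with a warning (the
    source accounting is then incomplete: bubble dissolution or lateral
    input implied).
    """
    if F_sed <= 0:
        raise ParameterError(f"F_sed must be > 0, got {F_sed}")
    if F_atm < 0:
        raise ParameterError(f"F_atm must be >= 0, got {F_atm}")
    escape = 100.0 * F_atm / F_sed
    efficiency = 100.0 - escape
    if F_atm > F_sed:
        warnings.warn("F_atm exceeds F_sed: source exceeds sink accounting "
                      "(bubble dissolution or lateral input implied)",
                      DegenerateDataWarning, stacklevel=2)
    return efficiency, escape


def flux_vs_smtz(budgets: list[SiteBudget],
                 which: str = "benthic") -> tuple[float | None, int]:
    """Spearman rank correlation between SMTZ depth and a flux across sites.

    ``which`` selects the benthic flux (F_sed) or sea-air flux (F_atm_calc).
    Returns (rho, n); rho is None (with a warning) when ranks are
    degenerate, e.g. constant flux.  A negative rho reproduces the
    shallow-SMTZ = high-flux pattern.
    """
    attr = {"benthic": "F_sed", "sea_air": "F_atm_calc"}.get(which)
    if attr is None:
        raise ParameterError(f"which must be 'benthic' or 'sea_air', got {which!r}")
    pairs = [(b.smtz_depth, getattr(b, attr)) for b in budgets
             if b.smtz_depth is not None and getattr(b, attr) is not None]
    if len(pairs) < 3:
        raise DataError(f"need >= 3 sites with SMTZ depth and {attr}, got {len(pairs)}")
    smtz = np.array([p[0] for p in pairs])
    flux = np.array([p[1] for p in pairs])
    if np.all(flux == flux[0]) or np.all(smtz == smtz[0]):
        warnings.warn("degenerate ranks (constant values); correlation undefined",
                      DegenerateDataWarning, stacklevel=2)
        return None, len(pairs)
    rho = stats.spearmanr(smtz, flux).statistic
    return float(rho), len(pairs)


def assemble_budget(site_id: str,
                    redox: RedoxClass | None = None,
                    smtz_depth: float | None = None,
                    F_sed: float | None = None,
                    F_atm_calc: float | None = None,
                    F_atm_insitu: float | None = None,
                    f_bubble_5m: float | None = None,
                    prefer_insitu: bool = False,
                    extras: dict | None = None) -> SiteBudget:
    """Populate a SiteBudget from available components.

    The removal efficiency is computed from F_sed and the calculated
    sea-air flux by default (``prefer_insitu`` switches to the chamber
    flux).  Absent components stay None.
    """
    budget = SiteBudget(site_id=site_id, redox=redox, smtz_depth=smtz_depth,
                        F_sed=F_sed, F_atm_calc=F_atm_calc,
                        F_atm_insitu=F_atm_insitu, f_bubble_5m=f_bubble_5m,
                        extras=extras or {})
    f_atm = F_atm_insitu if (prefer_insitu and F_atm_insitu is not None) else (
        F_atm_calc if F_atm_calc is not None else F_atm_insitu)
    if F_sed is not None and F_sed > 0 and f_atm is not None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            eff, esc = removal_efficiency(F_sed, f_atm)
        budget.removal_efficiency, budget.escape_fraction = eff, esc
        budget.warnings.extend(str(w.message) for w in caught)
    return budget
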