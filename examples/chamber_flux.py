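"""Floating-chamber flux from triplicate headspace time series.

Generates triplicate 5-minute chamber deployments with a planted sea-air
flux of 1.7 mmol m^-2 d^-1 plus instrument noise, then recovers the flux
from the linear rise in headspace methane via the ideal-gas chamber
equation.
"""

from coastalch4 import SyntheticSiteSpec, chamber_flux, generate_chamber
from coastalch4.watercolumn import average_chamber_fluxes

spec = SyntheticSiteSpec(seed=6)
series = generate_chamber(spec, F_true=1.7, noise_sd_ppb=5.0)

results = [chamber_flux(s) for s in series]
mean, sd = average_chamber_fluxes(results)

for i, r in enumerate(results, 1):
    print(f"replicate {i}: slope = {r.slope_ppb_s:.3f} ppb s^-1, "
          f"flux = {r.flux:.3f} mmol m^-2 d^-1, R^2 = {r.r_squared:.4f}")
print(f"chamber flux = {mean:.2f} +/- {sd:.2f} mmol m^-2 d^-1 (triplicate)")
# The planted truth is 1.7; the R^2 near 1 confirms the linear-rise window.
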