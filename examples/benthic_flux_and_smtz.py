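"""Benthic diffusive methane flux and SMTZ depth from a porewater profile.

Builds a small brackish porewater profile (methane rising, sulfate falling
with depth below the sediment-water interface), computes the sediment
diffusion coefficient, the interfacial gradient, the Fickian flux, and the
depth where sulfate and methane are equimolar (the SMTZ).
"""

from coastalch4 import (
    SedimentContext,
    diffusion_coefficient,
    fickian_flux,
    find_smtz,
    interfacial_gradient,
    profile_from_arrays,
)

# depths in m below the SWI; concentrations in mmol m^-3 (= umol/L)
profile = profile_from_arrays(
    [0.0, 0.025, 0.05, 0.075, 0.1], "porewater",
    ch4=[0.0, 700.0, 1400.0, 1900.0, 2200.0],
    so4=[3600.0, 2000.0, 800.0, 300.0, 120.0],
)

ctx = SedimentContext(porosity=0.9, temperature=10.0, salinity=4.5,
                      solute="methane")
d0, ds = diffusion_coefficient(ctx)
grad = interfacial_gradient(profile, "ch4")        # two-point across the SWI
flux = fickian_flux(ctx, grad)
smtz = find_smtz("ch4", "so4", profile=profile)

print(f"free-solution D0      = {d0:.3e} m^2 d^-1")
print(f"sediment Ds           = {ds:.3e} m^2 d^-1   (theta^2 = 1 - 2 ln phi)")
print(f"interfacial gradient  = {grad:.0f} mmol m^-4")
print(f"benthic CH4 flux J    = {flux.J:.2f} mmol m^-2 d^-1 (positive = efflux)")
print(f"SMTZ depth            = {smtz * 100:.1f} cm")
# A flux of a few mmol m^-2 d^-1 with an SMTZ a few cm below the interface
# is the signature of a eutrophied site with a weak benthic methane filter.
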