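"""Calculated sea-air methane flux for brackish surface water.

Runs the full gas-exchange chain: CH4 Schmidt number at the surface
temperature and salinity, quadratic wind-speed gas transfer velocity, the
atmospheric-equilibrium methane concentration, and F_atm = k (C_W - C_O).
"""

from coastalch4 import GasExchangeEnv, sea_air_flux

env = GasExchangeEnv(
    u10=5.0,            # m s^-1 wind at 10 m
    temperature=10.0,   # degC surface water
    salinity=4.5,       # practical (brackish archipelago water)
    C_W=0.39,           # mmol m^-3 dissolved CH4 at 1 m depth
    atm_mixing_ratio=1900.0,  # ppb
)
result = sea_air_flux(env)

print(f"Schmidt number Sc = {result.Sc:.0f}")
print(f"gas transfer velocity k = {result.k:.3f} m d^-1")
print(f"equilibrium concentration C_O = {result.C_O:.5f} mmol m^-3")
print(f"sea-air flux F_atm = {result.F_atm:.3f} mmol m^-2 d^-1")
# C_W is ~100x oversaturated relative to C_O, so the water column is a
# strong methane source to the atmosphere at this site.
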