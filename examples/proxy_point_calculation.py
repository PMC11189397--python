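"""Walk one sediment sample through the closed-form proxy chain.

Takes a phytane d13C measurement with its SST and foraminiferal d13C
context and prints every intermediate: biomass d13C, dissolved-CO2 d13C,
the photosynthetic fractionation epsilon_p, the Henry's-law solubility,
and the final CO2(aq) and pCO2 point estimates.
"""
from epco2 import (
    biomass_from_lipid,
    delta_co2aq_from_foram,
    epsilon_p,
    henry_k0,
    pco2_point,
)

d13c_phytane = -26.0  # per-mil VPDB, measured on the lipid
sst = 18.0            # degC, TEX86-H derived
d13c_foram = 1.5      # per-mil VPDB, interpolated compilation value

delta_p = biomass_from_lipid(d13c_phytane, offset=3.5)
delta_d = delta_co2aq_from_foram(d13c_foram, sst)
eps_p = epsilon_p(delta_d, delta_p)
k0 = henry_k0(sst, salinity=35.0)
co2aq, pco2 = pco2_point(eps_p, b=168.0, eps_f=26.5, k0=k0)

print(f"lipid d13C           {d13c_phytane:8.2f} per-mil")
print(f"biomass d13C (dp)    {delta_p:8.2f} per-mil  (lipid + 3.5 offset)")
print(f"CO2(aq) d13C (dd)    {delta_d:8.2f} per-mil  (foram corrected to {sst} degC)")
print(f"epsilon_p            {eps_p:8.2f} per-mil")
print(f"K0                   {k0:8.5f} mol kg-1 atm-1")
print(f"CO2(aq)              {co2aq:8.2f} umol kg-1  = b/(eps_f - eps_p)")
print(f"pCO2                 {pco2:8.1f} ppmv       = CO2(aq)/K0")
print()
print("A larger epsilon_p (biomass more depleted relative to dissolved CO2)")
print("means more CO2 was available: pCO2 increases with epsilon_p.")
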