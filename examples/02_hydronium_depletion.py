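"""Hydronium budget of an acid-filled crevice under active corrosion.

How long can proton reduction run before the crevice's acid inventory is
consumed?  Inputs: crevice volume 5e-3 cm^3 of 0.1 M acid, corrosion rate
0.5 mA/cm^2 (from Tafel extrapolation) over 5 cm^2 of crevice wall.
"""

import crevsim as cs

inventory = cs.hydronium_inventory(volume_cm3=5e-3, concentration_M=0.1)
flux = cs.faraday_flux(0.5, electrons_per_ion=1)
time_s, rate = cs.depletion_time(inventory, round(flux, 9), area_cm2=5.0)

print(f"hydronium inventory : {inventory:.1e} mol")
print(f"reduction flux      : {flux:.2e} mol/(s cm2)  (~5e-9 after rounding)")
print(f"total reduction rate: {rate:.2e} mol/s")
print(f"depletion time      : {time_s:.0f} s")

# The inventory is gone within tens of seconds: the crevice pH must rise
# early in the experiment, which explains why potentials measured inside
# the crevice recover after the first moments of immersion.
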