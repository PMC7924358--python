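"""Build the crevice gap of the reference trunnion/bore junction.

A 0.02 deg cone mismatch over a 13 mm crevice opens a few-micrometre wedge;
the machined thread pattern (270 um period) modulates it.
"""

import numpy as np

import crevsim as cs

geometry = cs.CreviceGeometry(alpha_deg=0.02, length=13.0, r_int=6.0)
profile = cs.generate_fixture_profile(
    "triangle", period=0.27, amplitude=0.015, length=geometry.length
)
gap = cs.build_gap_profile(geometry, profile)
x = profile.positions

print(f"nominal mouth aperture : {geometry.nominal_mouth_aperture * 1e3:.2f} um")
print(f"gap at the mouth       : {gap[0] * 1e3:.2f} um (peak-first: asperity meets wedge)")
print(f"gap at mid-crevice     : {gap[np.argmin(abs(x - 6.5))] * 1e3:.2f} um")
print(f"narrowest gap          : {gap.min() * 1e3:.2f} um (clamped asperity film)")

# The nominal aperture is the wedge alone (tan(alpha) * L, about 4.5 um).
# Roughness widens the mouth by the peak-to-valley height where a valley
# faces the bore, and the clamp keeps a 0.1 um electrolyte film where the
# highest asperity touches it.
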