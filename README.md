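# crevsim

An IR-drop crevice-corrosion simulator for the conical taper (trunnion/bore)
junctions of modular hip implants.

Modular implants join a metallic trunnion to a ceramic or metallic bore
through matching cones. A small angular mismatch `α` between the cones
leaves a convergent, micrometre-scale crevice, and crevice corrosion is
often invoked to explain degradation at these junctions — even though the
biomedical alloys involved (Ti6Al4V, CoCrMo) are generally considered
resistant to it. `crevsim` implements a one-dimensional electrochemical
model that decides, from geometry, surface finish and a handful of
electrochemical parameters, whether active crevice corrosion can be
*sustained* at all.

## The model

The local electrolyte gap combines the cone wedge with the machined surface
profile `y_p(x)` (centerline-averaged, maximum height `C`):

```
y_g(x) = tan(α) (L − x) + C − y_p(x)
```

with `x` the depth from the crevice mouth and `L` the crevice length. The
electrolyte column is discretized into annular segments between the trunnion
(radius `r_int`) and the bore (radius `r_int + y_g`); the cumulative
resistance from the mouth is

```
R(x) = Σ ρ Δx / (π (r_int + y_g)² − π r_int²)
```

with `ρ` the solution resistivity. The passive trunnion wall feeds an anodic
current, cumulative from the mouth,

```
I_pass(x) = i_pass · 2π r_int · x
```

and the ohmic (IR) drop along the electrolyte path sets the local electrode
potential,

```
E(x) = E_out − I_pass(x) · R(x)
```

valid while cathodic currents are negligible (`E(x) ≥ E_corr`). Each depth is
then classified: **passive** where `E > E_pass`, **active** where
`E_corr < E ≤ E_pass` (crevice corrosion can be sustained there), and
**negligible** where `E ≤ E_corr`. Helpers for Tafel extrapolation of
(`E_corr`, `i_corr`) from a polarization curve and for Faraday's-law
depletion budgets round out the toolkit.

## Worked example

Running the bundled alloy scenarios (`python examples/03_alloy_scenarios.py`)
on the reference junction (α = 0.02°, L = 13 mm, r_int = 6 mm, triangular
270 µm-period roughness fixture) prints:

```
FeCr_H2SO4             crevice corrosion sustainable: yes
                       drop @4.5 mm  6819.07 mV | @10 mm 38481.41 mV
                       passive down to 1.63 mm; active corrosion until 1.76 mm, negligible deeper
CoCrMo_NaCl_pH2.3      crevice corrosion sustainable: no
                       drop @4.5 mm    17.27 mV | @10 mm    99.28 mV
Ti6Al4V_NaCl_pH5.6     crevice corrosion sustainable: no
                       drop @4.5 mm     0.11 mV | @10 mm     0.61 mV
```

For the crevice-corrosion-prone FeCr reference alloy in 0.05 M H₂SO₄
(i_pass = 1.8 mA/cm²) the IR drop is large enough to pull `E(x)` through the
active window about 2 mm into the crevice — the model predicts localized
corrosion there, and nowhere else. For CoCrMo (i_pass bounded by the 2 µA/cm²
pseudo-active peak) the drop stays below 100 mV at the 10 mm
reference-electrode position, and for Ti6Al4V (i_pass ≤ 0.01 µA/cm²) it is a
fraction of a millivolt: neither alloy ever reaches its passivation
potential, so crevice corrosion cannot be sustained in either saline
scenario. The same library call behind each line is:

```python
import crevsim as cs
solution = cs.run_scenario(cs.get_preset("CoCrMo_NaCl_pH2.3"))
print(solution.summary())        # verdict, crossings, max drop
solution.to_csv("cocr.csv")      # per-depth x, gap, R, I_pass, E, zone
```

The other examples cover the gap geometry (`01`), the hydronium depletion
budget (`02`), design-sensitivity sweeps over mismatch angle and roughness
scale (`04`), and Tafel extrapolation (`05`). A thin CLI wraps the same
functions, e.g.:

```sh
crevsim run --preset Ti6Al4V_NaCl_pH5.6 --out out/
crevsim sweep --param angle --values 0.02,0.01,0.005 --preset CoCrMo_NaCl_pH2.3
crevsim faraday --volume-cm3 5e-3 --conc-m 0.1 --current-ma-cm2 0.5 --area-cm2 5
```

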