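# Methods

## Model

`crevsim` implements a steady-state, one-dimensional ohmic-drop model of
crevice corrosion in a convergent conical crevice, in the tradition of
Pickering's IR-drop mechanism for active–passive metals. The physics is
deliberately minimal: the crevice electrolyte is a resistive path, the
passive crevice wall is a distributed anodic current source, and the local
electrode potential is the outer (applied) potential minus the cumulative
ohmic loss. Transient crevice chemistry (oxygen depletion, pH drift),
cathodic kinetics inside the crevice, repassivation kinetics and 2-D/3-D
current distribution are all outside the model's scope; what it answers is
whether, given the geometry and the alloy's passivation parameters, an
active-dissolution window can exist at all.

### Gap construction

The gap at depth `x` from the crevice mouth is

    y_g(x) = tan(α) (L − x) + C − y_p(x)

where `α` is the cone mismatch angle, `L` the crevice length, `y_p` the
machined roughness profile after centerline normalization (zero mean) and
`C = max(y_p)`. The coordinate convention is `x = 0` at the mouth and
`x = L` at the closed end, which makes the wedge term widest at the mouth —
the geometry of a trunnion pressed into a slightly steeper bore. With
`C = max(y_p)` the analytic gap is non-negative; where the highest asperity
nominally touches the bore the gap is clamped to a floor (default 0.1 µm)
representing an asperity-scale residual electrolyte film and keeping segment
resistances finite.

Measured profiles are reduced to a repeating unit by cutting consecutive
full periods from the trace, rotating each to start at its maximum sample,
averaging point-wise (three periods by default, to suppress measurement
noise) and re-centering; the unit is then tiled over the full crevice
length. Synthetic profiles are generated directly over `[0, L]`.

### Resistance, current, potential

Each grid segment of length `dx` contributes an annular resistance
`ρ·dx / (π (r_int + y_g)² − π r_int²)`; segments use the midpoint gap of
their two bounding samples, and cumulative sums give `R(x)` with `R(0) = 0`.
The anodic current attributed to depth `x` is the passive current density
integrated over the inner-cylinder wall from the mouth to `x`,
`I_pass(x) = i_pass · 2π r_int · x`. This cumulative-from-mouth reading
matches the "area of the inner cylinder at each gap distance" formulation;
the alternative reading (current generated by the wall deeper than `x`,
proportional to `L − x`) is available behind `passive_current(...,
mode="beyond_x")` but is not the default. The potential profile is
`E(x) = E_out − I_pass(x)·R(x)` (mA × Ω = mV, stored in V). Samples with
`E < E_corr` violate the net-anodic-current assumption; they are reported
unchanged but flagged as outside the validity domain rather than truncated.

### Zone classification

Per-sample labels follow the sustainment criterion with a closed upper and
open lower bound: *passive* for `E > E_pass`, *active* for
`E_corr < E ≤ E_pass`, *negligible* for `E ≤ E_corr`. Crevice corrosion is
judged sustainable iff any active sample exists. Threshold crossing depths
are located by linear interpolation between adjacent grid samples so that
reported depths are grid-independent at the default resolution.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `α` | 0.02° | cone mismatch angle of the reference junction |
| `L` | 13 mm | crevice length |
| `r_int` | 6 mm | trunnion radius (taper of ~5 µm over L neglected) |
| `dx` | 1 µm | depth grid step; resolves the 270 µm machining period with 270 samples |
| `gap_floor` | 0.1 µm | residual electrolyte film at asperity contact |
| profile period | 0.27 mm | peak-to-peak periodicity of the machined thread |
| profile amplitude | 15 µm | half peak-to-valley of the triangle fixture |
| `ρ` | from Table of solutions, `ρ = 10⁴/κ` | electrolyte resistivity, Ω·mm (κ in mS/cm) |
| Faraday constant | 96485 C/mol | with z = 1 for H⁺ + e⁻ → ½H₂ |

Current densities are user-facing in mA/cm² and converted to mA/mm²
(×0.01) internally so that all geometric factors stay in millimetres;
mA × Ω products are millivolts.

Material presets: FeCr (15% Cr stainless, 0.05 M H₂SO₄) uses
`E_pass = −0.37 V`, `i_pass = 1.8 mA/cm²`, `E_corr = −0.5 V`, `E_out = 0.5 V`
(all vs Ag/AgCl), read off its polarization curve. Ti6Al4V and CoCrMo show
no distinct active–passive transition in saline, so their parameters are
literature bounds: Ti `i_pass = 0.01 µA/cm²` (an upper limit from
dilute-H₂SO₄ data) with `E_pass = −0.75 V`; CoCrMo `i_pass = 2 µA/cm²` with
`E_pass = −0.9 V` from the pseudo-active peak occasionally reported in PBS.
Their `E_corr` values are nominal open-circuit placeholders (−1.0 V) below
`E_pass`; they anchor the zone classification, which these scenarios never
reach, and no quantitative claim depends on them. Applied potentials follow
the experimental protocol: FeCr 0.5 V; CoCrMo −0.1 and 0.5 V at pH 2.3 and
−0.1 V at pH 5.6; Ti 0.3 V at pH 2.3 and 0.5 V at pH 5.6. Preset
electrolytes derive ρ from the measured conductivities (H₂SO₄ 28.3 mS/cm →
353.4 Ω·mm; NaCl 17.1 and 14.0 mS/cm); the round figure of 350 Ω·mm can be
supplied explicitly via `Electrolyte.from_resistivity` or the
`resistivity_ohm_mm` config key.

## Synthetic roughness fixture

The generator emulates the fine-machined thread pattern of real trunnions as
a periodic line profile: a triangle wave (machining-thread-like; sine and a
seeded jittered variant are also available) with 0.27 mm period, starting at
its peak to match the anchoring convention used when averaging measured
periods. It does *not* emulate 2-D/3-D topography, waviness at scales longer
than the period, plastic flattening of asperities under assembly load, or
stochastic roughness at scales below the grid step. Consequently, passing
tests show that the pipeline propagates a controlled topography correctly;
they do not certify absolute gap values for any particular physical
trunnion, whose profile must be measured and supplied as a file.

The default amplitude (half peak-to-valley) is 15 µm, a mid-range plausible
thread height for such surfaces. For the FeCr scenario the measured profile
is available only graphically, so its amplitude is a calibration parameter
constrained to a plausible 10–25 µm band; the shipped FeCr preset uses
25 µm, the value in that band that places the predicted active-corrosion
site closest to the experimentally observed one (~2 mm from the mouth).
Within the band the predicted E_corr crossing moves from ≈1.35 mm (10 µm) to
≈1.76 mm (25 µm) — the location of the active window is robust at the
millimetre scale, its exact depth is not better determined than the profile
amplitude itself.

## Numerical choices

- Midpoint-gap segments: each segment resistance uses the average of its two
  bounding gap samples. On a smooth cone the summed resistance agrees with
  the closed-form antiderivative of the annulus integrand to better than
  0.1% at `dx = 1 µm` and converges under grid halving; over the triangle
  profile the narrowest samples dominate and halving `dx` still moves
  `R(L)` by well under 1%.
- The gap floor bounds the worst-case segment resistance; it only affects
  the last ~0.3 mm of the reference geometry, where the wedge term falls
  below 0.1 µm at profile peaks.
- Crossings are interpolated linearly; exact threshold equality follows the
  closed/open zone convention (a sample exactly at `E_pass` is active, one
  exactly at `E_corr` is negligible).
- Tafel windows are user-supplied potential ranges; each must contain at
  least five samples of the correct current sign. No automatic
  linear-region detection is attempted — choosing Tafel regions robustly is
  a problem in its own right. Near-parallel fitted lines raise a numerical
  error with the two slopes in the diagnostic.
- Degenerate inputs are rejected early: non-uniform profile grids,
  non-positive gaps reaching the resistance sum, mismatched trace lengths,
  zero/negative physical parameters.

## Determinism

Only the `jittered` profile kind consumes randomness, through a seeded
`numpy` generator (default seed 0); triangle and sine fixtures and the whole
downstream pipeline are deterministic, so repeated runs produce
byte-identical CSV output.

## Known limitations

- Steady state only: the model cannot reproduce incubation times or the
  potential recovery that follows hydronium depletion (the Faraday helpers
  quantify that budget but no kinetics are solved).
- `I_pass(x)·R(x)` multiplies two cumulative quantities; it is a bounding
  approximation to the segment-by-segment ohmic integral rather than a
  solution of the 1-D current-conservation problem.
- Predictions scale linearly with `i_pass`, which for Ti6Al4V and CoCrMo is
  bounded rather than measured; conclusions for those alloys are robust only
  because the bound sits orders of magnitude below values that would matter.
- `r_int` is held constant along the crevice; the metal cone's own taper
  (≈4.5 µm over 13 mm) is neglected.
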