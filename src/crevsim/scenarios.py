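"""Scenario presets, synthetic roughness fixtures, sweeps and configuration.

A :class:`Scenario` bundles everything one crevice-model run needs: the
crevice geometry, a roughness profile (synthetic or from file), the
electrolyte and the material electrochemistry.  Presets reproduce the
FeCr / Ti6Al4V / CoCrMo study conditions; sweeps vary one design parameter
(mismatch angle or roughness scale) with everything else held fixed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import electrochem, io
from .crevice_model import (
    CreviceSolutionProfile,
    classify_zones,
    cumulative_resistance,
    passive_current,
    potential_profile,
)
from .electrochem import Electrolyte, MaterialElectrochem
from .errors import CrevSimError, InputError
from .geometry import (
    CreviceGeometry,
    SurfaceProfile,
    average_periods,
    build_gap_profile,
    normalize_profile,
    tile_profile,
)

__all__ = [
    "ProfileSpec",
    "Scenario",
    "SweepResult",
    "generate_fixture_profile",
    "resolve_profile",
    "run_scenario",
    "sweep_mismatch_angle",
    "sweep_roughness_scale",
    "SCENARIO_PRESETS",
    "get_preset",
    "scenario_to_config",
    "scenario_from_config",
    "load_scenario",
    "save_scenario",
]

#: machining-pattern repeat length of the reference trunnions, mm
DEFAULT_PERIOD_MM = 0.27
#: default synthetic roughness amplitude (half peak-to-valley), um
DEFAULT_AMPLITUDE_UM = 15.0

_FIXTURE_KINDS = ("triangle", "sine", "jittered")


def generate_fixture_profile(
    kind: str = "triangle",
    period: float = DEFAULT_PERIOD_MM,
    amplitude: float = DEFAULT_AMPLITUDE_UM * 1e-3,
    length: Optional[float] = None,
    seed: int = 0,
    *,
    dx: float = 1e-3,
    jitter: float = 0.1,
) -> SurfaceProfile:
    """Generate a synthetic machined-surface roughness profile.

    Stands in for a measured trunnion topography: a periodic, thread-like
    trace with the stated repeat length.  All lengths in mm.

    Parameters
    ----------
    kind
        ``triangle`` (machining-thread-like, the default), ``sine``, or
        ``jittered`` (triangle plus seeded Gaussian height noise).
    period
        Repeat length, mm.
    amplitude
        Half peak-to-valley height, mm; the maximum height C equals the
        amplitude for the deterministic kinds.
    length
        Axial extent, mm; defaults to one period.
    seed
        Seed for the jittered kind; triangle and sine ignore it.
    dx
        Sampling step, mm.
    jitter
        Noise standard deviation as a fraction of the amplitude
        (jittered kind only).

    Every kind starts at its highest point (peak-first), matching the
    anchoring convention used when averaging measured periods.
    """
    if kind not in _FIXTURE_KINDS:
        raise InputError(f"unknown profile kind {kind!r}; choose from {_FIXTURE_KINDS}")
    if not period > 0:
        raise InputError(f"period must be positive, got {period}")
    if not amplitude > 0:
        raise InputError(f"amplitude must be positive, got {amplitude}")
    if length is None:
        length = period
    if not length > 0:
        raise InputError(f"length must be positive, got {length}")

    n = int(round(length / dx))
    positions = np.arange(n + 1) * dx
    phase = (positions % period) / period
    if kind == "sine":
        heights = amplitude * np.cos(2.0 * np.pi * phase)
    else:
        # triangle: +A at phase 0, -A at phase 1/2, back to +A at phase 1
        heights = amplitude * np.where(phase < 0.5, 1.0 - 4.0 * phase, 4.0 * phase - 3.0)
        if kind == "jittered":
            rng = np.random.default_rng(seed)
            heights = heights + rng.normal(0.0, jitter * amplitude, heights.shape)
            heights = heights - heights.mean()
    return SurfaceProfile(positions, heights, period)


@dataclass(frozen=True)
class ProfileSpec:
    """Declarative description of a roughness profile.

    ``kind`` is one of the synthetic kinds or ``file``; synthetic kinds use
    ``period_mm``/``amplitude_um``/``seed`` and file profiles are read from
    ``path`` (averaging ``n_periods`` measured periods when the trace is
    long enough).
    """

    kind: str = "triangle"
    period_mm: float = DEFAULT_PERIOD_MM
    amplitude_um: float = DEFAULT_AMPLITUDE_UM
    path: Optional[str] = None
    seed: int = 0
    n_periods: int = 3

    def __post_init__(self) -> None:
        if self.kind not in _FIXTURE_KINDS + ("file",):
            raise InputError(f"unknown profile kind {self.kind!r}")
        if self.kind == "file" and not self.path:
            raise InputError("profile kind 'file' requires a path")


@dataclass(frozen=True)
class Scenario:
    """One complete crevice-corrosion case."""

    label: str
    geometry: CreviceGeometry
    profile: Union[ProfileSpec, SurfaceProfile]
    electrolyte: Electrolyte
    material: MaterialElectrochem

    def with_e_out(self, e_out: float) -> "Scenario":
        return replace(self, material=self.material.with_e_out(e_out))

    def with_i_pass(self, i_pass: float) -> "Scenario":
        return replace(self, material=self.material.with_i_pass(i_pass))


def resolve_profile(scenario: Scenario) -> SurfaceProfile:
    """Materialise the scenario's profile over the full crevice length."""
    geom = scenario.geometry
    spec = scenario.profile
    if isinstance(spec, SurfaceProfile):
        if spec.length + spec.dx / 2 >= geom.length:
            return spec
        return tile_profile(spec, geom.length)
    if spec.kind == "file":
        raw = io.read_profile(spec.path, period_mm=spec.period_mm)
        spp = int(round(raw.period / raw.dx))
        if raw.heights.size >= spec.n_periods * spp:
            one_period = average_periods(
                raw, period=raw.period, n_periods=spec.n_periods
            )
        else:
            one_period = normalize_profile(raw)
        return tile_profile(one_period, geom.length)
    return generate_fixture_profile(
        kind=spec.kind,
        period=spec.period_mm,
        amplitude=spec.amplitude_um * 1e-3,
        length=geom.length,
        seed=spec.seed,
        dx=geom.dx,
    )


def run_scenario(scenario: Scenario) -> CreviceSolutionProfile:
    """Run the full pipeline: profile -> gap -> R(x) -> I_pass(x) -> E(x) -> zones.

    Deterministic: identical inputs (including the profile seed) give
    identical outputs.
    """
    try:
        profile = resolve_profile(scenario)
        gap = build_gap_profile(scenario.geometry, profile)
        resistance = cumulative_resistance(scenario.geometry, scenario.electrolyte, gap)
        current = passive_current(
            scenario.material.i_pass_mA_mm2,
            scenario.geometry.r_int,
            profile.positions,
        )
        potential = potential_profile(scenario.material, resistance, current)
        return classify_zones(
            profile.positions,
            potential,
            scenario.material,
            gap=gap,
            resistance=resistance,
            current=current,
        )
    except CrevSimError as exc:
        raise type(exc)(f"scenario {scenario.label!r}: {exc}") from exc


@dataclass(frozen=True)
class SweepResult:
    """Per-value summaries of a one-parameter sweep, in input order."""

    parameter: str
    values: tuple
    summaries: tuple
    solutions: tuple = field(repr=False, default=())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for value, summary in zip(self.values, self.summaries):
            rows.append({self.parameter: value, **summary})
        return pd.DataFrame(rows)


def _summarize(solution: CreviceSolutionProfile) -> dict:
    return solution.summary()


def sweep_mismatch_angle(base: Scenario, angles: Sequence[float]) -> SweepResult:
    """Re-run the base scenario at each mismatch angle, all else fixed.

    Narrower wedges (smaller angles) raise the electrolyte resistance and
    the ohmic drop at every depth.
    """
    angles = list(angles)
    if any(a <= 0 for a in angles):
        raise InputError("mismatch angles must be positive")
    if len(set(angles)) != len(angles):
        raise InputError("mismatch angles must be distinct")
    solutions = []
    for a in angles:
        scenario = replace(
            base,
            label=f"{base.label}_alpha{a:g}",
            geometry=replace(base.geometry, alpha_deg=a),
        )
        solutions.append(run_scenario(scenario))
    return SweepResult(
        parameter="alpha_deg",
        values=tuple(angles),
        summaries=tuple(_summarize(s) for s in solutions),
        solutions=tuple(solutions),
    )


def sweep_roughness_scale(base: Scenario, scales: Sequence[float]) -> SweepResult:
    """Re-run the base scenario with profile heights scaled by each factor.

    The scaled profile is re-centred on its mean and C recomputed before the
    run.  Smoother surfaces (factors < 1) leave less interstitial space, so
    the drop grows at every depth.
    """
    scales = list(scales)
    if any(s <= 0 for s in scales):
        raise InputError("roughness scale factors must be positive")
    base_profile = resolve_profile(base)
    solutions = []
    for s in scales:
        scenario = replace(
            base, label=f"{base.label}_scale{s:g}", profile=base_profile.scaled(s)
        )
        solutions.append(run_scenario(scenario))
    return SweepResult(
        parameter="roughness_scale",
        values=tuple(scales),
        summaries=tuple(_summarize(s) for s in solutions),
        solutions=tuple(solutions),
    )


# ---------------------------------------------------------------------------
# Presets
#
# Geometry: the reference junction (alpha 0.02 deg, L 13 mm, r_int 6 mm).
# Profile: triangle fixture, 0.27 mm period.  Ti and CoCrMo use the default
# 15 um amplitude.  The FeCr trunnion's measured profile is only available
# graphically, so its amplitude is a calibration parameter constrained to
# 10-25 um; 25 um is shipped because it places the predicted corrosion site
# closest to the observed one (~2 mm from the mouth).
# ---------------------------------------------------------------------------

REFERENCE_GEOMETRY = CreviceGeometry(alpha_deg=0.02, length=13.0, r_int=6.0)

_FIXTURE = ProfileSpec(kind="triangle")
_FIXTURE_FECR = ProfileSpec(kind="triangle", amplitude_um=25.0)


def _preset(label: str, profile: ProfileSpec) -> Scenario:
    ep = electrochem.PRESETS[label]
    return Scenario(
        label=label,
        geometry=REFERENCE_GEOMETRY,
        profile=profile,
        electrolyte=ep.electrolyte,
        material=ep.material,
    )


SCENARIO_PRESETS: dict[str, Scenario] = {
    "FeCr_H2SO4": _preset("FeCr_H2SO4", _FIXTURE_FECR),
    "CoCrMo_NaCl_pH2.3": _preset("CoCrMo_NaCl_pH2.3", _FIXTURE),
    "CoCrMo_NaCl_pH5.6": _preset("CoCrMo_NaCl_pH5.6", _FIXTURE),
    "Ti6Al4V_NaCl_pH2.3": _preset("Ti6Al4V_NaCl_pH2.3", _FIXTURE),
    "Ti6Al4V_NaCl_pH5.6": _preset("Ti6Al4V_NaCl_pH5.6", _FIXTURE),
}


def get_preset(name: str, e_out: Optional[float] = None) -> Scenario:
    """Fetch a named scenario preset, optionally overriding the applied
    potential (the CoCrMo pH 2.3 case was tested at both -0.1 and 0.5 V)."""
    try:
        scenario = SCENARIO_PRESETS[name]
    except KeyError:
        raise InputError(
            f"unknown preset {name!r}; available: {sorted(SCENARIO_PRESETS)}"
        ) from None
    if e_out is not None:
        options = electrochem.PRESETS[name].e_out_options
        if e_out not in options:
            raise InputError(
                f"preset {name!r} was characterised at E_out in {options}, "
                f"not {e_out} V; build a custom Scenario to go outside them"
            )
        scenario = scenario.with_e_out(e_out)
    return scenario


# ---------------------------------------------------------------------------
# Configuration round-trip (YAML-style key tree)
# ---------------------------------------------------------------------------


def scenario_to_config(scenario: Scenario) -> dict:
    if isinstance(scenario.profile, SurfaceProfile):
        raise InputError(
            "only declarative profiles (ProfileSpec) can be serialised to config"
        )
    return {
        "label": scenario.label,
        "geometry": {
            "alpha_deg": scenario.geometry.alpha_deg,
            "length_mm": scenario.geometry.length,
            "r_int_mm": scenario.geometry.r_int,
            "dx_mm": scenario.geometry.dx,
            "gap_floor_mm": scenario.geometry.gap_floor,
        },
        "profile": {k: v for k, v in asdict(scenario.profile).items() if v is not None},
        "electrolyte": {
            "conductivity_mS_cm": scenario.electrolyte.conductivity,
            "ph": scenario.electrolyte.ph,
        },
        "material": {
            "name": scenario.material.name,
            "e_pass_V": scenario.material.e_pass,
            "i_pass_mA_cm2": scenario.material.i_pass,
            "e_corr_V": scenario.material.e_corr,
            "e_out_V": scenario.material.e_out,
        },
    }


def scenario_from_config(config: dict) -> Scenario:
    try:
        geo = config["geometry"]
        mat = config["material"]
        ely = config["electrolyte"]
        geometry = CreviceGeometry(
            alpha_deg=geo["alpha_deg"],
            length=geo.get("length_mm", 13.0),
            r_int=geo.get("r_int_mm", 6.0),
            dx=geo.get("dx_mm", 1e-3),
            gap_floor=geo.get("gap_floor_mm", 1e-4),
        )
        profile = ProfileSpec(**config.get("profile", {}))
        if "resistivity_ohm_mm" in ely:
            electrolyte = Electrolyte.from_resistivity(
                ely["resistivity_ohm_mm"], ely.get("ph", 7.0)
            )
        else:
            electrolyte = Electrolyte(
                conductivity=ely["conductivity_mS_cm"], ph=ely.get("ph", 7.0)
            )
        material = MaterialElectrochem(
            name=mat.get("name", "custom"),
            e_pass=mat["e_pass_V"],
            i_pass=mat["i_pass_mA_cm2"],
            e_corr=mat["e_corr_V"],
            e_out=mat["e_out_V"],
        )
    except KeyError as exc:
        raise InputError(f"config is missing required key {exc}") from exc
    return Scenario(
        label=config.get("label", "scenario"),
        geometry=geometry,
        profile=profile,
        electrolyte=electrolyte,
        material=material,
    )


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise InputError(f"{path}: config must be a mapping")
    return scenario_from_config(config)


def save_scenario(scenario: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_config(scenario), sort_keys=False))
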