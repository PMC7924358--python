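"""Electrochemical parameters, polarization-curve analysis and Faraday helpers.

Potentials are in V vs Ag/AgCl (the saturated Ag/AgCl electrode sits at
+205 mV vs SHE); user-facing current densities are in mA/cm^2, the field's
conventional unit, and are converted to mA/mm^2 where they meet the
millimetre-based geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .errors import InputError, NumericalError

__all__ = [
    "FARADAY",
    "MaterialElectrochem",
    "Electrolyte",
    "PolarizationCurve",
    "ElectrochemPreset",
    "PRESETS",
    "resistivity_from_conductivity",
    "conductivity_from_resistivity",
    "hydronium_inventory",
    "faraday_flux",
    "depletion_time",
    "tafel_extrapolate",
]

#: Faraday constant, C/mol
FARADAY = 96485.0


@dataclass(frozen=True)
class MaterialElectrochem:
    """Electrochemical fingerprint of one alloy/solution pair.

    e_pass
        Passivation potential, V vs Ag/AgCl.  Above it the surface is
        passive; between ``e_corr`` and ``e_pass`` the metal dissolves
        actively.
    i_pass
        Passive current density, mA/cm^2 (must be positive).
    e_corr
        Corrosion potential, V vs Ag/AgCl; below it net anodic dissolution
        is negligible.
    e_out
        Potential established or applied at the metal surface outside the
        crevice, V vs Ag/AgCl.
    """

    name: str
    e_pass: float
    i_pass: float
    e_corr: float
    e_out: float

    def __post_init__(self) -> None:
        if not self.i_pass > 0:
            raise InputError(f"i_pass must be positive, got {self.i_pass}")
        if self.e_corr > self.e_pass:
            raise InputError(
                f"e_corr ({self.e_corr} V) must not exceed e_pass "
                f"({self.e_pass} V): the active domain is delimited by them"
            )
        if self.e_out <= self.e_pass:
            warnings.warn(
                f"{self.name}: e_out ({self.e_out} V) does not exceed e_pass "
                f"({self.e_pass} V); the outer surface is not meaningfully "
                "passive",
                stacklevel=2,
            )

    @property
    def i_pass_mA_mm2(self) -> float:
        """Passive current density in mA/mm^2 (geometry-consistent units)."""
        return self.i_pass * 0.01

    def with_e_out(self, e_out: float) -> "MaterialElectrochem":
        return replace(self, e_out=e_out)

    def with_i_pass(self, i_pass: float) -> "MaterialElectrochem":
        return replace(self, i_pass=i_pass)


@dataclass(frozen=True)
class Electrolyte:
    """Test-solution properties: conductivity (mS/cm), resistivity (Ohm*mm), pH.

    Either quantity determines the other through rho * kappa = 1e4
    (Ohm*mm * mS/cm); supplying both is allowed only if consistent.
    """

    conductivity: float
    ph: float
    rho: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.conductivity > 0:
            raise InputError(
                f"conductivity must be positive, got {self.conductivity}"
            )
        if self.rho is None:
            object.__setattr__(
                self, "rho", resistivity_from_conductivity(self.conductivity)
            )
        else:
            if not self.rho > 0:
                raise InputError(f"rho must be positive, got {self.rho}")
            if abs(self.rho * self.conductivity - 1e4) > 1e-6 * 1e4:
                raise InputError(
                    f"inconsistent electrolyte: rho*kappa = "
                    f"{self.rho * self.conductivity:g}, expected 1e4"
                )

    @classmethod
    def from_resistivity(cls, rho: float, ph: float) -> "Electrolyte":
        if not rho > 0:
            raise InputError(f"rho must be positive, got {rho}")
        return cls(conductivity=1e4 / rho, ph=ph, rho=rho)


@dataclass(frozen=True)
class PolarizationCurve:
    """A potentiodynamic sweep: potential (V vs Ag/AgCl) vs signed current
    density (mA/cm^2, anodic positive)."""

    potentials: np.ndarray
    current_densities: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.potentials, dtype=float)
        i = np.asarray(self.current_densities, dtype=float)
        if e.shape != i.shape or e.ndim != 1:
            raise InputError("potentials and current densities must be equal-length 1-D")
        if e.size < 10:
            raise InputError(f"a polarization curve needs >= 10 samples, got {e.size}")
        de = np.diff(e)
        if not (np.all(de > 0) or np.all(de < 0)):
            raise InputError("potentials must be a monotone sweep")
        object.__setattr__(self, "potentials", e)
        object.__setattr__(self, "current_densities", i)


def resistivity_from_conductivity(kappa: float) -> float:
    """Convert conductivity (mS/cm) to resistivity (Ohm*mm): rho = 1e4 / kappa."""
    if not kappa > 0:
        raise InputError(f"conductivity must be positive, got {kappa}")
    return 1e4 / kappa


def conductivity_from_resistivity(rho: float) -> float:
    """Inverse of :func:`resistivity_from_conductivity`."""
    if not rho > 0:
        raise InputError(f"resistivity must be positive, got {rho}")
    return 1e4 / rho


def hydronium_inventory(volume_cm3: float, concentration_M: float) -> float:
    """Moles of hydronium held in a crevice volume.

    ``volume_cm3`` in cm^3, ``concentration_M`` in mol/L.
    """
    if not volume_cm3 > 0:
        raise InputError(f"volume must be positive, got {volume_cm3}")
    if not concentration_M > 0:
        raise InputError(f"concentration must be positive, got {concentration_M}")
    return volume_cm3 * 1e-3 * concentration_M


def faraday_flux(current_density: float, electrons_per_ion: int = 1) -> float:
    """Convert a current density to a molar flux via Faraday's law.

    ``current_density`` in mA/cm^2; returns mol/(s*cm^2).  For proton
    reduction (H+ + e- -> 1/2 H2) one electron is transferred per ion.
    """
    if not current_density > 0:
        raise InputError(f"current density must be positive, got {current_density}")
    if electrons_per_ion < 1:
        raise InputError(f"electrons_per_ion must be >= 1, got {electrons_per_ion}")
    return (current_density * 1e-3) / (electrons_per_ion * FARADAY)


class DepletionResult(NamedTuple):
    time_s: float
    total_rate_mol_s: float


def depletion_time(inventory: float, flux: float, area_cm2: float) -> DepletionResult:
    """Time to consume an ion inventory at a given areal reaction flux.

    ``inventory`` in mol, ``flux`` in mol/(s*cm^2), ``area_cm2`` in cm^2.
    Returns the depletion time (s) and the total consumption rate (mol/s).
    """
    if inventory < 0:
        raise InputError(f"inventory must be non-negative, got {inventory}")
    if not flux > 0:
        raise InputError(f"flux must be positive, got {flux}")
    if not area_cm2 > 0:
        raise InputError(f"area must be positive, got {area_cm2}")
    rate = flux * area_cm2
    return DepletionResult(time_s=inventory / rate, total_rate_mol_s=rate)


class TafelResult(NamedTuple):
    e_corr: float
    i_corr: float
    anodic_slope: float   # V/decade
    cathodic_slope: float  # V/decade


def tafel_extrapolate(
    curve: PolarizationCurve,
    anodic_window: tuple[float, float],
    cathodic_window: tuple[float, float],
) -> TafelResult:
    """Estimate (E_corr, i_corr) by Tafel extrapolation.

    Straight lines are fitted to log10|i| vs E inside each user-supplied
    potential window; their intersection gives the corrosion potential and
    corrosion current density.  The anodic window must contain net anodic
    (positive) current, the cathodic window net cathodic (negative) current,
    i.e. the windows lie on opposite sides of the zero crossing.
    """
    e = curve.potentials
    i = curve.current_densities

    def _fit(window, branch):
        lo, hi = sorted(window)
        mask = (e >= lo) & (e <= hi) & (np.abs(i) > 0)
        if mask.sum() < 5:
            raise InputError(
                f"{branch} window [{lo}, {hi}] V contains {int(mask.sum())} "
                "usable samples; >= 5 are required"
            )
        sign = 1.0 if branch == "anodic" else -1.0
        if np.median(np.sign(i[mask])) != sign:
            raise InputError(
                f"{branch} window [{lo}, {hi}] V does not lie on the "
                f"{branch} side of the zero crossing"
            )
        slope, intercept = np.polyfit(e[mask], np.log10(np.abs(i[mask])), 1)
        if not (np.isfinite(slope) and np.isfinite(intercept)):
            raise NumericalError(f"{branch} Tafel fit is degenerate")
        return slope, intercept

    m_a, b_a = _fit(anodic_window, "anodic")
    m_c, b_c = _fit(cathodic_window, "cathodic")
    if abs(m_a - m_c) < 1e-9:
        raise NumericalError(
            f"Tafel lines are parallel (slopes {m_a:.4g} and {m_c:.4g} "
            "decade/V); no intersection"
        )
    e_corr = (b_c - b_a) / (m_a - m_c)
    i_corr = 10.0 ** (m_a * e_corr + b_a)
    return TafelResult(
        e_corr=float(e_corr),
        i_corr=float(i_corr),
        anodic_slope=1.0 / m_a,
        cathodic_slope=1.0 / m_c,
    )


# ---------------------------------------------------------------------------
# Presets: alloy/solution pairs used in the trunnion crevice study.
#
# FeCr (AISI430-type, 15 wt.% Cr) in 0.05 M H2SO4 shows a clear
# active-passive transition, read off its polarization curve.  Ti6Al4V and
# CoCrMo show no distinct transition in NaCl; their (E_pass, i_pass) are
# literature bounds: Ti from dilute-H2SO4 data (0.01 uA/cm^2 as an upper
# limit, E_pass -0.75 V), CoCrMo from the pseudo-active peak reported in PBS
# (2 uA/cm^2 at -0.9 V).  E_corr for Ti and CoCrMo is a nominal open-circuit
# value below E_pass; it only anchors the zone classification, which these
# scenarios never reach.
# ---------------------------------------------------------------------------

H2SO4_PH1_5 = Electrolyte(conductivity=28.3, ph=1.5)
NACL_PH2_3 = Electrolyte(conductivity=17.1, ph=2.3)
NACL_PH5_6 = Electrolyte(conductivity=14.0, ph=5.6)

FECR = MaterialElectrochem("FeCr", e_pass=-0.37, i_pass=1.8, e_corr=-0.5, e_out=0.5)
COCRMO = MaterialElectrochem(
    "CoCrMo", e_pass=-0.9, i_pass=2e-3, e_corr=-1.0, e_out=0.5
)
TI6AL4V = MaterialElectrochem(
    "Ti6Al4V", e_pass=-0.75, i_pass=1e-5, e_corr=-1.0, e_out=0.5
)


@dataclass(frozen=True)
class ElectrochemPreset:
    """Bundle of material + electrolyte + the applied potentials tested."""

    material: MaterialElectrochem
    electrolyte: Electrolyte
    e_out_options: tuple[float, ...]


PRESETS: dict[str, ElectrochemPreset] = {
    "FeCr_H2SO4": ElectrochemPreset(FECR, H2SO4_PH1_5, (0.5,)),
    "CoCrMo_NaCl_pH2.3": ElectrochemPreset(
        COCRMO, NACL_PH2_3, (-0.1, 0.5)
    ),
    "CoCrMo_NaCl_pH5.6": ElectrochemPreset(
        COCRMO.with_e_out(-0.1), NACL_PH5_6, (-0.1,)
    ),
    "Ti6Al4V_NaCl_pH2.3": ElectrochemPreset(
        TI6AL4V.with_e_out(0.3), NACL_PH2_3, (0.3,)
    ),
    "Ti6Al4V_NaCl_pH5.6": ElectrochemPreset(TI6AL4V, NACL_PH5_6, (0.5,)),
}
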