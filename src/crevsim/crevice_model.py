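"""One-dimensional IR-drop model of crevice corrosion in a conical junction.

The crevice electrolyte is treated as a chain of resistive annular segments.
Each depth increment dx contributes

    R_i = rho * dx / (pi * ((r_int + y_g)^2 - r_int^2))

where the annulus between the trunnion (radius ``r_int``) and the bore
(radius ``r_int + y_g``) is the conducting cross-section.  Summing segments
from the mouth gives the cumulative electrolyte resistance R(x).

The passive trunnion wall feeds an anodic current; the current attributed to
depth x is the passive current density times the lateral cylinder area from
the mouth to x,

    I_pass(x) = i_pass * 2 * pi * r_int * x,

and the ohmic potential drop shifts the local electrode potential to

    E(x) = E_out - I_pass(x) * R(x).

The model is a net-anodic-current approximation: it is valid for
E(x) >= E_corr, and samples below E_corr are reported but flagged as lying
outside the validity domain.  Crevice corrosion can be sustained wherever
E(x) falls below E_pass while staying above E_corr (the active zone).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .electrochem import Electrolyte, MaterialElectrochem
from .errors import InputError
from .geometry import CreviceGeometry

__all__ = [
    "CreviceSolutionProfile",
    "segment_resistance",
    "cumulative_resistance",
    "passive_current",
    "potential_profile",
    "classify_zones",
]

ZONE_PASSIVE = "passive"
ZONE_ACTIVE = "active"
ZONE_NEGLIGIBLE = "negligible"


def segment_resistance(rho: float, dx: float, r_int: float, gap) -> np.ndarray | float:
    """Resistance of one annular electrolyte segment, Ohm.

    ``rho`` in Ohm*mm, ``dx``, ``r_int`` and ``gap`` in mm.  ``gap`` may be
    an array.  A zero or negative gap is rejected: gaps must be clamped to
    the geometry's floor upstream.
    """
    if not rho > 0:
        raise InputError(f"rho must be positive, got {rho}")
    if not dx > 0:
        raise InputError(f"dx must be positive, got {dx}")
    if not r_int > 0:
        raise InputError(f"r_int must be positive, got {r_int}")
    gap = np.asarray(gap, dtype=float)
    if np.any(gap <= 0):
        raise InputError("gap must be positive everywhere (clamp to gap_floor first)")
    area = np.pi * ((r_int + gap) ** 2 - r_int**2)
    out = rho * dx / area
    return float(out) if out.ndim == 0 else out


def cumulative_resistance(
    geometry: CreviceGeometry, electrolyte: Electrolyte, gap: np.ndarray
) -> np.ndarray:
    """Cumulative electrolyte resistance R(x) from the mouth, Ohm.

    ``gap`` is the gap trace on the uniform depth grid with step
    ``geometry.dx`` spanning [0, L].  Each segment between two grid samples
    uses the midpoint gap; R(0) = 0 and R is non-decreasing.
    """
    gap = np.asarray(gap, dtype=float)
    if gap.ndim != 1 or gap.size < 2:
        raise InputError("gap trace must be 1-D with at least 2 samples")
    if np.any(gap <= 0):
        raise InputError("gap trace must be positive on [0, L]")
    gap_mid = 0.5 * (gap[1:] + gap[:-1])
    segments = segment_resistance(electrolyte.rho, geometry.dx, geometry.r_int, gap_mid)
    resistance = np.empty_like(gap)
    resistance[0] = 0.0
    np.cumsum(segments, out=resistance[1:])
    return resistance


def passive_current(
    i_pass_mA_mm2: float,
    r_int: float,
    x,
    *,
    mode: str = "from_mouth",
    length: Optional[float] = None,
) -> np.ndarray | float:
    """Cumulative passive (anodic) current at depth x, mA.

    Default reading (``mode="from_mouth"``): the current collected over the
    inner-cylinder lateral area between the mouth and depth x,
    ``i_pass * 2*pi*r_int * x``; it vanishes at the mouth.

    The alternative reading (``mode="beyond_x"``) attributes to x the
    current generated by the wall deeper than x, proportional to (L - x);
    it requires ``length``.
    """
    if not i_pass_mA_mm2 > 0:
        raise InputError(f"i_pass must be positive, got {i_pass_mA_mm2}")
    if not r_int > 0:
        raise InputError(f"r_int must be positive, got {r_int}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InputError("depth x must be non-negative")
    if mode == "from_mouth":
        extent = x
    elif mode == "beyond_x":
        if length is None:
            raise InputError("mode='beyond_x' requires the crevice length")
        extent = length - x
        if np.any(extent < 0):
            raise InputError("depth x must not exceed the crevice length")
    else:
        raise InputError(f"unknown passive-current mode {mode!r}")
    out = i_pass_mA_mm2 * 2.0 * np.pi * r_int * extent
    return float(out) if out.ndim == 0 else out


def potential_profile(
    material: MaterialElectrochem, resistance: np.ndarray, current: np.ndarray
) -> np.ndarray:
    """Potential distribution E(x) = E_out - I_pass(x) * R(x), V vs Ag/AgCl.

    ``resistance`` in Ohm and ``current`` in mA share one grid; their
    product is a drop in mV, converted to V here.
    """
    resistance = np.asarray(resistance, dtype=float)
    current = np.asarray(current, dtype=float)
    if resistance.shape != current.shape:
        raise InputError(
            f"resistance ({resistance.shape}) and current ({current.shape}) "
            "traces do not share a grid"
        )
    return material.e_out - current * resistance * 1e-3


def _interp_crossing(x: np.ndarray, potential: np.ndarray, threshold: float):
    """First depth where the (decreasing) potential reaches ``threshold``,
    located by linear interpolation between adjacent samples; None if the
    potential never reaches it."""
    below = np.nonzero(potential <= threshold)[0]
    if below.size == 0:
        return None
    k = int(below[0])
    if k == 0:
        return float(x[0])
    e0, e1 = potential[k - 1], potential[k]
    return float(x[k - 1] + (e0 - threshold) / (e0 - e1) * (x[k] - x[k - 1]))


@dataclass(frozen=True)
class CreviceSolutionProfile:
    """Per-depth solution of the crevice model plus its zone classification.

    Arrays share one grid: depth ``x`` (mm, from the mouth), gap (mm),
    cumulative resistance (Ohm), cumulative passive current (mA), potential
    (V vs Ag/AgCl) and a zone label per sample.  ``valid`` flags the samples
    where the net-anodic assumption holds (E >= E_corr).
    """

    x: np.ndarray
    gap: np.ndarray
    resistance: np.ndarray
    current: np.ndarray
    potential: np.ndarray
    zone: np.ndarray
    material: MaterialElectrochem
    e_pass_crossing_mm: Optional[float]
    e_corr_crossing_mm: Optional[float]

    @property
    def sustainable(self) -> bool:
        """Whether crevice corrosion can be sustained (any active sample)."""
        return bool(np.any(self.zone == ZONE_ACTIVE))

    @property
    def valid(self) -> np.ndarray:
        """Mask of samples inside the model's validity domain (E >= E_corr)."""
        return self.potential >= self.material.e_corr

    @property
    def max_drop_mV(self) -> float:
        """Largest ohmic potential drop E_out - E(x) along the crevice, mV."""
        return float((self.material.e_out - self.potential.min()) * 1e3)

    def drop_mV(self, depth_mm: float) -> float:
        """Ohmic potential drop at a given depth, mV (linear interpolation)."""
        e = float(np.interp(depth_mm, self.x, self.potential))
        return (self.material.e_out - e) * 1e3

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_mm": self.x,
                "gap_mm": self.gap,
                "R_ohm": self.resistance,
                "Ipass_mA": self.current,
                "E_V": self.potential,
                "zone": self.zone,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> dict:
        verdict = "yes" if self.sustainable else "no"
        return {
            "verdict": f"crevice corrosion sustainable: {verdict}",
            "sustainable": self.sustainable,
            "e_pass_crossing_mm": self.e_pass_crossing_mm,
            "e_corr_crossing_mm": self.e_corr_crossing_mm,
            "max_drop_mV": self.max_drop_mV,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def classify_zones(
    x: np.ndarray,
    potential: np.ndarray,
    material: MaterialElectrochem,
    *,
    gap: Optional[np.ndarray] = None,
    resistance: Optional[np.ndarray] = None,
    current: Optional[np.ndarray] = None,
) -> CreviceSolutionProfile:
    """Label each depth as passive / active / negligible and locate crossings.

    The thresholds follow the sustainment criterion: a sample is *passive*
    when E > E_pass, *active* when E_corr < E <= E_pass (crevice corrosion
    can be sustained there), and *negligible* when E <= E_corr (the anodic
    rate collapses; also outside the model's validity domain).  Crossing
    depths of E_pass and E_corr are located by linear interpolation between
    grid samples.
    """
    x = np.asarray(x, dtype=float)
    potential = np.asarray(potential, dtype=float)
    if x.shape != potential.shape:
        raise InputError("x and potential traces do not share a grid")

    zone = np.full(x.shape, ZONE_ACTIVE, dtype="U10")
    zone[potential > material.e_pass] = ZONE_PASSIVE
    zone[potential <= material.e_corr] = ZONE_NEGLIGIBLE

    placeholder = np.full_like(potential, np.nan)
    return CreviceSolutionProfile(
        x=x,
        gap=placeholder if gap is None else np.asarray(gap, dtype=float),
        resistance=placeholder if resistance is None else np.asarray(resistance, dtype=float),
        current=placeholder if current is None else np.asarray(current, dtype=float),
        potential=potential,
        zone=zone,
        material=material,
        e_pass_crossing_mm=_interp_crossing(x, potential, material.e_pass),
        e_corr_crossing_mm=_interp_crossing(x, potential, material.e_corr),
    )
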