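"""Plain-text readers for profile and polarization-curve files.

Both formats are two-column numeric text, whitespace- or comma-delimited,
with comment lines starting with '#'.  Header keys may be declared in
comments as ``# key: value``; recognised keys are ``units`` (um or mm,
default um) and ``period_mm`` for profile files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .electrochem import PolarizationCurve
from .errors import InputError
from .geometry import SurfaceProfile

__all__ = ["read_two_column", "read_profile", "read_polarization_curve"]

_UNIT_SCALE_MM = {"um": 1e-3, "mm": 1.0}


def read_two_column(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column text file; returns (col1, col2, header dict)."""
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip().lower()] = value.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    if not rows:
        raise InputError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    return data[:, 0], data[:, 1], header


def read_profile(
    path, period_mm: float | None = None, default_units: str = "um"
) -> SurfaceProfile:
    """Load a roughness profile (position, height) into mm.

    The file unit (``# units: um|mm``) defaults to micrometres.  The period
    may come from a ``# period_mm:`` header or the ``period_mm`` argument
    (the argument wins); without either the whole trace is treated as one
    period.
    """
    positions, heights, header = read_two_column(path)
    units = header.get("units", default_units).lower()
    if units not in _UNIT_SCALE_MM:
        raise InputError(f"{path}: unknown units {units!r}; use um or mm")
    scale = _UNIT_SCALE_MM[units]
    if period_mm is None and "period_mm" in header:
        period_mm = float(header["period_mm"])
    positions = positions * scale
    heights = heights * scale
    if period_mm is None:
        dx = positions[1] - positions[0]
        period_mm = positions[-1] - positions[0] + dx
    return SurfaceProfile(positions, heights, period_mm)


def read_polarization_curve(path) -> PolarizationCurve:
    """Load a polarization curve: potential (V) vs current density (mA/cm^2)."""
    potentials, currents, _ = read_two_column(path)
    return PolarizationCurve(potentials, currents)
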