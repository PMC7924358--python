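"""Crevice gap geometry for conical taper junctions.

A male cone (trunnion) inserted into a female cone (bore) with a small
angular mismatch ``alpha`` forms a convergent crevice: the gap is widest at
the mouth and closes toward the deep end.  On top of this nominal wedge the
machined surface of the trunnion carries a periodic roughness/thread
pattern, so the local electrolyte gap is

    y_g(x) = tan(alpha) * (L - x) + C - y_p(x)

with ``x`` the depth measured from the crevice mouth (``x = 0`` at the
mouth, ``x = L`` at the closed end), ``y_p`` the roughness height relative
to the profile centerline and ``C = max(y_p)`` so that the gap is
non-negative where the highest asperity touches the bore.

All lengths in this module are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError

__all__ = [
    "SurfaceProfile",
    "CreviceGeometry",
    "normalize_profile",
    "average_periods",
    "tile_profile",
    "build_gap_profile",
]

#: absolute tolerance (mm) for "uniformly spaced" position grids
SPACING_TOL = 1e-9


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def _check_uniform(positions: np.ndarray) -> float:
    """Validate a strictly increasing, uniformly spaced grid; return the step."""
    if positions.size < 2:
        raise InputError("a surface profile needs at least 2 samples")
    steps = np.diff(positions)
    if np.any(steps <= 0):
        raise InputError("profile positions must be strictly increasing")
    dx = float(steps[0])
    if np.any(np.abs(steps - dx) > SPACING_TOL):
        raise InputError(
            f"profile positions must be uniformly spaced within {SPACING_TOL} mm"
        )
    return dx


@dataclass(frozen=True)
class SurfaceProfile:
    """A sampled surface roughness trace.

    Parameters
    ----------
    positions
        Sample positions along the cone axis, mm, uniformly spaced and
        strictly increasing.
    heights
        Roughness heights ``y_p`` relative to the centerline, mm.
    period
        Repeat length of the machining pattern, mm (0.27 mm for the
        fine-machined trunnions modelled here).
    """

    positions: np.ndarray
    heights: np.ndarray
    period: float

    def __post_init__(self) -> None:
        positions = _as_float_array(self.positions, "positions")
        heights = _as_float_array(self.heights, "heights")
        if positions.shape != heights.shape:
            raise InputError(
                f"positions ({positions.size}) and heights ({heights.size}) "
                "must have the same length"
            )
        _check_uniform(positions)
        if not self.period > 0:
            raise InputError(f"period must be positive, got {self.period}")
        positions.flags.writeable = False
        heights.flags.writeable = False
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "heights", heights)
        object.__setattr__(self, "period", float(self.period))

    @property
    def dx(self) -> float:
        """Sampling step, mm."""
        return float(self.positions[1] - self.positions[0])

    @property
    def c_max(self) -> float:
        """Maximum profile height C, mm (the highest asperity)."""
        return float(self.heights.max())

    @property
    def is_normalized(self) -> bool:
        """Whether the centerline average is zero (within 1e-9 mm)."""
        return abs(float(self.heights.mean())) < 1e-9

    @property
    def length(self) -> float:
        """Axial extent of the trace, mm."""
        return float(self.positions[-1] - self.positions[0])

    def normalized(self) -> "SurfaceProfile":
        """Return a copy with the centerline average subtracted."""
        return replace(self, heights=self.heights - self.heights.mean())

    def scaled(self, factor: float) -> "SurfaceProfile":
        """Return a copy with heights multiplied by ``factor`` and re-centred."""
        if not factor > 0:
            raise InputError(f"scale factor must be positive, got {factor}")
        scaled = self.heights * factor
        return replace(self, heights=scaled - scaled.mean())


@dataclass(frozen=True)
class CreviceGeometry:
    """Geometry of the convergent crevice between trunnion and bore.

    Parameters
    ----------
    alpha_deg
        Mismatch angle between the two cones, degrees (0.02 deg for the
        reference junction).
    length
        Crevice length L from mouth to closed end, mm (13 mm reference).
    r_int
        Inner (trunnion) radius, mm (6 mm reference); the metal taper over
        L is a few micrometres and is neglected.
    dx
        Discretization step of the depth grid, mm.  The default 1 um
        resolves the 270 um machining period with 270 samples.
    gap_floor
        Minimum admissible electrolyte gap, mm.  Where the highest asperity
        nominally touches the bore the analytical gap goes to zero; a
        residual asperity-scale film of 0.1 um is kept so that segment
        resistances stay finite.
    """

    alpha_deg: float
    length: float = 13.0
    r_int: float = 6.0
    dx: float = 1e-3
    gap_floor: float = 1e-4

    def __post_init__(self) -> None:
        if not self.alpha_deg > 0:
            raise InputError(f"alpha_deg must be positive, got {self.alpha_deg}")
        if not self.length > 0:
            raise InputError(f"length must be positive, got {self.length}")
        if not self.r_int > 0:
            raise InputError(f"r_int must be positive, got {self.r_int}")
        if not 0 < self.dx <= self.length:
            raise InputError(f"dx must satisfy 0 < dx <= length, got {self.dx}")
        if not self.gap_floor > 0:
            raise InputError(f"gap_floor must be positive, got {self.gap_floor}")

    @property
    def tan_alpha(self) -> float:
        return float(np.tan(np.radians(self.alpha_deg)))

    @property
    def nominal_mouth_aperture(self) -> float:
        """Gap at the mouth for a perfectly smooth cone, mm: tan(alpha) * L."""
        return self.tan_alpha * self.length

    def grid(self) -> np.ndarray:
        """Depth grid from the mouth (0) to the closed end (L), mm."""
        n = int(round(self.length / self.dx))
        return np.linspace(0.0, n * self.dx, n + 1)


def normalize_profile(
    heights,
    spacing: float | None = None,
    *,
    positions=None,
    period: float | None = None,
) -> SurfaceProfile:
    """Centre a raw height trace on its mean (centerline average = 0).

    Accepts either a :class:`SurfaceProfile` or a raw height array.  For raw
    arrays the position grid is built from ``spacing`` (default 1 um) unless
    ``positions`` is given explicitly; ``period`` defaults to the full trace
    length (one period).

    Idempotent: normalizing an already-normalized profile is a no-op.
    """
    if isinstance(heights, SurfaceProfile):
        return heights.normalized()
    h = _as_float_array(heights, "heights")
    if h.size < 2:
        raise InputError("a surface profile needs at least 2 samples")
    if positions is not None:
        pos = _as_float_array(positions, "positions")
        _check_uniform(pos)
        if pos.shape != h.shape:
            raise InputError("positions and heights must have the same length")
    else:
        dx = 1e-3 if spacing is None else float(spacing)
        if not dx > 0:
            raise InputError(f"spacing must be positive, got {dx}")
        pos = np.arange(h.size) * dx
    if period is None:
        period = float(pos[-1] - pos[0] + (pos[1] - pos[0]))
    return SurfaceProfile(pos, h - h.mean(), period)


def average_periods(
    trace,
    period: float = 0.27,
    n_periods: int = 3,
    spacing: float = 1e-3,
) -> SurfaceProfile:
    """Average several machining periods of a measured trace into one.

    Measured roughness traces carry sample-to-sample noise; the repeating
    unit is estimated by cutting the first ``n_periods`` full periods out of
    the trace, re-anchoring each so it starts at its highest sample, and
    averaging them point-wise.  The averaged period is then centred on its
    mean.

    Parameters
    ----------
    trace
        Raw height samples (mm) or a :class:`SurfaceProfile`.
    period
        Repeat length, mm (default 0.27 mm).
    n_periods
        Number of periods to average (default 3).
    spacing
        Sampling step, mm, ignored when ``trace`` is a profile.
    """
    if isinstance(trace, SurfaceProfile):
        spacing = trace.dx
        h = trace.heights
    else:
        h = _as_float_array(trace, "trace")
    if n_periods < 1:
        raise InputError(f"n_periods must be >= 1, got {n_periods}")
    spp = int(round(period / spacing))
    if spp < 2:
        raise InputError(
            f"period {period} mm is not resolved by spacing {spacing} mm"
        )
    if h.size < n_periods * spp:
        raise InputError(
            f"trace has {h.size} samples; {n_periods} periods of {spp} "
            "samples are required"
        )
    anchored = np.empty((n_periods, spp))
    for k in range(n_periods):
        chunk = h[k * spp : (k + 1) * spp]
        anchored[k] = np.roll(chunk, -int(np.argmax(chunk)))
    mean_period = anchored.mean(axis=0)
    return normalize_profile(mean_period, spacing, period=period)


def tile_profile(profile: SurfaceProfile, length_L: float) -> SurfaceProfile:
    """Repeat a one-period profile along the whole crevice length.

    The output spans ``[0, length_L]``; each sample equals the source sample
    at the same position modulo the period.
    """
    if not length_L > 0:
        raise InputError(f"length_L must be positive, got {length_L}")
    dx = profile.dx
    spp = int(round(profile.period / dx))
    if profile.heights.size < spp:
        raise InputError(
            f"profile holds {profile.heights.size} samples, fewer than one "
            f"period ({spp} samples)"
        )
    n = int(round(length_L / dx))
    idx = np.arange(n + 1) % spp
    return SurfaceProfile(np.arange(n + 1) * dx, profile.heights[idx], profile.period)


def build_gap_profile(geometry: CreviceGeometry, profile: SurfaceProfile) -> np.ndarray:
    """Compute the electrolyte gap trace y_g(x) along the crevice.

        y_g(x) = tan(alpha) * (L - x) + C - y_p(x),   C = max(y_p)

    evaluated on the profile's own grid, which must span the full crevice
    length ``[0, L]``.  Gaps below ``geometry.gap_floor`` (the highest
    asperity touching the bore) are clamped to the floor.

    Returns the gap array (mm) aligned with ``profile.positions``.
    """
    x = profile.positions
    if abs(x[0]) > SPACING_TOL or abs(x[-1] - geometry.length) > geometry.dx / 2:
        raise InputError(
            f"profile spans [{x[0]:g}, {x[-1]:g}] mm but the crevice length "
            f"is {geometry.length:g} mm; tile the profile to L first"
        )
    gap = geometry.tan_alpha * (geometry.length - x) + profile.c_max - profile.heights
    return np.maximum(gap, geometry.gap_floor)
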