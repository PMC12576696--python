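"""Forward model and inversion for quantitative birefringence microscopy (qBRM).

A thin birefringent sample (myelin) illuminated with linearly polarized
light at angle ``theta`` and imaged through a circular analyzer transmits

    I(theta) = (I0 / 2) * [1 + sin(delta) * sin(2 * (theta - phi))]

where ``delta`` is the phase retardance and ``phi`` the in-plane optic-axis
orientation (periodic over 180 degrees).  Acquiring frames at >= 3 distinct
polarizer angles determines the three unknowns per pixel: the mean level
``I0/2``, the relative retardance ``|sin(delta)|`` and the orientation
``phi``.  The crossed-circular-polarizer mode (CCP) instead transmits
``I0 * sin^2(delta/2)`` independent of orientation.

Orientation convention: degrees counterclockwise from the +x image axis,
modulo 180, on a 0-based pixel grid with the origin at the top-left and y
pointing down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarizationStack",
    "ParameterMap",
    "ColormapSpec",
    "ReconstructionError",
    "forward_intensity",
    "ccp_intensity",
    "reconstruct_parameter_map",
    "render_rgb",
    "hue_to_rgb",
]

#: Orientation is meaningless where the modulation amplitude vanishes;
#: pixels with relative retardance below this floor are masked invalid.
DEFAULT_RETARDANCE_FLOOR = 0.01


class ReconstructionError(ValueError):
    """Raised when a stack cannot be inverted (too few or collapsed angles)."""


def _check_angles(angles_deg: np.ndarray) -> None:
    angles = np.asarray(angles_deg, dtype=float)
    if angles.ndim != 1 or angles.size < 3:
        raise ReconstructionError(
            f"need >= 3 illumination angles, got {angles.size}"
        )
    folded = np.sort(np.mod(angles, 180.0))
    # pairwise-distinct modulo 180: adjacent gaps, plus the wrap-around gap
    gaps = np.diff(folded)
    wrap = 180.0 - (folded[-1] - folded[0])
    if np.any(gaps < 1e-9) or wrap < 1e-9:
        raise ReconstructionError("illumination angles collapse modulo 180")


@dataclass
class PolarizationStack:
    """Co-registered intensity frames, one per illumination polarization angle.

    Parameters
    ----------
    frames:
        Array ``[N, H, W]`` of non-negative intensities.
    angles_deg:
        The N linear-polarization angles of illumination, degrees.
    i0:
        Nominal transmitted intensity scale (scalar or per-pixel ``[H, W]``).
    pixel_size_um:
        Physical pixel pitch in micrometres.
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    i0: float | np.ndarray = 1.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be [N, H, W]")
        if self.frames.shape[0] != self.angles_deg.size:
            raise ValueError("one angle per frame required")
        _check_angles(self.angles_deg)
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frames must be non-negative")


@dataclass
class ParameterMap:
    """Per-pixel relative retardance |sin delta| and optic-axis orientation."""

    retardance_rel: np.ndarray
    orientation_deg: np.ndarray
    validity_mask: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.retardance_rel = np.asarray(self.retardance_rel, dtype=float)
        self.orientation_deg = np.asarray(self.orientation_deg, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if not (
            self.retardance_rel.shape
            == self.orientation_deg.shape
            == self.validity_mask.shape
        ):
            raise ValueError("field shapes must agree")


@dataclass
class ColormapSpec:
    """Orientation color wheel: hue = ``hue_per_degree`` * orientation.

    With the default two hue-degrees per orientation-degree the wheel
    completes one full cycle per 180 degrees of orientation, so a cyclic
    RGB channel permutation equals a +60 degree orientation shift.
    """

    period_deg: float = 180.0
    hue_per_degree: float = 2.0


def forward_intensity(retardance_rel, orientation_deg, angle_deg, i0=1.0):
    """Intensity under the rotating-polarizer / circular-analyzer model.

    ``I = (i0/2) * [1 + s * sin(2*(theta - phi))]`` with
    ``s = |sin delta|`` the relative retardance.  Vectorized over pixels.
    """
    s = np.asarray(retardance_rel, dtype=float)
    phi = np.deg2rad(np.asarray(orientation_deg, dtype=float))
    theta = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return (np.asarray(i0, dtype=float) / 2.0) * (
        1.0 + s * np.sin(2.0 * (theta - phi))
    )


def ccp_intensity(delta_deg, i0=1.0):
    """Crossed-circular-polarizer intensity ``i0 * sin^2(delta/2)``.

    Depends on retardance only: the crossed circular polarizers make the
    transmitted power independent of the in-plane optic-axis orientation.
    """
    delta = np.deg2rad(np.asarray(delta_deg, dtype=float))
    return np.asarray(i0, dtype=float) * np.sin(delta / 2.0) ** 2


def reconstruct_parameter_map(
    stack: PolarizationStack,
    retardance_floor: float = DEFAULT_RETARDANCE_FLOOR,
) -> ParameterMap:
    """Invert a multi-angle stack into retardance and orientation maps.

    Per pixel, fits ``I(theta) = c0 + c1*cos(2 theta) + c2*sin(2 theta)``
    by least squares over the N angles (normal equations of the 3-column
    harmonic design, angles weighted equally).  Then

    * ``retardance_rel = sqrt(c1^2 + c2^2) / c0`` clipped to [0, 1]
    * ``orientation = 0.5 * atan2(-c1, c2)`` mapped into [0, 180)

    which round-trips :func:`forward_intensity` exactly on noise-free data.
    Pixels with ``c0 <= 0`` or retardance below ``retardance_floor`` are
    flagged invalid (orientation of a near-isotropic pixel is noise).
    """
    _check_angles(stack.angles_deg)
    theta = np.deg2rad(stack.angles_deg)
    design = np.column_stack(
        [np.ones_like(theta), np.cos(2.0 * theta), np.sin(2.0 * theta)]
    )
    gram = design.T @ design
    if np.linalg.matrix_rank(gram) < 3:
        raise ReconstructionError("rank-deficient harmonic design")
    n, h, w = stack.frames.shape
    flat = stack.frames.reshape(n, -1)
    coeffs = np.linalg.solve(gram, design.T @ flat)  # [3, H*W]
    c0, c1, c2 = (c.reshape(h, w) for c in coeffs)

    amp = np.hypot(c1, c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        retardance = np.where(c0 > 0, amp / np.where(c0 > 0, c0, 1.0), 0.0)
    retardance = np.clip(retardance, 0.0, 1.0)
    orientation = np.mod(np.rad2deg(0.5 * np.arctan2(-c1, c2)), 180.0)
    valid = (c0 > 0) & (retardance >= retardance_floor)
    orientation = np.where(valid, orientation, 0.0)
    return ParameterMap(
        retardance_rel=retardance,
        orientation_deg=orientation,
        validity_mask=valid,
        pixel_size_um=stack.pixel_size_um,
    )


def hue_to_rgb(hue_deg: np.ndarray) -> np.ndarray:
    """Full-saturation, unit-value hue wheel, returned as ``[..., 3]``.

    Piecewise-linear HSV at S = V = 1: channel i peaks at hue 120*i with a
    60-degree plateau on either side.  The three channels are computed from
    hue offsets of exactly 0/120/240 degrees, so a +120 degree hue shift is
    exactly a cyclic channel permutation (R,G,B) -> (B,R,G) whenever the
    shifted hue values themselves are exact.
    """
    hue = np.mod(np.asarray(hue_deg, dtype=float), 360.0)

    def weight(x: np.ndarray) -> np.ndarray:
        x = np.mod(x, 360.0)
        out = np.zeros_like(x)
        out = np.where((x < 60.0) | (x >= 300.0), 1.0, out)
        rising = (x >= 240.0) & (x < 300.0)
        out = np.where(rising, (x - 240.0) / 60.0, out)
        falling = (x >= 60.0) & (x < 120.0)
        out = np.where(falling, (120.0 - x) / 60.0, out)
        return out

    return np.stack([weight(hue), weight(hue - 120.0), weight(hue - 240.0)], axis=-1)


def render_rgb(pmap: ParameterMap, spec: ColormapSpec | None = None) -> np.ndarray:
    """Render a parameter map as the standard qBRM RGB visualization.

    Hue encodes orientation (two hue-degrees per orientation-degree by
    default), the value channel encodes relative retardance, saturation is
    full.  Invalid pixels render black.  Channels are floats in [0, 1].
    """
    spec = spec or ColormapSpec()
    hue = spec.hue_per_degree * pmap.orientation_deg
    rgb = hue_to_rgb(hue)
    value = np.clip(pmap.retardance_rel, 0.0, 1.0)
    value = np.where(pmap.validity_mask, value, 0.0)
    return rgb * value[..., None]
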