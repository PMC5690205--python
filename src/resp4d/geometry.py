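"""Lever-arm geometry of the fiducial frame.

The device couples a central piece resting on the abdomen (longitudinal
coordinate ``Z0``) to pivot points on the body-frame sidewalls (``Zp``)
through rigid bars carrying copper wires.  A vertical displacement ``A0``
of the central piece moves the wire seen in an axial slice at longitudinal
coordinate ``Z`` by

    Az = A0 * (Z - Zp) / (Z0 - Zp)

and conversely the central-piece displacement is recovered from a wire
reading by

    A0 = Az * (Z0 - Zp) / (Z - Zp).

All Z readings must share one longitudinal coordinate system (DICOM or
stereotactic — the frame alignment procedure makes them parallel).  The
rod rotation about the pivot is treated as pure vertical translation at
each slice: amplitudes <= 10 mm over lever arms of hundreds of mm make the
angular correction far below 0.1 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameGeometry",
    "lever_ratio",
    "project_amplitude_to_slice",
    "scale_amplitude_to_central",
    "DEFAULT_GEOMETRY",
]


@dataclass(frozen=True)
class FrameGeometry:
    """Longitudinal geometry of the bar-and-pivot system.

    Parameters
    ----------
    z0_mm
        Longitudinal coordinate of the central piece (attachment point of
        the bars), mm.
    zp_mm
        Longitudinal coordinate of the bar/sidewall contact point (pivot),
        mm.
    bar_length_mm
        Physical bar length, mm; the lever arm cannot exceed it.
    wire_sep_x_mm
        Lateral distance between the left and right wires at a slice, mm
        (used by the simulator to place the wires).
    """

    z0_mm: float
    zp_mm: float
    bar_length_mm: float = 470.0
    wire_sep_x_mm: float = 360.0

    def __post_init__(self) -> None:
        if self.z0_mm == self.zp_mm:
            raise ValueError("z0_mm and zp_mm must differ")
        if abs(self.z0_mm - self.zp_mm) > self.bar_length_mm:
            raise ValueError(
                "lever arm |z0 - zp| exceeds the bar length "
                f"({abs(self.z0_mm - self.zp_mm):g} > {self.bar_length_mm:g} mm)"
            )
        if self.wire_sep_x_mm <= 0:
            raise ValueError("wire_sep_x_mm must be positive")

    @classmethod
    def from_config(cls, cfg: dict) -> "FrameGeometry":
        return cls(**cfg)

    def to_config(self) -> dict:
        return {
            "z0_mm": self.z0_mm,
            "zp_mm": self.zp_mm,
            "bar_length_mm": self.bar_length_mm,
            "wire_sep_x_mm": self.wire_sep_x_mm,
        }


#: Default preset: central piece at stereotactic Z = 580 mm, 470 mm bars
#: pivoting at Z = 110 mm.
DEFAULT_GEOMETRY = FrameGeometry(z0_mm=580.0, zp_mm=110.0)


def lever_ratio(g: FrameGeometry, z_mm: float) -> float:
    """Dimensionless ratio (Z - Zp)/(Z0 - Zp) in (0, 1] for a valid slice.

    Raises ``ValueError`` when the slice coincides with the pivot (no wire
    motion there) or lies outside the span between pivot and central piece
    (the linear model does not extrapolate).
    """
    r = (z_mm - g.zp_mm) / (g.z0_mm - g.zp_mm)
    if not (0.0 < r <= 1.0):
        raise ValueError(
            f"slice z={z_mm:g} mm is outside the lever span "
            f"(zp={g.zp_mm:g}, z0={g.z0_mm:g}]"
        )
    return r


def project_amplitude_to_slice(a0_mm, z_mm: float, g: FrameGeometry):
    """Forward model: central-piece displacement -> wire displacement at Z.

    ``a0_mm`` may be a scalar or array of non-negative displacements (mm).
    """
    a0 = np.asarray(a0_mm, dtype=float)
    if np.any(a0 < 0):
        raise ValueError("displacement must be non-negative")
    out = a0 * lever_ratio(g, z_mm)
    return out if out.ndim else float(out)


def scale_amplitude_to_central(az_mm, z_mm: float, g: FrameGeometry):
    """Inverse model: wire displacement at Z -> central-piece displacement.

    Exact inverse of :func:`project_amplitude_to_slice` (the ratio is a
    single multiplicative factor, so the round-trip is identity to machine
    precision).  Scalar or array input.
    """
    az = np.asarray(az_mm, dtype=float)
    if np.any(az < 0):
        raise ValueError("displacement must be non-negative")
    out = az / lever_ratio(g, z_mm)
    return out if out.ndim else float(out)
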