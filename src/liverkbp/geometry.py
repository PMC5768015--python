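"""Geometric features of the patient anatomy.

The single driver of the knowledge model is RTL, the ratio of PTV volume to
liver volume.  This module also provides the boolean structure arithmetic
needed to form normal liver (liver minus GTV), spacing-aware isotropic margin
expansion for planning risk volumes (cord PRV 5 mm), the lateral offset
between PTV and liver centers used for subgroup analysis, and the
maximum-segment budget rule y = 40 + 50·RTL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dvh import StructureMask
from .errors import CongruenceError, DomainError, EmptyStructureError

__all__ = [
    "GeometricFeatures",
    "compute_rtl",
    "max_segments",
    "subtract_structures",
    "expand_margin",
    "lateral_offset",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (67.5 -> 68)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class GeometricFeatures:
    """Per-patient geometric summary used by the knowledge model."""

    patient_id: str
    rtl: float
    lateral_offset_mm: float
    max_segments: int

    def __post_init__(self) -> None:
        if self.rtl <= 0:
            raise DomainError("rtl must be positive")
        if self.max_segments < 40:
            raise DomainError("max_segments below the formula floor of 40")


def compute_rtl(ptv_volume_cc: float, liver_volume_cc: float) -> float:
    """RTL = PTV volume / liver volume (dimensionless).

    The denominator is the whole liver.  Values above 1.5 are anatomically
    implausible and trigger a warning without being rejected.
    """
    if liver_volume_cc <= 0:
        raise DomainError("liver volume must be positive")
    if ptv_volume_cc < 0:
        raise DomainError("PTV volume must be non-negative")
    rtl = ptv_volume_cc / liver_volume_cc
    if rtl > 1.5:
        warnings.warn(f"rtl = {rtl:.3g} > 1.5 is anatomically implausible", stacklevel=2)
    return rtl


def max_segments(rtl: float) -> int:
    """Maximum number of optimization segments: round(40 + 50·rtl).

    The segment budget grows with the plan complexity proxied by RTL; the
    floor at rtl = 0 is 40 segments.
    """
    if rtl < 0:
        raise DomainError("rtl must be >= 0")
    return round_half_up(40.0 + 50.0 * rtl)


def subtract_structures(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Boolean difference a AND NOT b (e.g. liver minus GTV -> normal liver)."""
    if a.shape != b.shape:
        raise CongruenceError(f"masks {a.shape} and {b.shape} are not congruent")
    return StructureMask(
        name=name or f"{a.name}-{b.name}",
        mask=a.mask & ~b.mask,
        spacing=a.spacing,
    )


def expand_margin(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic physical-distance dilation of a binary structure.

    An output voxel is true iff its center lies within ``margin_mm``
    (Euclidean, spacing-aware) of some true input voxel center; margin 0 is
    the identity.  This is how a planning risk volume (PRV) is grown from an
    organ, e.g. spinal cord + 5 mm.
    """
    if margin_mm < 0:
        raise DomainError("margin must be >= 0")
    if margin_mm == 0 or mask.voxel_count == 0:
        return StructureMask(name=mask.name, mask=mask.mask.copy(), spacing=mask.spacing)
    # EDT of the complement gives, for every voxel, the distance to the
    # nearest true voxel center (0 inside the structure).
    dist = ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)
    return StructureMask(
        name=f"{mask.name}+{margin_mm:g}mm",
        mask=dist <= margin_mm + 1e-9,
        spacing=mask.spacing,
    )


def lateral_offset(ptv: StructureMask, liver: StructureMask, axis: int = 0) -> float:
    """Signed lateral distance (mm) between PTV and liver centers of mass.

    Positive values mean the PTV center lies toward the patient's left of the
    liver center under the default orientation (+axis 0 = patient left); the
    axis is configurable because image orientation conventions vary.
    """
    if ptv.shape != liver.shape:
        raise CongruenceError("PTV and liver masks are not congruent")
    if ptv.voxel_count == 0 or liver.voxel_count == 0:
        raise EmptyStructureError("both masks must be non-empty")
    com_ptv = ndimage.center_of_mass(ptv.mask)
    com_liver = ndimage.center_of_mass(liver.mask)
    return (com_ptv[axis] - com_liver[axis]) * ptv.spacing[axis]
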