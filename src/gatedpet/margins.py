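"""Planning-margin expansion of clinical target volumes.

Two margin recipes are used in liver SBRT planning here:

* BITV + 3 mm isotropic  -> gated planning target volume (PTVg), covering
  set-up uncertainty only (motion already lives in the BITV);
* CTV + 5 mm radial / 10 mm craniocaudal -> conventional PTV, covering both
  set-up uncertainty and respiratory motion.

A "radial r / craniocaudal c" margin is realized as morphological dilation by
the ellipsoid {(dx,dy,dz) : (dx/r)^2 + (dy/r)^2 + (dz/c)^2 <= 1}: margins in
treatment planning are distances, and the ellipsoid is the distance-isotropic
kernel under per-axis scaling. The dilation is computed from the Euclidean
distance transform of the mask complement with the voxel spacing scaled by
the per-axis margin, thresholded at 1 — equivalent to a Minkowski sum with
the voxelized ellipsoid, and exact on anisotropic grids without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import BinaryMask

__all__ = ["MarginSpec", "expand", "make_ptvg", "make_ptv"]

# tolerance on the unit-distance threshold so that voxel offsets exactly on
# the ellipsoid boundary are included regardless of floating-point round-off
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class MarginSpec:
    """Radial (in-plane x/y) and craniocaudal (z) margin in mm."""

    radial_mm: float
    craniocaudal_mm: float

    def __post_init__(self) -> None:
        if self.radial_mm < 0 or self.craniocaudal_mm < 0:
            raise ValueError("margins must be >= 0 mm")

    @property
    def isotropic(self) -> bool:
        return self.radial_mm == self.craniocaudal_mm

    @classmethod
    def iso(cls, mm: float) -> "MarginSpec":
        return cls(mm, mm)


PTVG_MARGIN = MarginSpec.iso(3.0)
PTV_MARGIN = MarginSpec(radial_mm=5.0, craniocaudal_mm=10.0)


def expand(mask: BinaryMask, spec: MarginSpec) -> BinaryMask:
    """Dilate ``mask`` by the ellipsoidal margin kernel; result is a superset.

    Zero margins return the input unchanged. A zero margin along one axis
    with a positive margin along another dilates only along the positive
    axes (degenerate ellipsoid).
    """
    r, c = spec.radial_mm, spec.craniocaudal_mm
    if r == 0 and c == 0:
        return BinaryMask(mask.geometry, mask.values.copy())
    sx, sy, sz = mask.geometry.spacing
    if not mask.values.any():
        return BinaryMask(mask.geometry, mask.values.copy())
    # scaled spacing: distance 1 in transformed space == on the margin ellipsoid.
    # A zero margin on an axis means "infinitely costly to move" along it.
    big = 1e9
    sampling = (
        sx / r if r > 0 else big,
        sy / r if r > 0 else big,
        sz / c if c > 0 else big,
    )
    dist = ndimage.distance_transform_edt(~mask.values, sampling=sampling)
    return BinaryMask(mask.geometry, dist <= 1.0 + _BOUNDARY_EPS)


def make_ptvg(bitv: BinaryMask, margin: MarginSpec = PTVG_MARGIN) -> BinaryMask:
    """Gated planning target volume: BITV + isotropic set-up margin (3 mm)."""
    return expand(bitv, margin)


def make_ptv(ctv: BinaryMask, margin: MarginSpec = PTV_MARGIN) -> BinaryMask:
    """Conventional planning target volume: CTV + 5 mm radial / 10 mm
    craniocaudal margin for motion plus set-up uncertainty."""
    return expand(ctv, margin)
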