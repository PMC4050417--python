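"""Voxel-grid data model and NIfTI I/O shared by all pipeline stages.

The package works on three kinds of objects that all live on a common
rectilinear voxel grid: SUV images (scalar, body-weight SUV units), binary
masks (target volumes such as BTV/BITV/CTV/PTV), and ordered series of SUV
images, one per respiratory phase bin.

Conventions fixed here and relied on everywhere else:

* voxel indices are 0-based and arrays are indexed ``(x, y, z)``;
* the z axis is craniocaudal, x/y are in-plane (radial);
* each voxel owns the half-open physical cube centred on its centre;
* volumes are computed by voxel counting (count x voxel volume), matching
  what a clinical treatment-planning system reports, with no sub-voxel
  surface correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "SUVImage",
    "BinaryMask",
    "GatedSeries",
    "read_image",
    "read_mask",
    "write_image",
    "volume_cc",
]


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing (mm) and origin (mm) of a rectilinear voxel grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("GridGeometry is strictly 3-D")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (= mL); spacings are mm so /1000."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


def _check_same_geometry(a: GridGeometry, b: GridGeometry) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise ValueError(f"geometry mismatch: {a} vs {b}")


@dataclass
class SUVImage:
    """3-D scalar voxel grid in body-weight SUV units (non-negative, finite)."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV image contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("SUV image contains negative values")

    @property
    def suv_max(self) -> float:
        return float(self.values.max())


@dataclass
class BinaryMask:
    """Boolean voxel grid on the same geometry as the images it is combined with."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    def check_compatible(self, other: "BinaryMask | SUVImage") -> None:
        _check_same_geometry(self.geometry, other.geometry)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self.check_compatible(other)
        return BinaryMask(self.geometry, self.values | other.values)

    def intersection(self, other: "BinaryMask") -> "BinaryMask":
        self.check_compatible(other)
        return BinaryMask(self.geometry, self.values & other.values)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class GatedSeries:
    """Ordered respiratory phase bins of one gated PET exam on one grid.

    Six equally weighted phases by default; ``phase_fractions`` are the
    fractions of the breathing cycle each bin covers and must sum to 1.
    """

    phases: list[SUVImage]
    phase_fractions: Sequence[float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("a gated series needs at least one phase")
        geo = self.phases[0].geometry
        for p in self.phases[1:]:
            _check_same_geometry(geo, p.geometry)
        if self.phase_fractions is None:
            self.phase_fractions = [1.0 / len(self.phases)] * len(self.phases)
        self.phase_fractions = [float(f) for f in self.phase_fractions]
        if len(self.phase_fractions) != len(self.phases):
            raise ValueError("one phase fraction per phase required")
        if not np.isclose(sum(self.phase_fractions), 1.0):
            raise ValueError("phase fractions must sum to 1")

    @property
    def geometry(self) -> GridGeometry:
        return self.phases[0].geometry

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    def __getitem__(self, i: int) -> SUVImage:
        return self.phases[i]


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def _geometry_from_nifti(img: nib.Nifti1Image) -> GridGeometry:
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing in header: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return GridGeometry(shape=img.shape[:3], spacing=tuple(float(z) for z in zooms), origin=origin)


def read_image(path: str | Path) -> SUVImage:
    """Read a scalar 3-D NIfTI-1 volume as an :class:`SUVImage`.

    Rejects missing files, 4-D/non-scalar content and non-positive spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar volume, got shape {img.shape}")
    geo = _geometry_from_nifti(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return SUVImage(geo, data)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI-1 volume as a binary mask (non-zero voxels are true)."""
    img = read_image(path)
    return BinaryMask(img.geometry, img.values > 0)


def write_image(img: SUVImage | BinaryMask, path: str | Path) -> None:
    """Write an image or mask to NIfTI-1, preserving spacing and origin.

    Masks are stored as 8-bit {0, 1}; images as float32.
    """
    path = Path(path)
    if isinstance(img, BinaryMask):
        data = img.values.astype(np.uint8)
    else:
        data = img.values.astype(np.float32)
    out = nib.Nifti1Image(data, img.geometry.affine())
    out.header.set_zooms(img.geometry.spacing)
    nib.save(out, path)


def volume_cc(mask: BinaryMask) -> float:
    """Volume of a mask in cc by voxel counting: (#true voxels) x voxel volume."""
    return mask.n_voxels * mask.geometry.voxel_volume_cc
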