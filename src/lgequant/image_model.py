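"""Voxel data model for short-axis CMR stacks, label maps and mass computation.

Conventions
-----------
* Arrays are indexed ``(slice, row, col)``, 0-based, base-to-apex.
* In-plane pixel spacing is isotropic (mm); the through-plane extent of a
  voxel is ``slice_thickness_mm + slice_gap_mm`` (contiguous-coverage
  convention, gap defaults to 0).
* Ground-truth label maps use the coding table
  ``{0 background, 1 blood pool, 2 myocardium, 3 papillary muscle, 4 scar}``.
  Boolean analysis masks are :class:`LabelMap` objects with values ``{0, 1}``.
* Myocardial mass uses a tissue density of 1.05 g/ml, the standard constant
  of the CMR mass literature; it is exposed as a parameter of
  :func:`mass_of` for sensitivity analyses.

On disk, stacks and masks are single-file NIfTI-1 volumes.  NIfTI has no
native inter-slice-gap field, so the gap is carried in the header ``descrip``
string and restored on read; zooms carry (pixel, pixel, thickness).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_BLOOD",
    "LABEL_MYOCARDIUM",
    "LABEL_PAPILLARY",
    "LABEL_SCAR",
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "LgeQuantError",
    "GeometryError",
    "FormatError",
    "CodingError",
    "SliceStack",
    "LabelMap",
    "MassResult",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "myocardium_mask",
    "mass_of",
]

LABEL_BACKGROUND = 0
LABEL_BLOOD = 1
LABEL_MYOCARDIUM = 2
LABEL_PAPILLARY = 3
LABEL_SCAR = 4

_VALID_LABELS = frozenset(
    {LABEL_BACKGROUND, LABEL_BLOOD, LABEL_MYOCARDIUM, LABEL_PAPILLARY, LABEL_SCAR}
)

#: Myocardial tissue density (g/ml) used to convert voxel volume to mass.
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


class LgeQuantError(Exception):
    """Base class for all lgequant errors."""


class GeometryError(LgeQuantError):
    """Inconsistent or invalid voxel geometry."""


class FormatError(LgeQuantError):
    """A file does not match the expected on-disk format."""


class CodingError(LgeQuantError):
    """A label map contains values outside the coding table."""


def _check_spacing(pixel_spacing_mm: float, slice_thickness_mm: float, slice_gap_mm: float) -> None:
    if pixel_spacing_mm <= 0:
        raise GeometryError(f"pixel_spacing_mm must be > 0, got {pixel_spacing_mm}")
    if slice_thickness_mm <= 0:
        raise GeometryError(f"slice_thickness_mm must be > 0, got {slice_thickness_mm}")
    if slice_gap_mm < 0:
        raise GeometryError(f"slice_gap_mm must be >= 0, got {slice_gap_mm}")


@dataclass
class SliceStack:
    """A 3-D stack of signal intensities with voxel geometry.

    Parameters
    ----------
    intensities
        Array of shape ``(n_slices, rows, cols)`` of nonnegative signal.
    pixel_spacing_mm
        Isotropic in-plane pixel spacing.
    slice_thickness_mm
        Acquired slice thickness.
    slice_gap_mm
        Inter-slice gap; the voxel's through-plane extent is
        ``thickness + gap``.
    """

    intensities: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    slice_gap_mm: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise GeometryError(
                f"intensities must be 3-D (slice, row, col), got ndim={self.intensities.ndim}"
            )
        _check_spacing(self.pixel_spacing_mm, self.slice_thickness_mm, self.slice_gap_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_spacing_mm**2 * (self.slice_thickness_mm + self.slice_gap_mm)


@dataclass
class LabelMap:
    """Integer voxel grid sharing the geometry of a :class:`SliceStack`."""

    labels: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    slice_gap_mm: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.dtype == bool:
            self.labels = self.labels.astype(np.uint8)
        if self.labels.ndim != 3:
            raise GeometryError(
                f"labels must be 3-D (slice, row, col), got ndim={self.labels.ndim}"
            )
        _check_spacing(self.pixel_spacing_mm, self.slice_thickness_mm, self.slice_gap_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_spacing_mm**2 * (self.slice_thickness_mm + self.slice_gap_mm)

    def as_bool(self) -> np.ndarray:
        """View the map as a boolean mask (any nonzero voxel)."""
        return self.labels.astype(bool)

    def same_geometry_as(self, other: "SliceStack | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and self.pixel_spacing_mm == other.pixel_spacing_mm
            and self.slice_thickness_mm == other.slice_thickness_mm
            and self.slice_gap_mm == other.slice_gap_mm
        )


@dataclass(frozen=True)
class MassResult:
    """Mass of a voxel set: ``mass_g = volume_ml x density``."""

    mass_g: float
    voxel_count: int
    volume_ml: float

    def to_json(self) -> str:
        return json.dumps(
            {"mass_g": self.mass_g, "voxel_count": self.voxel_count, "volume_ml": self.volume_ml}
        )


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------

_GAP_RE = re.compile(r"slice_gap_mm=([0-9.eE+-]+)")


def _to_nifti(data: np.ndarray, pixel: float, thickness: float, gap: float) -> nib.Nifti1Image:
    # store (col, row, slice) so the first two NIfTI axes are in-plane
    img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), affine=None)
    img.header.set_zooms((pixel, pixel, thickness))
    img.header["descrip"] = f"slice_gap_mm={gap:g}".encode()
    return img


def _from_nifti(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D data, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms[:2]) or zooms[2] <= 0:
        raise FormatError(f"{path}: missing or non-positive spacing in header (pixdim={zooms})")
    if abs(zooms[0] - zooms[1]) > 1e-6:
        raise FormatError(f"{path}: anisotropic in-plane spacing unsupported (pixdim={zooms})")
    descrip = img.header["descrip"].tobytes().decode(errors="replace")
    m = _GAP_RE.search(descrip)
    gap = float(m.group(1)) if m else 0.0
    return data.transpose(2, 1, 0), float(zooms[0]), float(zooms[2]), gap


def write_volume(stack: SliceStack, path: str | Path) -> None:
    """Write a stack as single-file NIfTI-1 (.nii or .nii.gz)."""
    nib.save(
        _to_nifti(stack.intensities, stack.pixel_spacing_mm, stack.slice_thickness_mm, stack.slice_gap_mm),
        str(path),
    )


def read_volume(path: str | Path) -> SliceStack:
    """Read a 3-D NIfTI-1 volume; spacing is taken from the header."""
    data, pixel, thickness, gap = _from_nifti(path)
    return SliceStack(data.astype(np.float64), pixel, thickness, gap)


def write_labelmap(mask: LabelMap, path: str | Path) -> None:
    nib.save(
        _to_nifti(mask.labels.astype(np.uint8), mask.pixel_spacing_mm, mask.slice_thickness_mm, mask.slice_gap_mm),
        str(path),
    )


def read_labelmap(path: str | Path) -> LabelMap:
    data, pixel, thickness, gap = _from_nifti(path)
    return LabelMap(np.rint(data).astype(np.int16), pixel, thickness, gap)


# ---------------------------------------------------------------------------
# Masks and mass
# ---------------------------------------------------------------------------

def myocardium_mask(truth: LabelMap) -> LabelMap:
    """Myocardium mask from a ground-truth label map.

    Scar voxels are wall tissue and count toward myocardial mass; papillary
    muscles and (intertrabecular) blood pool are excluded, mirroring the
    clinical tracing protocol.
    """
    labels = truth.labels
    present = set(np.unique(labels).tolist())
    unknown = present - _VALID_LABELS
    if unknown:
        raise CodingError(f"label map contains values outside the coding table: {sorted(unknown)}")
    mask = (labels == LABEL_MYOCARDIUM) | (labels == LABEL_SCAR)
    return LabelMap(mask, truth.pixel_spacing_mm, truth.slice_thickness_mm, truth.slice_gap_mm)


def mass_of(
    mask: LabelMap,
    *,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> MassResult:
    """Tissue mass of a boolean voxel mask.

    ``volume_ml = count x pixel_spacing^2 x (thickness + gap) / 1000`` and
    ``mass_g = volume_ml x density``.
    """
    _check_spacing(mask.pixel_spacing_mm, mask.slice_thickness_mm, mask.slice_gap_mm)
    count = int(np.count_nonzero(mask.labels))
    volume_ml = count * mask.voxel_volume_mm3 / 1000.0
    return MassResult(mass_g=volume_ml * density_g_per_ml, voxel_count=count, volume_ml=volume_ml)
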