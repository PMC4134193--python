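"""Image containers, NIfTI I/O, and elementary mask algebra.

All pipeline stages operate on three light-weight containers defined here:

``ImageVolume``
    a 3-D scalar grid with NIfTI affine metadata and an explicit validity
    flag.  Out-of-mask voxels are *flagged* invalid rather than zero-filled,
    so intensity statistics (normalization, tissue means) never see them.
``BinaryMask``
    a {0,1} volume on the same grid.
``LabelMap``
    a connected-component labeling (0 = background, 1..K = components).

Grids are considered compatible when shapes match exactly and voxel
spacings agree within 1e-3 mm; anything else raises ``GridMismatchError``
instead of silently resampling, which would hide registration bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "LabelMap",
    "GridMismatchError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "binarize_probability",
    "mask_and",
    "apply_mask",
    "label_components",
]

MODALITIES = ("T1w", "FLAIR", "DWI", "fused", "probability", "other")

#: spacing agreement tolerance for grid compatibility, mm
SPACING_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Two volumes do not share shape/spacing and cannot be combined."""


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class ImageVolume:
    """3-D scalar image with affine metadata and a validity flag.

    Parameters
    ----------
    data:
        3-D array of intensities (arbitrary units).
    affine:
        4x4 voxel-to-world (mm) matrix, NIfTI convention.
    modality:
        one of ``{"T1w", "FLAIR", "DWI", "fused", "probability", "other"}``.
    valid:
        optional boolean array marking voxels that carry meaningful
        intensity; ``None`` means all voxels are valid.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "other"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"ImageVolume requires a 3-D array, got {self.data.ndim}-D "
                f"shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        finite = np.isfinite(self.data)
        if self.valid is None:
            if not finite.all():
                raise ValueError("non-finite intensities in volume")
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("valid flag shape must match data")
            if not finite[self.valid].all():
                raise ValueError("non-finite intensities among valid voxels")
        if (self.spacing <= 0).any():
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (dx, dy, dz) in mm."""
        return _spacing_from_affine(self.affine)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean validity array (all-True when no flag is set)."""
        if self.valid is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid

    def valid_values(self) -> np.ndarray:
        """Flat array of intensities at valid voxels."""
        return self.data[self.valid_mask]

    def with_data(self, data: np.ndarray, *, modality: str | None = None,
                  valid: np.ndarray | None = None) -> "ImageVolume":
        """New volume on the same grid with replaced data/validity."""
        return ImageVolume(
            data=data,
            affine=self.affine.copy(),
            modality=self.modality if modality is None else modality,
            valid=self.valid_mask.copy() if valid is None and self.valid is not None else valid,
        )


@dataclass
class BinaryMask:
    """Voxel set over {0,1} on an image grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def complement(self) -> "BinaryMask":
        return BinaryMask(~self.data, self.affine.copy())

    @classmethod
    def full(cls, like: "ImageVolume | BinaryMask") -> "BinaryMask":
        return cls(np.ones(like.shape, dtype=bool), like.affine.copy())

    @classmethod
    def empty(cls, like: "ImageVolume | BinaryMask") -> "BinaryMask":
        return cls(np.zeros(like.shape, dtype=bool), like.affine.copy())


@dataclass
class LabelMap:
    """Connected-component labeling; 0 is background, labels run 1..K."""

    data: np.ndarray
    affine: np.ndarray
    n_labels: int = field(default=0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("label map must be 3-D")
        if (self.data < 0).any():
            raise ValueError("labels must be non-negative")
        observed = int(self.data.max())
        if self.n_labels == 0:
            self.n_labels = observed
        elif observed > self.n_labels:
            raise ValueError("data contains labels above n_labels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    def mask(self) -> BinaryMask:
        """Union of all labeled voxels."""
        return BinaryMask(self.data > 0, self.affine.copy())

    def label_sizes(self) -> np.ndarray:
        """Voxel count per label, index 0 unused (background omitted)."""
        return np.bincount(self.data.ravel(), minlength=self.n_labels + 1)


def check_same_grid(a, b) -> None:
    """Raise GridMismatchError unless a and b live on the same grid."""
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=SPACING_TOL_MM):
        raise GridMismatchError(
            f"spacing mismatch: {a.spacing} vs {b.spacing} (tol {SPACING_TOL_MM} mm)"
        )


def read_volume(path: str | Path, modality: str = "other") -> ImageVolume:
    """Read a 3-D NIfTI image.

    Raises a descriptive error for missing files, non-3-D images, or
    unreadable headers.  Intensities are returned unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad headers
        raise IOError(f"cannot read NIfTI {path}: {exc}") from exc
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
        shape = img.shape
    if len(shape) != 3:
        raise ValueError(
            f"{path} is {len(shape)}-D (shape {shape}); expected a 3-D volume"
        )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return ImageVolume(data=data, affine=np.asarray(img.affine), modality=modality)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask stored as NIfTI; nonzero voxels become 1."""
    vol = read_volume(path)
    return BinaryMask((vol.data > 0.5), vol.affine)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def binarize_probability(p: ImageVolume, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map: voxel is 1 iff p > threshold (strict).

    The strict inequality keeps only voxels with probability *over* the
    threshold; a voxel at exactly 0.5 falls to background.
    """
    vals = p.valid_values()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError(
            f"probability map values outside [0,1]: min {vals.min()}, max {vals.max()}"
        )
    data = (p.data > threshold) & p.valid_mask
    return BinaryMask(data, p.affine.copy())


def mask_and(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise logical conjunction of two masks on the same grid."""
    check_same_grid(a, b)
    return BinaryMask(a.data & b.data, a.affine.copy())


def apply_mask(v: ImageVolume, m: BinaryMask) -> ImageVolume:
    """Restrict a volume to a mask.

    In-mask intensities are preserved; out-of-mask voxels are flagged
    invalid (not overwritten with a fake intensity), so downstream
    statistics only ever see in-mask values.
    """
    check_same_grid(v, m)
    return v.with_data(v.data, valid=v.valid_mask & m.data)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components(m: BinaryMask, connectivity: int = 26) -> LabelMap:
    """Connected-component labeling of a binary mask.

    ``connectivity`` is the 3-D neighbor count (6, 18 or 26; default 26 —
    confluent lesions cross slices).  Labels are contiguous from 1.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    labels, n = ndimage.label(m.data, structure=_STRUCTURES[connectivity])
    return LabelMap(labels, m.affine.copy(), n_labels=int(n))
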