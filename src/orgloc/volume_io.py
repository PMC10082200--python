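"""Volume and mask I/O with a fixed (z, y, x) axis convention.

Every consumer in this package indexes grids as ``data[z, y, x]`` where
``z`` is the axial slice index, ``y`` the in-slice row and ``x`` the
in-slice column.  All index ranges are 0-based and half-open.  NIfTI
files store data in (x, y, z) order; reading transposes to (z, y, x)
and writing transposes back, so round trips are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "VolumeFormatError",
    "ORGAN_LABELS",
    "DEFAULT_WINDOW",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "normalize_window",
    "resample_depth",
    "crop_half",
]

#: Recognized organ tags.  ``kidney_right`` is the anatomical right kidney,
#: which appears in the *left* image half in radiological convention.
ORGAN_LABELS = ("kidney_left", "kidney_right", "spleen", "background")

#: Default soft-tissue display window in HU, used when normalizing real CT.
DEFAULT_WINDOW = (-135.0, 215.0)


class VolumeFormatError(ValueError):
    """Raised for inputs that are not a 3D scalar image grid."""


@dataclass
class Volume:
    """A 3D scalar grid indexed (z, y, x) with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"Volume data must be 3D (z, y, x), got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise VolumeFormatError(f"Volume dimensions must be positive: {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise VolumeFormatError("spacing must have three entries (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class BinaryMask:
    """Boolean grid aligned to a parent :class:`Volume` (or one slice of it)."""

    data: np.ndarray
    label: str = "background"
    spacing: tuple[float, ...] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            if not np.isin(np.unique(self.data), (0, 1)).all():
                raise VolumeFormatError("mask values must be strictly binary")
            self.data = self.data.astype(bool)
        if self.label not in ORGAN_LABELS:
            raise ValueError(f"unknown organ label {self.label!r}; expected one of {ORGAN_LABELS}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def volume_voxels(self) -> int:
        return int(self.data.sum())


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D NIfTI image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # on-disk (x, y, z) -> in-memory (z, y, x)
    return np.ascontiguousarray(data.T), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def read_volume(path) -> Volume:
    """Read a NIfTI-1 volume into (z, y, x) order with spacing from the header."""
    data, spacing = _load_nifti(path)
    return Volume(data=data, spacing=spacing)


def write_volume(vol: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI-1; spacing is stored in the header."""
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    img = nib.Nifti1Image(np.asarray(vol.data).T, affine)
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))


def read_mask(path, label: str = "background") -> BinaryMask:
    data, spacing = _load_nifti(path)
    return BinaryMask(data=data != 0, label=label, spacing=spacing)


def write_mask(mask: BinaryMask, path) -> None:
    spacing = tuple(mask.spacing) + (1.0,) * (3 - len(mask.spacing))
    vol = Volume(data=mask.data.astype(np.uint8), spacing=spacing[:3])
    write_volume(vol, path)


def normalize_window(vol: Volume, low: float, high: float) -> Volume:
    """Clip intensities to [low, high] HU and rescale linearly onto [0, 1]."""
    if not low < high:
        raise ValueError(f"window requires low < high, got ({low}, {high})")
    data = np.clip((vol.data.astype(np.float32) - low) / (high - low), 0.0, 1.0)
    return Volume(data=data, spacing=vol.spacing, normalized=True)


def resample_depth(vol: Volume, target_z: int = 43) -> Volume:
    """Resample along z to exactly ``target_z`` slices by linear interpolation.

    In-slice dimensions are untouched.  When the depth already matches the
    target the input volume is returned unchanged.
    """
    if target_z < 1:
        raise ValueError(f"target_z must be >= 1, got {target_z}")
    z = vol.n_slices
    if z == target_z:
        return vol
    if z < 2:
        raise ValueError("resample_depth requires at least 2 slices")
    data = _interp_depth(vol.data, target_z)
    sz = vol.spacing[0] * (z - 1) / max(target_z - 1, 1)
    return replace(vol, data=data, spacing=(sz, vol.spacing[1], vol.spacing[2]))


def _interp_depth(data: np.ndarray, target_z: int) -> np.ndarray:
    """1D linear interpolation along axis 0 (exact at the endpoints)."""
    z = data.shape[0]
    if z == target_z:
        return data
    pos = np.linspace(0.0, z - 1, target_z)
    i0 = np.floor(pos).astype(np.intp)
    i0 = np.minimum(i0, z - 2)
    frac = (pos - i0).astype(np.float32)
    lo = data[i0].astype(np.float32, copy=False)
    hi = data[i0 + 1].astype(np.float32, copy=False)
    return lo + frac[:, None, None] * (hi - lo)


def crop_half(image: np.ndarray, side: str) -> np.ndarray:
    """Return the left (columns [0, W/2)) or right (columns [W/2, W)) half."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"crop_half expects a 2D slice, got ndim={image.ndim}")
    w = image.shape[1]
    if w % 2 != 0:
        raise ValueError(f"image width must be even, got {w}")
    if side == "left":
        return image[:, : w // 2]
    if side == "right":
        return image[:, w // 2 :]
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")
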