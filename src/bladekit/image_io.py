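"""NIfTI image handling, ROI signal extraction and intensity preprocessing.

Images are represented by :class:`ImageVolume` (data + affine + spacing) and
regions of interest by :class:`ROIMask` (integer label array on the same
grid).  Masks must share the image grid exactly; no implicit resampling is
ever performed, because silent resampling corrupts quantitative maps.  For
4D series the varying dimension (b-value or time frame) is the last axis;
b-values and frame times travel as plain-text sidecars, not in the NIfTI
header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import (
    AlignmentError,
    DegenerateInputError,
    EmptyROIError,
    FormatError,
)

__all__ = [
    "ImageVolume",
    "ROIMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "extract_roi_signals",
    "write_back_voxels",
    "summarize_roi",
    "normalize_intensity",
    "resize_image",
]


@dataclass
class ImageVolume:
    """A 3D or 4D scalar image with its voxel-to-world transform.

    The 4th axis, when present, carries the varying acquisition dimension
    (b-value or dynamic frame).
    """

    data: np.ndarray
    affine: np.ndarray
    spacing: tuple = field(default=None)
    axis_order: str = "xyz"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise FormatError(f"expected 3D or 4D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if self.spacing is None:
            self.spacing = tuple(np.linalg.norm(self.affine[:3, :3], axis=0))
        if any(s <= 0 for s in self.spacing):
            raise FormatError("voxel spacing must be strictly positive")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]


@dataclass
class ROIMask:
    """Integer label mask aligned voxelwise to a reference image grid (0 = background)."""

    data: np.ndarray
    reference_shape: tuple = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError("mask must be a 3D label array")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise FormatError("mask values must be integer labels")
            self.data = rounded.astype(np.int32)
        if self.data.min() < 0:
            raise FormatError("mask labels must be non-negative")
        if self.reference_shape is None:
            self.reference_shape = self.data.shape
        elif tuple(self.reference_shape) != self.data.shape:
            raise AlignmentError(
                f"mask shape {self.data.shape} != reference {tuple(self.reference_shape)}"
            )

    def labels(self) -> np.ndarray:
        vals = np.unique(self.data)
        return vals[vals > 0]


def read_volume(path) -> ImageVolume:
    """Read a NIfTI file (.nii or .nii.gz), 3D or 4D, without resampling."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises various types on bad content
        raise FormatError(f"not a readable NIfTI file: {path} ({exc})") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, affine=img.affine, spacing=spacing)


def write_volume(volume: ImageVolume, path) -> None:
    """Write an ImageVolume as NIfTI-1; dtype is preserved."""
    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_zooms(volume.spacing + (1.0,) * (volume.data.ndim - 3))
    nib.save(img, str(path))


def read_mask(path, reference_shape=None) -> ROIMask:
    vol = read_volume(path)
    return ROIMask(data=vol.data, reference_shape=reference_shape)


def _check_alignment(volume: ImageVolume, mask: ROIMask) -> None:
    if volume.spatial_shape != mask.data.shape:
        raise AlignmentError(
            f"mask grid {mask.data.shape} does not match image grid "
            f"{volume.spatial_shape}; resample masks before fitting"
        )


def extract_roi_signals(volume: ImageVolume, mask: ROIMask, label: int):
    """Pull the frame series of every masked voxel into a (n_voxels, n_frames) matrix.

    Voxels are ordered lexicographically by (i, j, k) index; the returned
    index array allows writing per-voxel results back onto the grid.
    """
    if volume.data.ndim != 4:
        raise FormatError("extract_roi_signals requires a 4D series")
    _check_alignment(volume, mask)
    if label <= 0:
        raise EmptyROIError("label must be a positive integer")
    idx = np.argwhere(mask.data == label)  # argwhere is C-ordered == lexicographic
    if idx.shape[0] == 0:
        raise EmptyROIError(f"label {label} selects no voxels")
    signals = volume.data[idx[:, 0], idx[:, 1], idx[:, 2], :].astype(float)
    return signals, idx


def write_back_voxels(shape, idx: np.ndarray, values: np.ndarray, fill=np.nan) -> np.ndarray:
    """Scatter per-voxel values onto a 3D grid, leaving unmasked voxels at ``fill``."""
    out = np.full(shape, fill, dtype=float)
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    return out


def summarize_roi(map_volume: ImageVolume, mask: ROIMask, label: int) -> dict:
    """ROI statistics of a 3D parametric map: mean, sample SD, median, counts.

    Non-finite voxels (failed fits) are excluded and counted in ``n_excluded``.
    """
    if map_volume.data.ndim != 3:
        raise FormatError("summarize_roi expects a 3D parametric map")
    _check_alignment(map_volume, mask)
    sel = mask.data == label
    if not sel.any():
        raise EmptyROIError(f"label {label} selects no voxels")
    vals = map_volume.data[sel].astype(float)
    finite = np.isfinite(vals)
    n_excluded = int((~finite).sum())
    vals = vals[finite]
    if vals.size == 0:
        raise EmptyROIError(f"all {n_excluded} masked voxels are non-finite")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {
        "mean": float(np.mean(vals)),
        "sd": sd,
        "median": float(np.median(vals)),
        "n_voxels": int(vals.size),
        "n_excluded": n_excluded,
    }


def normalize_intensity(image: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Scale intensities to a consistent range: minmax -> [0, 1], zscore -> mean 0 / sd 1."""
    image = np.asarray(image, dtype=float)
    if method == "minmax":
        lo, hi = np.nanmin(image), np.nanmax(image)
        if hi == lo:
            raise DegenerateInputError("constant image: min-max normalization undefined")
        return (image - lo) / (hi - lo)
    if method == "zscore":
        sd = np.nanstd(image)
        if sd == 0:
            raise DegenerateInputError("constant image: z-score normalization undefined")
        return (image - np.nanmean(image)) / sd
    raise ValueError(f"unknown normalization method: {method!r}")


def resize_image(image: np.ndarray, target, interpolation: str = "bilinear") -> np.ndarray:
    """Resize a 2D image to (H, W) with bilinear or nearest interpolation.

    Bilinear output never leaves the input value range (no anti-alias
    pre-blur, no spline overshoot).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("resize_image expects a 2D array")
    h, w = int(target[0]), int(target[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation: {interpolation!r}")
    if (h, w) == image.shape and order == 0:
        return image.copy()
    return _sk_resize(
        image, (h, w), order=order, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
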