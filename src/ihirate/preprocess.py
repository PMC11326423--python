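"""Loading, cropping and tensor preparation of normalized grey-matter maps.

Inputs are grey-matter probability maps already spatially normalized to a
common template; tissue segmentation and spatial normalization themselves
are upstream of this package.  The hippocampal region of interest is cut
out with half-open voxel-index slices on the normalized grid; the default
box ``[24:96, 54:107, 16:49]`` covers the hippocampi and the surrounding
sulci and yields 72 x 53 x 33 crops.

Right-hemisphere crops are mapped into the left-hemisphere frame by
mirroring the left-right axis, so a single geometric frame serves every
model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "RoiBox",
    "DEFAULT_ROI",
    "GreyMatterCrop",
    "load_volume",
    "crop_roi",
    "mirror_hemisphere",
    "normalize_intensity",
    "flatten",
    "unflatten",
]


@dataclass(frozen=True)
class RoiBox:
    """Half-open voxel index intervals on the normalized template grid."""

    x_range: tuple[int, int]
    y_range: tuple[int, int]
    z_range: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip("xyz", (self.x_range, self.y_range, self.z_range)):
            if not (0 <= lo < hi):
                raise ValueError(f"invalid {name}_range [{lo}, {hi})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (
            self.x_range[1] - self.x_range[0],
            self.y_range[1] - self.y_range[0],
            self.z_range[1] - self.z_range[0],
        )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(*self.x_range),
            slice(*self.y_range),
            slice(*self.z_range),
        )


#: Hippocampal ROI on the normalized grid (half-open slices), 72 x 53 x 33.
DEFAULT_ROI = RoiBox(x_range=(24, 96), y_range=(54, 107), z_range=(16, 49))


@dataclass
class GreyMatterCrop:
    """A 3D grey-matter probability crop over the hippocampal ROI."""

    voxels: np.ndarray  # (nx, ny, nz) float array
    roi: RoiBox
    hemisphere: str
    subject_id: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"crop must be 3D, got shape {self.voxels.shape}")
        if self.voxels.shape != self.roi.shape:
            raise ValueError(
                f"crop shape {self.voxels.shape} does not match ROI extents "
                f"{self.roi.shape}"
            )
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right: {self.hemisphere!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def load_volume(path: str | Path) -> tuple[np.ndarray, nib.Nifti1Header, np.ndarray]:
    """Load a NIfTI volume; returns (voxels, header, affine). No resampling."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error surface varies
        raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return data, img.header, img.affine


def crop_roi(
    volume: np.ndarray,
    roi: RoiBox = DEFAULT_ROI,
    hemisphere: str = "left",
    subject_id: str = "",
    cohort: str = "",
) -> GreyMatterCrop:
    """Extract the ROI sub-array (half-open slice semantics)."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {volume.ndim}D")
    for axis, (name, (lo, hi)) in enumerate(
        zip("xyz", (roi.x_range, roi.y_range, roi.z_range))
    ):
        if hi > volume.shape[axis]:
            raise ValueError(
                f"ROI {name}-range [{lo}, {hi}) exceeds volume extent "
                f"{volume.shape[axis]} on axis {axis}"
            )
    sub = volume[roi.slices].astype(np.float64, copy=True)
    return GreyMatterCrop(
        voxels=sub, roi=roi, hemisphere=hemisphere, subject_id=subject_id, cohort=cohort
    )


def mirror_hemisphere(crop: GreyMatterCrop) -> GreyMatterCrop:
    """Reverse the left-right (x) axis and toggle the hemisphere label."""
    flipped = crop.voxels[::-1, :, :].copy()
    other = "right" if crop.hemisphere == "left" else "left"
    return replace(crop, voxels=flipped, hemisphere=other)


def normalize_intensity(crop: GreyMatterCrop) -> GreyMatterCrop:
    """Min-max scale voxel values to [0, 1]; constant crops map to zeros."""
    v = crop.voxels
    if not np.all(np.isfinite(v)):
        raise ValueError(f"crop {crop.subject_id!r} contains non-finite voxels")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        scaled = np.zeros_like(v)
    else:
        scaled = (v - lo) / (hi - lo)
    return replace(crop, voxels=scaled)


def flatten(crop: GreyMatterCrop) -> np.ndarray:
    """Flatten to a 1D feature vector, x varying fastest, then y, then z.

    The inverse is :func:`unflatten` with the crop's shape.
    """
    return crop.voxels.ravel(order="F").copy()


def unflatten(vector: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Reshape a flattened feature vector back into a 3D crop array."""
    vector = np.asarray(vector)
    if vector.size != int(np.prod(shape)):
        raise ValueError(f"vector of length {vector.size} does not fill {shape}")
    return vector.reshape(shape, order="F")
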