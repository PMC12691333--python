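"""Volume and mask containers with NIfTI/NRRD I/O and isotropic resampling.

All downstream analysis operates on :class:`VolumeImage` / :class:`TumorMask`
pairs that share one grid (shape, spacing, origin, direction).  Arrays are
indexed ``(z, y, x)``; ``spacing`` is stored in the same axis order, in mm.
World coordinates follow the file's affine.  Masks are ``{0, 1}`` with 1 =
tumor.  A mask on a different grid than its image is a hard error rather than
a silent resample — segmentations are drawn on the native grid and must stay
there until both are resampled together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeImage",
    "TumorMask",
    "TumorVolumeStats",
    "GridMismatchError",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "volume_stats",
]


class GridMismatchError(ValueError):
    """Mask and image do not share shape/spacing/origin/direction."""


class VolumeFormatError(ValueError):
    """File is not a readable 3D scalar volume."""


def _identity_direction() -> np.ndarray:
    return np.eye(3)


@dataclass
class VolumeImage:
    """A 3D scalar volume (CT semantics: values in HU).

    Parameters
    ----------
    values
        ``(nz, ny, nx)`` float array.
    spacing
        Voxel size in mm per axis, ``(z, y, x)`` order, strictly positive.
    origin
        World position of voxel (0, 0, 0) in mm, ``(z, y, x)`` order.
    direction
        3x3 direction-cosine matrix (rows = world axes); need not be
        orthogonal to the grid axes.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=_identity_direction)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.values.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeImage | TumorMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.direction, other.direction)
        )


@dataclass
class TumorMask:
    """Binary segmentation aligned to a :class:`VolumeImage` grid."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=_identity_direction)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D mask, got {labels.ndim} dimensions"
            )
        self.labels = (labels > 0).astype(np.uint8)
        if self.labels.sum() == 0:
            raise ValueError("mask has no foreground voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.labels.sum())

    def indices(self) -> tuple[np.ndarray, ...]:
        """Voxel indices of the foreground, ``(z, y, x)`` arrays."""
        return np.nonzero(self.labels)

    def same_grid(self, other: "VolumeImage | TumorMask") -> bool:
        return VolumeImage.same_grid(self, other)  # type: ignore[arg-type]


@dataclass(frozen=True)
class TumorVolumeStats:
    """Voxel-count volume summary: total = n_voxels x voxel_volume."""

    n_voxels: int
    voxel_volume: float
    total_volume: float


def require_same_grid(image: VolumeImage, mask: TumorMask) -> None:
    if not image.same_grid(mask):
        raise GridMismatchError(
            "image and mask are on different grids "
            f"(shapes {image.shape} vs {mask.shape}, "
            f"spacings {image.spacing} vs {mask.spacing})"
        )


# ---------------------------------------------------------------------------
# File I/O via SimpleITK (handles both NIfTI-1 and NRRD)
# ---------------------------------------------------------------------------

def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple, np.ndarray]:
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"expected a 3D volume, file has {img.GetDimension()} dimensions"
        )
    values = sitk.GetArrayFromImage(img)  # (z, y, x)
    # SimpleITK reports spacing/origin in (x, y, z); flip to array order.
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    direction = np.array(img.GetDirection()).reshape(3, 3)
    return values, spacing, origin, direction


def _to_sitk(values: np.ndarray, spacing, origin, direction) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values))
    img.SetSpacing(tuple(reversed(spacing)))
    img.SetOrigin(tuple(reversed(origin)))
    img.SetDirection(tuple(np.asarray(direction).reshape(9)))
    return img


def read_volume(path) -> VolumeImage:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume."""
    try:
        img = sitk.ReadImage(str(path), sitk.sitkFloat64)
    except RuntimeError as exc:  # unreadable / unknown format
        raise VolumeFormatError(f"cannot read volume {path!s}: {exc}") from exc
    return VolumeImage(*_from_sitk(img))


def write_volume(image: VolumeImage, path) -> None:
    sitk.WriteImage(_to_sitk(image.values, image.spacing, image.origin,
                             image.direction), str(path))


def read_mask(path) -> TumorMask:
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"cannot read mask {path!s}: {exc}") from exc
    values, spacing, origin, direction = _from_sitk(img)
    return TumorMask(values, spacing, origin, direction)


def write_mask(mask: TumorMask, path) -> None:
    sitk.WriteImage(
        _to_sitk(mask.labels.astype(np.uint8), mask.spacing, mask.origin,
                 mask.direction),
        str(path),
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(
    image: VolumeImage,
    mask: TumorMask,
    target: float = 1.0,
    *,
    interpolation: str = "linear",
) -> tuple[VolumeImage, TumorMask]:
    """Resample an image/mask pair to an isotropic grid.

    The image is interpolated trilinearly (``"bspline"`` available behind the
    flag); the mask always by nearest neighbour so it stays binary.

    Raises
    ------
    GridMismatchError
        If the pair is not grid-aligned.
    ValueError
        If ``target <= 0`` or the mask is empty after resampling.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    require_same_grid(image, mask)

    interp = {"linear": sitk.sitkLinear, "bspline": sitk.sitkBSpline}[interpolation]

    src = _to_sitk(image.values, image.spacing, image.origin, image.direction)
    src_mask = _to_sitk(mask.labels.astype(np.uint8), mask.spacing, mask.origin,
                        mask.direction)

    old_spacing = np.array(src.GetSpacing())
    old_size = np.array(src.GetSize())
    new_spacing = (float(target),) * 3
    new_size = np.maximum(
        1, np.ceil(old_size * old_spacing / target).astype(int)
    )

    def _resample(img: sitk.Image, how, default) -> sitk.Image:
        rs = sitk.ResampleImageFilter()
        rs.SetOutputSpacing(new_spacing)
        rs.SetSize([int(s) for s in new_size])
        rs.SetOutputOrigin(img.GetOrigin())
        rs.SetOutputDirection(img.GetDirection())
        rs.SetInterpolator(how)
        rs.SetDefaultPixelValue(default)
        return rs.Execute(img)

    out_img = VolumeImage(*_from_sitk(
        _resample(src, interp, float(image.values.min()))))
    mask_arr, sp, orig, dirn = _from_sitk(
        _resample(src_mask, sitk.sitkNearestNeighbor, 0))
    if mask_arr.sum() == 0:
        raise ValueError("mask is empty after resampling")
    out_mask = TumorMask(mask_arr, sp, orig, dirn)
    return out_img, out_mask


def volume_stats(mask: TumorMask) -> TumorVolumeStats:
    """Voxel-count tumor volume: N voxels times the constant voxel volume."""
    n = mask.n_voxels
    vk = mask.voxel_volume
    return TumorVolumeStats(n_voxels=n, voxel_volume=vk, total_volume=n * vk)
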