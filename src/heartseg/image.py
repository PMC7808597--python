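"""Volumetric image and mask data model with physical-space geometry.

Images are stored as numpy arrays indexed ``[i, j, k]`` (x fastest-varying in
the ITK sense) together with the standard NIfTI/ITK geometry triple: origin
(mm position of the centre of voxel ``(0, 0, 0)``), per-axis spacing in mm and
a 3x3 orthonormal direction matrix.  The physical position of voxel ``idx`` is

    point = origin + direction @ (idx * spacing)

All distances throughout the package are in mm.  Voxel indices are 0-based and
boxes are half-open ``[lo, hi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Image3D",
    "BinaryMask",
    "VoxelBox",
    "GeometryError",
    "FormatError",
    "read_volume",
    "write_volume",
    "resample",
    "crop",
    "mask_bounding_box",
    "centroid_mm",
    "same_grid",
]

#: fill value for voxels sampled outside an image's support (CT air)
IMAGE_FILL = -1000.0
#: fill value for voxels sampled outside a mask's support
MASK_FILL = 0

MASK_ROLES = frozenset(
    {"heart_manual", "heart_auto", "prv", "lungs", "truth", "other"}
)


class GeometryError(ValueError):
    """Invalid or mismatched image geometry."""


class FormatError(ValueError):
    """File could not be read as a supported volumetric format."""


def _check_geometry(dims, spacing, origin, direction) -> None:
    if len(dims) != 3 or any(int(d) < 1 for d in dims):
        raise GeometryError(f"dims must be three positive counts, got {dims}")
    if len(spacing) != 3 or any(not (s > 0) for s in spacing):
        raise GeometryError(f"spacing must be strictly positive, got {spacing}")
    if not np.all(np.isfinite(origin)):
        raise GeometryError(f"origin must be finite, got {origin}")
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise GeometryError("direction must be a 3x3 matrix")
    if not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
        raise GeometryError("direction matrix is not orthonormal")
    if abs(abs(np.linalg.det(d)) - 1.0) > 1e-6:
        raise GeometryError("direction matrix determinant is not +/-1")


@dataclass
class Image3D:
    """Scalar volumetric image (HU-like intensities) in physical space."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError("values must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float)
        _check_geometry(self.dims, self.spacing, self.origin, self.direction)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def physical_point(self, index) -> np.ndarray:
        """mm position of a (possibly fractional) voxel index."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + self.direction @ (idx * np.asarray(self.spacing))

    def index_of(self, point) -> np.ndarray:
        """Continuous voxel index of a physical point (inverse of physical_point)."""
        p = np.asarray(point, dtype=float) - np.asarray(self.origin)
        return (self.direction.T @ p) / np.asarray(self.spacing)

    def same_geometry(self, other: "Image3D", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    # --- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        # sitk arrays are indexed [z, y, x]
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.values.transpose(2, 1, 0).astype(np.float64))
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Image3D":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            values=np.ascontiguousarray(arr),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )


@dataclass
class BinaryMask(Image3D):
    """Organ delineation on an :class:`Image3D` grid; values in {0, 1}."""

    role: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(np.unique(self.values), (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.values = self.values.astype(np.uint8)
        super().__post_init__()
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; one of {sorted(MASK_ROLES)}")

    def volume_mm3(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_mm3()

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.values.transpose(2, 1, 0).astype(np.uint8))
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, role: str = "other") -> "BinaryMask":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            values=np.ascontiguousarray((arr != 0).astype(np.uint8)),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
            role=role,
        )


@dataclass(frozen=True)
class VoxelBox:
    """Half-open voxel-index box ``[lo, hi)``."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        if any(l > h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"box lo must not exceed hi: {self.lo} vs {self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def within(self, dims) -> bool:
        return all(0 <= l and h <= d for l, h, d in zip(self.lo, self.hi, dims))

    def contains_index(self, idx) -> bool:
        return all(l <= i < h for l, i, h in zip(self.lo, idx, self.hi))

    def shifted(self, offset) -> "VoxelBox":
        off = tuple(int(o) for o in offset)
        return VoxelBox(
            tuple(l + o for l, o in zip(self.lo, off)),
            tuple(h + o for h, o in zip(self.hi, off)),
        )


def same_grid(a: Image3D, b: Image3D, atol: float = 1e-6) -> None:
    """Raise :class:`GeometryError` unless a and b share a voxel grid."""
    if not a.same_geometry(b, atol=atol):
        raise GeometryError("images are not defined on the same voxel grid")


# ---------------------------------------------------------------------------
# I/O

_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _has_supported_suffix(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _SUFFIXES)


def read_volume(path, as_mask: bool = False, role: str = "other"):
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    With ``as_mask`` the voxel values are binarised (nonzero -> 1) and a
    :class:`BinaryMask` is returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if not _has_supported_suffix(path):
        raise FormatError(
            f"unsupported format {path.name!r}; expected one of {_SUFFIXES}"
        )
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # ITK wraps unreadable/truncated files here
        raise FormatError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path} is not a 3-D volume")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-4):
        raise GeometryError(f"{path}: non-orthonormal direction matrix")
    if as_mask:
        return BinaryMask.from_sitk(img, role=role)
    return Image3D.from_sitk(sitk.Cast(img, sitk.sitkFloat64))


def write_volume(volume: Image3D, path) -> Path:
    """Write to NIfTI or MetaImage; masks are stored as unsigned 8-bit."""
    path = Path(path)
    if not _has_supported_suffix(path):
        raise FormatError(f"unsupported output format for {path.name!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    img = volume.to_sitk()
    if not isinstance(volume, BinaryMask):
        img = sitk.Cast(img, sitk.sitkFloat32)
    sitk.WriteImage(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Grid operations


def resample(source: Image3D, reference: Image3D, interp: str = "linear"):
    """Resample ``source`` onto the grid of ``reference`` in physical space.

    Out-of-support voxels are filled with -1000 (air) for images and 0 for
    masks.  Returns the same type as ``source``; a mask resampled with
    ``nearest`` (or thresholded linear) stays binary.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    interpolator = sitk.sitkLinear if interp == "linear" else sitk.sitkNearestNeighbor
    is_mask = isinstance(source, BinaryMask)
    fill = MASK_FILL if is_mask else IMAGE_FILL
    out = sitk.Resample(
        source.to_sitk(),
        reference.to_sitk(),
        sitk.Transform(),
        interpolator,
        float(fill),
    )
    if is_mask:
        arr = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
        return BinaryMask(
            values=(arr > 0.5).astype(np.uint8),
            spacing=reference.spacing,
            origin=reference.origin,
            direction=reference.direction.copy(),
            role=source.role,
        )
    return Image3D.from_sitk(out)


def crop(source: Image3D, box: VoxelBox):
    """Extract the half-open voxel box, keeping physical coordinates intact."""
    if not box.within(source.dims):
        raise ValueError(f"box {box} lies outside grid of dims {source.dims}")
    vals = source.values[box.slices()].copy()
    new_origin = tuple(source.physical_point(box.lo))
    if isinstance(source, BinaryMask):
        return BinaryMask(
            values=vals,
            spacing=source.spacing,
            origin=new_origin,
            direction=source.direction.copy(),
            role=source.role,
        )
    return Image3D(
        values=vals,
        spacing=source.spacing,
        origin=new_origin,
        direction=source.direction.copy(),
    )


def mask_bounding_box(mask: BinaryMask, margin_mm=0.0) -> VoxelBox:
    """Smallest voxel box containing every 1-voxel, expanded by ``margin_mm``.

    The margin is converted to voxels per axis as ``ceil(margin / spacing)``
    and the result is clipped to the grid.
    """
    if mask.is_empty():
        raise ValueError("cannot take the bounding box of an empty mask")
    margin = np.broadcast_to(np.asarray(margin_mm, dtype=float), (3,))
    nz = np.nonzero(mask.values)
    lo, hi = [], []
    for ax in range(3):
        grow = math.ceil(margin[ax] / mask.spacing[ax]) if margin[ax] > 0 else 0
        lo.append(max(0, int(nz[ax].min()) - grow))
        hi.append(min(mask.dims[ax], int(nz[ax].max()) + 1 + grow))
    return VoxelBox(tuple(lo), tuple(hi))


def centroid_mm(mask: BinaryMask) -> np.ndarray:
    """Physical-space centroid (mm) of a nonempty mask."""
    if mask.is_empty():
        raise ValueError("centroid of empty mask is undefined")
    idx = np.argwhere(mask.values > 0).mean(axis=0)
    return mask.physical_point(idx)
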