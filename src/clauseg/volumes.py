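"""Volumetric images and masks in one fixed anatomical convention.

Every volume handled by this package is held in RAS+ voxel order: the first
axis increases left->right, the second posterior->anterior, the third
inferior->superior. Files are reoriented to this convention on read (via
nibabel's closest-canonical transform), so downstream geometric operations —
"lateral", "anterior", "dorsal" — can be phrased as fixed array axes.

Volumes are matched by shape and spacing only (all inputs are assumed
co-registered); full spatial-registration checking is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import AlignmentError, VolumeIOError

#: Tolerance (mm) when comparing voxel spacings of two grids.
SPACING_TOL_MM = 1e-3

#: Human-readable labels of the canonical axes, in array-axis order.
CANONICAL_AXES = ("left->right", "posterior->anterior", "inferior->superior")


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ScalarVolume:
    """A 3-D intensity grid with voxel spacing in mm.

    ``data`` may carry T1w or T2w intensities (arbitrary units), a T1w/T2w
    ratio, or a mean-diffusivity map (mm^2/s). NaN is allowed (masked-out
    voxels); infinities are not.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    orientation: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeIOError(f"expected a 3-D volume, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"voxel spacings must be positive, got {self.spacing}")
        if np.isinf(self.data).any():
            raise VolumeIOError("volume contains infinite values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def aligned_with(self, other: "ScalarVolume | BinaryMask") -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= SPACING_TOL_MM for a, b in zip(self.spacing, other.spacing)
        )


@dataclass
class BinaryMask:
    """A 3-D boolean grid aligned to a companion :class:`ScalarVolume`.

    Carries putamen, CSF, ROI and claustrum segmentations — the voxel sets
    A and B of the Dice overlap.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    orientation: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise VolumeIOError(f"expected a 3-D mask, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"voxel spacings must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()

    def aligned_with(self, other: "ScalarVolume | BinaryMask") -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= SPACING_TOL_MM for a, b in zip(self.spacing, other.spacing)
        )


@dataclass(frozen=True)
class Hemisphere:
    """One side of the brain, with its direction along the left->right axis.

    ``lateral_sign`` is +1 for the right hemisphere (lateral = increasing
    first-axis index) and -1 for the left.
    """

    side: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.side!r}")

    @property
    def lateral_sign(self) -> int:
        return 1 if self.side == "right" else -1


LEFT = Hemisphere("left")
RIGHT = Hemisphere("right")


def _load_canonical(path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
    except FileNotFoundError as exc:
        raise VolumeIOError(f"no such file: {path}") from exc
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"not a NIfTI volume: {path} ({exc})") from exc
    return nib.as_closest_canonical(img)


def read_volume(path) -> ScalarVolume:
    """Read a 3-D NIfTI file and reorient it to the canonical RAS+ convention."""
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(
            f"{path}: expected a 3-D volume, got shape {data.shape} "
            "(use read_dwi_series for 4-D diffusion data)"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(data.astype(np.float64), spacing, affine=np.asarray(img.affine))


def read_dwi_series(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Read a 4-D diffusion series; returns (signals, spacing, affine)."""
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise VolumeIOError(f"{path}: expected a 4-D DWI series, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_mask(path, threshold: float = 0.5) -> BinaryMask:
    """Read a binary or probabilistic mask; probabilistic values binarize at >= threshold.

    The inclusive-half rule means hard 0/1 masks pass through unchanged and a
    probability of exactly ``threshold`` counts as inside.
    """
    if not 0 < threshold < 1:
        raise VolumeIOError(f"threshold must lie in (0, 1), got {threshold}")
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    if np.isnan(data).all():
        raise VolumeIOError(f"{path}: mask contains no numeric values (all NaN)")
    binary = np.nan_to_num(data, nan=0.0) >= threshold
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask(binary, spacing, affine=np.asarray(img.affine))


def write_volume(volume: ScalarVolume, path) -> None:
    """Write a scalar volume as NIfTI-1 (float64)."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write {path}: {exc}") from exc


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as NIfTI-1 unsigned 8-bit 0/1; round-trips bit-exactly."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write {path}: {exc}") from exc


def ratio_image(t1w: ScalarVolume, t2w: ScalarVolume) -> ScalarVolume:
    """Voxelwise T1w/T2w ratio.

    Dividing co-registered T1- and T2-weighted images removes most shared
    multiplicative biases (e.g. receive-coil inhomogeneity) and yields a
    semiquantitative, myelin-sensitive contrast. Voxels where the T2w value
    is <= 0 are set to NaN rather than producing infinities.
    """
    if not t1w.aligned_with(t2w):
        raise AlignmentError(
            f"T1w {t1w.shape}@{t1w.spacing} and T2w {t2w.shape}@{t2w.spacing} are not aligned"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.where(t2w.data > 0, t1w.data / t2w.data, np.nan)
    return ScalarVolume(out, t1w.spacing, affine=t1w.affine)
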