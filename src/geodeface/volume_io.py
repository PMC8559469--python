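"""Volume ingest/egress and coordinate canonicalization.

All geometry in this package lives in world millimetres, RAS+ (x: left to
right, y: posterior to anterior, z: inferior to superior). Voxel indices
are 0-based and a voxel is the closed unit cube centred on its grid point.
Volumes are read and written as NIfTI-1 through nibabel; written headers
carry only the geometric fields regenerated from the volume itself, never
descriptive or extension blocks from a source file, so a defaced output
cannot leak identifying header content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError, VolumeIOError

__all__ = [
    "VolumeGrid",
    "Orientation",
    "read_volume",
    "write_volume",
    "to_canonical",
]


@dataclass
class VolumeGrid:
    """A 3D scalar image with its voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"VolumeGrid requires 3D data, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume data contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Column norms of the affine's 3x3 block, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.affine.copy())


@dataclass(frozen=True)
class Orientation:
    """Anatomical direction codes of the three voxel axes, e.g. R, A, S."""

    axis_codes: tuple[str, str, str]

    @property
    def is_canonical(self) -> bool:
        return self.axis_codes == ("R", "A", "S")


def orientation_of(v: VolumeGrid) -> Orientation:
    return Orientation(tuple(nib.orientations.aff2axcodes(v.affine)))


def read_volume(path) -> VolumeGrid:
    """Read a volume file into a :class:`VolumeGrid`.

    Accepts any format nibabel reads natively (NIfTI-1/2, Analyze, MGH...).
    4D volumes with singleton trailing dimensions are squeezed; genuinely
    4D data is rejected. Non-finite voxels are sanitized to 0 with a
    warning, so downstream geometry never sees NaN/Inf.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeIOError(f"cannot read volume {path}: {exc}") from exc

    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        non_singleton = [s for s in data.shape if s > 1]
        if len(non_singleton) > 3:
            raise ValidationError(
                f"{path}: {data.ndim}D volume with >3 non-singleton axes"
            )
        data = np.squeeze(data)
    if data.ndim < 3:
        raise ValidationError(f"{path}: expected 3D data, got shape {data.shape}")

    if not np.all(np.isfinite(data)):
        n_bad = int(np.count_nonzero(~np.isfinite(data)))
        warnings.warn(
            f"{path}: sanitized {n_bad} non-finite voxels to 0", stacklevel=2
        )
        data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)

    return VolumeGrid(data, np.asarray(img.affine))


def write_volume(v: VolumeGrid, path) -> None:
    """Write a NIfTI file whose header holds geometry only.

    The header is built fresh from the volume's dtype and affine; nothing
    (extensions, descriptions, intent fields) is propagated from any source
    file. Non-finite data refuses to write.
    """
    if not np.all(np.isfinite(v.data)):
        raise ValidationError("refusing to write volume containing NaN/Inf")
    img = nib.Nifti1Image(v.data, v.affine)
    img.header.set_data_dtype(v.data.dtype)
    # nibabel starts from a clean header here, but be explicit: no extensions
    img.header.extensions.clear()
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write volume {path}: {exc}") from exc


def to_canonical(v: VolumeGrid, obliquity_tol_deg: float = 5.0) -> VolumeGrid:
    """Reorder/flip axes to the closest-canonical RAS orientation.

    Pure permutation + flips: every voxel keeps its world coordinate
    exactly (no resampling). Volumes more oblique than
    ``obliquity_tol_deg`` still canonicalize but trigger a warning, since
    "anterior" etc. only approximate the voxel axes there.
    """
    ornt = nib.orientations.io_orientation(v.affine)
    current = nib.orientations.ornt2axcodes(ornt)
    # obliquity: worst angle between a voxel axis and its nearest world axis
    cols = v.affine[:3, :3] / np.linalg.norm(v.affine[:3, :3], axis=0)
    worst = np.degrees(np.arccos(np.clip(np.abs(cols).max(axis=0), -1, 1))).max()
    if worst > obliquity_tol_deg:
        warnings.warn(
            f"volume is oblique ({worst:.1f} deg from axis-aligned); "
            "proceeding in world space",
            stacklevel=2,
        )
    if current == ("R", "A", "S"):
        return v
    transform = nib.orientations.ornt_transform(
        ornt, nib.orientations.axcodes2ornt(("R", "A", "S"))
    )
    data = nib.orientations.apply_orientation(v.data, transform)
    affine = v.affine @ nib.orientations.inv_ornt_aff(transform, v.data.shape)
    return VolumeGrid(data, affine)
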