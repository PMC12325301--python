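"""NIfTI volume containers and grid plumbing.

All images are handled in native voxel space: the pipeline consumes volumes
that are already coregistered onto a common grid (e.g. FreeSurfer T1w space)
and only *verifies* grid agreement, it never resamples or reorients.

Physical volumes are voxel counts times the voxel volume from the header
spacing, reported in millilitres (1 ml = 1000 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from cpseg.errors import GridMismatchError, VolumeLoadError

#: Absolute tolerance (mm) when comparing spacings / affine entries of two
#: grids. Coregistered volumes share headers up to float noise.
GRID_ATOL = 1e-4


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass(eq=False)
class _Volume:
    """Shared fields of all 3-D grids: data, spacing (mm) and affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(eq=False)
class IntensityVolume(_Volume):
    """A 3-D scalar image (e.g. the T2-FLAIR) in arbitrary scanner units.

    Invariant: every voxel is finite. Loading a volume containing NaN/Inf
    fails rather than producing a volume that silently poisons the mixture
    fit downstream.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float64, copy=False)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity volume contains non-finite (NaN/Inf) voxels")


@dataclass(eq=False)
class LabelVolume(_Volume):
    """A 3-D integer parcellation (FreeSurfer aseg-style label IDs)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.rint(self.data).astype(np.int32)
            if not np.allclose(self.data, as_int, atol=1e-6, equal_nan=False):
                raise ValueError("label volume contains non-integer values")
            self.data = as_int
        if self.data.min() < 0:
            raise ValueError("label volume contains negative labels")


@dataclass(eq=False)
class BinaryMask(_Volume):
    """A 3-D boolean region (prior region, predicted CP, ground truth...)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool, copy=False)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


def read_volume(path: str | Path, kind: str = "intensity"):
    """Read a NIfTI (.nii/.nii.gz) file as an intensity, label or mask volume.

    Parameters
    ----------
    path
        Path to the file.
    kind
        One of ``"intensity"``, ``"label"`` or ``"mask"``.

    Raises
    ------
    VolumeLoadError
        Missing file, unreadable header, non-finite intensities, or a
        non-integer label map.
    """
    path = Path(path)
    if kind not in ("intensity", "label", "mask"):
        raise ValueError(f"unknown volume kind {kind!r}")
    if not path.exists():
        raise VolumeLoadError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises various header/IO errors
        raise VolumeLoadError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeLoadError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = img.affine
    try:
        if kind == "intensity":
            return IntensityVolume(data=np.asarray(data, dtype=np.float64),
                                   spacing=spacing, affine=affine)
        if kind == "label":
            return LabelVolume(data=data, spacing=spacing, affine=affine)
        return BinaryMask(data=data > 0, spacing=spacing, affine=affine)
    except ValueError as exc:
        raise VolumeLoadError(f"{path}: {exc}") from exc


def write_mask(mask: BinaryMask, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a binary mask as a uint8 {0,1} NIfTI file.

    ``affine`` overrides the mask's own grid token, e.g. to stamp the mask
    onto the FLAIR header grid.
    """
    aff = np.asarray(affine, dtype=float) if affine is not None else mask.affine
    img = nib.Nifti1Image(mask.data.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(Path(path)))


def write_volume(volume: _Volume, path: str | Path) -> None:
    """Write an intensity or label volume as NIfTI."""
    if isinstance(volume, LabelVolume):
        data = volume.data.astype(np.int32)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(Path(path)))


def volume_ml(mask: BinaryMask) -> float:
    """Physical volume of a mask in millilitres (voxels x voxel volume / 1000)."""
    return mask.voxel_count * mask.voxel_volume_mm3 / 1000.0


def assert_same_grid(a: _Volume, b: _Volume, atol: float = GRID_ATOL) -> None:
    """Raise :class:`GridMismatchError` unless the two volumes share a grid.

    Shapes must match exactly; spacings and affines within ``atol`` mm.
    """
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=atol, rtol=0):
        raise GridMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if not np.allclose(a.affine, b.affine, atol=atol, rtol=0):
        raise GridMismatchError("affine (grid orientation/origin) mismatch")
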