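"""Anatomical prior construction: merge LV + CP labels, erode by a sphere.

The prior region for each hemisphere is the union of that side's lateral
ventricle and choroid plexus labels from an aseg-style parcellation. Because
the CP sits on the ventricle wall, merging the two labels leaves no gap. The
merged region is then eroded with a spherical structuring element of radius
one voxel, which strips the partial-volume rim at the region boundary before
any intensity modelling.

Default label IDs follow the FreeSurfer colour-table convention
(left LV 4, left CP 31, right LV 43, right CP 63) and are overridable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cpseg.io_core import BinaryMask, LabelVolume

log = logging.getLogger(__name__)

#: FreeSurfer aseg label IDs for the structures of interest.
FS_LEFT_LV = 4
FS_LEFT_CP = 31
FS_RIGHT_LV = 43
FS_RIGHT_CP = 63


@dataclass(frozen=True)
class HemisphereLabels:
    """Label IDs defining one hemisphere's prior region."""

    side: str  # "left" | "right"
    lv_label: int
    cp_label: int

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.lv_label <= 0 or self.cp_label <= 0:
            raise ValueError("label IDs must be positive")
        if self.lv_label == self.cp_label:
            raise ValueError("LV and CP labels must differ")


LEFT = HemisphereLabels("left", FS_LEFT_LV, FS_LEFT_CP)
RIGHT = HemisphereLabels("right", FS_RIGHT_LV, FS_RIGHT_CP)


@dataclass(frozen=True)
class StructuringElement:
    """Spherical (Euclidean-ball) structuring element in voxel units.

    An offset (i, j, k) belongs to the element iff i^2 + j^2 + k^2 <= r^2.
    For radius 1 this is the 6-connected cross (centre + face neighbours) --
    the only sphere whose radius is one voxel.
    """

    radius_voxels: int = 1

    def __post_init__(self) -> None:
        if self.radius_voxels < 1:
            raise ValueError("structuring-element radius must be >= 1 voxel")

    def footprint(self) -> np.ndarray:
        r = self.radius_voxels
        grid = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
        return (grid ** 2).sum(axis=0) <= r * r


def merge_region(labels: LabelVolume, hemi: HemisphereLabels) -> BinaryMask:
    """Binary mask of voxels carrying the hemisphere's LV or CP label.

    An empty region is legal here (it is a pipeline-level error only when
    both hemispheres are empty); a warning is emitted for screening.
    """
    data = np.isin(labels.data, (hemi.lv_label, hemi.cp_label))
    mask = BinaryMask(data=data, spacing=labels.spacing, affine=labels.affine)
    log.info("%s prior region (LV %d + CP %d): %d voxels",
             hemi.side, hemi.lv_label, hemi.cp_label, mask.voxel_count)
    if mask.voxel_count == 0:
        warnings.warn(
            f"{hemi.side} prior region is empty "
            f"(no voxels labelled {hemi.lv_label} or {hemi.cp_label})",
            stacklevel=2,
        )
    return mask


def erode(mask: BinaryMask, elem: StructuringElement | int = 1) -> BinaryMask:
    """Morphological erosion with a spherical kernel.

    A voxel survives only if the whole element, centred on it, lies inside
    the mask; voxels outside the grid count as background, so the output can
    never touch the volume border. Output is always a subset of the input.
    """
    if isinstance(elem, int):
        elem = StructuringElement(elem)
    eroded = ndimage.binary_erosion(mask.data, structure=elem.footprint(),
                                    border_value=0)
    return BinaryMask(data=eroded, spacing=mask.spacing, affine=mask.affine)


def dilate(mask: BinaryMask, elem: StructuringElement | int = 1) -> BinaryMask:
    """Morphological dilation with a spherical kernel (phantom/label plumbing)."""
    if isinstance(elem, int):
        elem = StructuringElement(elem)
    dilated = ndimage.binary_dilation(mask.data, structure=elem.footprint())
    return BinaryMask(data=dilated, spacing=mask.spacing, affine=mask.affine)
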