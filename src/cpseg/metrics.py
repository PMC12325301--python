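"""Segmentation accuracy metrics: Dice, HD95 (mm) and volume difference %.

* DSC = 2TP / (2TP + FP + FN): overlap between predicted and reference
  masks, 1 is perfect. Both masks empty counts as perfect agreement (1.0).
* HD95: the symmetric 95th-percentile Hausdorff distance between mask
  boundaries — the larger of the two directed 95th percentiles of nearest
  boundary-to-boundary distances. Boundaries are the 6-connected surface
  voxels; distances are Euclidean between voxel centres in physical mm;
  percentiles use linear interpolation over the sorted directed distances.
* VD% = 100 (V_pred - V_true) / V_true: relative volume error, reported both
  signed and in magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from cpseg.io_core import BinaryMask, assert_same_grid, volume_ml

log = logging.getLogger(__name__)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy of a (predicted, truth) mask pair plus the two volumes."""

    dsc: float
    hd95_mm: float
    vd_pct_signed: float
    vd_pct_abs: float
    vol_pred_ml: float
    vol_true_ml: float

    def to_dict(self) -> dict:
        return asdict(self)


def dice(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|), in [0, 1]."""
    assert_same_grid(pred, truth)
    size = pred.voxel_count + truth.voxel_count
    if size == 0:
        log.info("dice of two empty masks: 1.0 by convention")
        return 1.0
    inter = int(np.count_nonzero(pred.data & truth.data))
    return 2.0 * inter / size


def boundary(mask: BinaryMask) -> np.ndarray:
    """(n, 3) coordinates of mask voxels with a 6-neighbour outside the mask.

    Voxels beyond the grid edge count as outside, so voxels on the volume
    border are always boundary voxels.
    """
    interior = ndimage.binary_erosion(mask.data, structure=_FACE_STRUCT,
                                      border_value=0)
    return np.argwhere(mask.data & ~interior)


def hd95(pred: BinaryMask, truth: BinaryMask, percentile: float = 95.0) -> float:
    """Symmetric 95th-percentile Hausdorff distance between boundaries, in mm.

    Raises
    ------
    ValueError
        "HD95 undefined for empty mask" if either mask has no voxels.
    """
    assert_same_grid(pred, truth)
    if pred.voxel_count == 0 or truth.voxel_count == 0:
        raise ValueError("HD95 undefined for empty mask")
    spacing = np.asarray(pred.spacing)
    a = boundary(pred) * spacing
    b = boundary(truth) * spacing
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def vd_pct(vol_pred_ml: float, vol_true_ml: float) -> tuple[float, float]:
    """Volume difference percentage (signed, absolute).

    Raises
    ------
    ValueError
        If the reference volume is not positive.
    """
    if vol_true_ml <= 0:
        raise ValueError("VD% undefined for non-positive reference volume")
    signed = 100.0 * (vol_pred_ml - vol_true_ml) / vol_true_ml
    return signed, abs(signed)


def evaluate(pred: BinaryMask, truth: BinaryMask) -> MetricsReport:
    """Full metric report for a (predicted, truth) pair on a shared grid."""
    assert_same_grid(pred, truth)
    vp, vt = volume_ml(pred), volume_ml(truth)
    signed, magnitude = vd_pct(vp, vt)
    return MetricsReport(dsc=dice(pred, truth), hd95_mm=hd95(pred, truth),
                         vd_pct_signed=signed, vd_pct_abs=magnitude,
                         vol_pred_ml=vp, vol_true_ml=vt)
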