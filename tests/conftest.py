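"""Shared fixtures and brute-force oracles for the cpseg test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cpseg.io_core import BinaryMask
from cpseg.pipeline import segment
from cpseg.synthetic_data import generate, preset

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations they check)
# ---------------------------------------------------------------------------


def ball_offsets(radius: int) -> list[tuple[int, int, int]]:
    """Offsets (i, j, k) with i^2 + j^2 + k^2 <= radius^2, by enumeration."""
    return [(i, j, k)
            for i in range(-radius, radius + 1)
            for j in range(-radius, radius + 1)
            for k in range(-radius, radius + 1)
            if i * i + j * j + k * k <= radius * radius]


def erode_oracle(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """O(N * |element|) erosion: a voxel survives iff every element offset
    lands on a foreground voxel inside the grid."""
    offsets = ball_offsets(radius)
    shape = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for idx in np.ndindex(shape):
        keep = True
        for off in offsets:
            p = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
            if (not (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]
                     and 0 <= p[2] < shape[2])) or not mask[p]:
                keep = False
                break
        out[idx] = keep
    return out


def boundary_oracle(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a 6-neighbour that is background or out-of-grid."""
    shape = mask.shape
    coords = []
    for idx in zip(*np.nonzero(mask)):
        for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)):
            p = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
            outside = not (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]
                           and 0 <= p[2] < shape[2])
            if outside or not mask[p]:
                coords.append(idx)
                break
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def percentile_oracle(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile, written out explicitly."""
    s = np.sort(np.asarray(values, dtype=float))
    h = (s.size - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, s.size - 1)
    return float(s[lo] + (s[hi] - s[lo]) * (h - lo))


def hd95_oracle(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs symmetric 95th-percentile boundary distance in mm."""
    pa = boundary_oracle(a) * np.asarray(spacing)
    pb = boundary_oracle(b) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return max(percentile_oracle(d.min(axis=1), 95.0),
               percentile_oracle(d.min(axis=0), 95.0))


def dice_oracle(a: np.ndarray, b: np.ndarray) -> float:
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    if tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def random_blob_mask(rng: np.random.Generator, shape, p: float = 0.35,
                     ensure_nonempty: bool = True) -> np.ndarray:
    """Random mask with spatial structure (union of random boxes + noise)."""
    mask = rng.random(shape) < p * 0.3
    for _ in range(rng.integers(1, 4)):
        lo = [rng.integers(0, max(1, s - 2)) for s in shape]
        hi = [min(s, low + rng.integers(2, max(3, s // 2)))
              for low, s in zip(lo, shape)]
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    if ensure_nonempty and not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask


def as_mask(data: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(data=np.asarray(data, dtype=bool), spacing=spacing)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_phantom():
    """The reference phantom triple (FLAIR, labels, truth) at its fixed seed."""
    return generate(preset("default"))


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    flair, labels, _ = default_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return segment(flair, labels)
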