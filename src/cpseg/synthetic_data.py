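"""Seeded 3-D phantoms with the statistical structure the method assumes.

Each phantom mimics a T2-FLAIR slab around the lateral ventricles: per
hemisphere an ellipsoidal ventricle whose interior holds three intensity
classes -- dark suppressed fluid (CSF) in the core, an intermediate
partial-volume shell along the wall, and bright choroid plexus blobs
attached to the wall from inside -- surrounded by a dim background. The
generator emits the intensity volume, an aseg-style label map that serves as
the (deliberately imperfect) anatomical prior, and the exact ground-truth
CP mask.

Two deliberate imperfections mirror real data:

* The emitted CP label is an eroded subset of the truth blobs (automated CP
  labels under-cover), so the prior constrains but does not dictate the CP.
* Blobs touch the ventricle wall, so the pipeline's one-voxel erosion of the
  prior region removes a thin rim of true CP -- the phantom therefore
  reproduces the slight, systematic volume underestimation characteristic
  of the erosion step.

Class means default to csf 55, shell 480, cp 1400 (scanner units): with the
default geometry, the region fractions put the region-normalized class means
near 0.15 / 1.5 / 4, the regime the published mixture initialization was
designed for.

All randomness flows from ``PhantomSpec.seed``; the same spec always yields
the identical triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from cpseg.io_core import BinaryMask, IntensityVolume, LabelVolume
from cpseg.region_prior import (
    FS_LEFT_CP,
    FS_LEFT_LV,
    FS_RIGHT_CP,
    FS_RIGHT_LV,
    StructuringElement,
)
from scipy import ndimage


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates (centre, semi-axes)."""

    centre: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError("ellipsoid semi-axes must be positive")


@dataclass(frozen=True)
class ClassIntensity:
    """Mean and standard deviation of one tissue class, in scanner units."""

    mean: float
    sd: float


@dataclass
class PhantomSpec:
    """Full description of one phantom; every field has a working default."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ventricles: Mapping[str, Ellipsoid] = field(default_factory=lambda: {
        "left": Ellipsoid((21.0, 32.0, 32.0), (10.5, 13.5, 8.5)),
        "right": Ellipsoid((43.0, 32.0, 32.0), (10.5, 13.5, 8.5)),
    })
    cp_blob_count: int = 2
    blob_radius_range: tuple[float, float] = (3.0, 3.6)
    blob_centre_jitter: float = 0.5
    csf: ClassIntensity = ClassIntensity(55.0, 8.0)
    shell: ClassIntensity = ClassIntensity(480.0, 100.0)
    cp: ClassIntensity = ClassIntensity(1400.0, 90.0)
    background: ClassIntensity = ClassIntensity(40.0, 10.0)
    shell_width_voxels: float = 3.0
    noise_sd: float = 25.0
    prior_dilation_voxels: int = 0
    cp_label_erosion_voxels: int = 1
    rician: bool = False
    seed: int = 7

    def validate(self) -> None:
        lo, hi = self.blob_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("blob radius range must be positive and ordered")
        if not (self.csf.mean < self.shell.mean < self.cp.mean):
            raise ValueError("class means must satisfy csf < shell < cp")
        if self.shell_width_voxels <= 0:
            raise ValueError("shell width must be positive")
        if self.cp_blob_count < 0:
            raise ValueError("blob count must be >= 0")


_SIDE_LABELS = {"left": (FS_LEFT_LV, FS_LEFT_CP),
                "right": (FS_RIGHT_LV, FS_RIGHT_CP)}


def _ellipsoid_mask(shape, ell: Ellipsoid, shrink: float = 0.0) -> np.ndarray:
    """Voxels inside the ellipsoid with semi-axes reduced by ``shrink``."""
    axes = np.maximum(np.asarray(ell.semiaxes) - shrink, 0.5)
    grids = np.ogrid[:shape[0], :shape[1], :shape[2]]
    rho = sum(((g - c) / a) ** 2
              for g, c, a in zip(grids, ell.centre, axes))
    return rho <= 1.0


def _sphere_mask(shape, centre: np.ndarray, radius: float) -> np.ndarray:
    grids = np.ogrid[:shape[0], :shape[1], :shape[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return d2 <= radius * radius


def _place_blobs(shape, ell: Ellipsoid, spec: PhantomSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Union of CP blobs attached to the ventricle wall, clipped to it.

    Blob centres sit along random radial directions at a depth of one blob
    radius inside the wall, so each blob's outer surface touches the wall:
    after the prior region is eroded by one voxel, the outermost blob rim
    lies outside the eroded region by construction.
    """
    blobs = np.zeros(shape, dtype=bool)
    lo, hi = spec.blob_radius_range
    centre = np.asarray(ell.centre)
    axes = np.asarray(ell.semiaxes)
    for _ in range(spec.cp_blob_count):
        radius = rng.uniform(lo, hi)
        if radius <= 0:
            raise ValueError("non-positive blob radius")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # distance from the ventricle centre to the wall along this ray
        t_wall = 1.0 / np.sqrt(((direction / axes) ** 2).sum())
        blob_centre = (centre + (t_wall - radius) * direction
                       + rng.normal(scale=spec.blob_centre_jitter, size=3))
        if (np.any(blob_centre - radius < -0.5)
                or np.any(blob_centre + radius > np.asarray(shape) - 0.5)):
            raise ValueError("CP blob would exit the grid")
        blobs |= _sphere_mask(shape, blob_centre, radius)
    return blobs


def generate(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume, BinaryMask]:
    """Render the phantom: (FLAIR-like volume, prior label map, truth CP mask)."""
    spec.validate()
    shape = tuple(spec.grid_shape)
    rng = np.random.default_rng(spec.seed)
    affine = np.diag((*spec.spacing_mm, 1.0))

    labels = np.zeros(shape, dtype=np.int32)
    truth = np.zeros(shape, dtype=bool)
    csf_all = np.zeros(shape, dtype=bool)
    shell_all = np.zeros(shape, dtype=bool)

    ball = StructuringElement(1).footprint()
    for side in ("left", "right"):
        ell = spec.ventricles.get(side)
        if ell is None:
            continue
        ventricle = _ellipsoid_mask(shape, ell)
        core = _ellipsoid_mask(shape, ell, shrink=spec.shell_width_voxels)
        blobs = _place_blobs(shape, ell, spec, rng) & ventricle
        truth |= blobs
        csf_all |= core & ~blobs
        shell_all |= ventricle & ~core & ~blobs

        lv_label, cp_label = _SIDE_LABELS[side]
        lv_region = ventricle
        if spec.prior_dilation_voxels > 0:
            lv_region = ndimage.binary_dilation(
                lv_region, ball, iterations=spec.prior_dilation_voxels)
        elif spec.prior_dilation_voxels < 0:
            lv_region = ndimage.binary_erosion(
                lv_region, ball, iterations=-spec.prior_dilation_voxels,
                border_value=0)
        cp_labelled = blobs
        if spec.cp_label_erosion_voxels > 0:
            cp_labelled = ndimage.binary_erosion(
                blobs, ball, iterations=spec.cp_label_erosion_voxels,
                border_value=0)
        labels[lv_region] = lv_label
        labels[cp_labelled] = cp_label

    intensity = rng.normal(spec.background.mean, spec.background.sd, shape)
    for mask, cls in ((csf_all, spec.csf), (shell_all, spec.shell),
                      (truth, spec.cp)):
        n = int(mask.sum())
        if n:
            intensity[mask] = rng.normal(cls.mean, cls.sd, n)
    if spec.rician:
        re = intensity + rng.normal(0.0, spec.noise_sd, shape)
        im = rng.normal(0.0, spec.noise_sd, shape)
        intensity = np.hypot(re, im)
    elif spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, shape)
    intensity = np.clip(intensity, 0.0, None)

    flair = IntensityVolume(data=intensity, spacing=spec.spacing_mm, affine=affine)
    aseg = LabelVolume(data=labels, spacing=spec.spacing_mm, affine=affine)
    truth_cp = BinaryMask(data=truth, spacing=spec.spacing_mm, affine=affine)
    return flair, aseg, truth_cp


PRESET_NAMES = ("default", "noisy", "small_cp", "one_sided")


def preset(name: str, seed: int | None = None) -> PhantomSpec:
    """Fixed phantom regimes.

    * ``default`` -- 64^3 grid, 1 mm isotropic, low noise, three medium CP
      blobs per side; the reference regime for end-to-end checks.
    * ``noisy`` -- same geometry with heavy class spread and additive noise.
    * ``small_cp`` -- fewer, smaller blobs (low-CP-volume subjects).
    * ``one_sided`` -- the right ventricle (and its labels) absent entirely.

    ``seed`` overrides the preset's fixed seed.
    """
    if name == "default":
        spec = PhantomSpec(seed=7)
    elif name == "noisy":
        spec = PhantomSpec(
            csf=ClassIntensity(55.0, 15.0),
            shell=ClassIntensity(480.0, 160.0),
            cp=ClassIntensity(1400.0, 250.0),
            background=ClassIntensity(40.0, 15.0),
            noise_sd=150.0,
            seed=11,
        )
    elif name == "small_cp":
        spec = PhantomSpec(cp_blob_count=2, blob_radius_range=(2.2, 2.6), seed=13)
    elif name == "one_sided":
        spec = PhantomSpec(
            ventricles={"left": Ellipsoid((21.0, 32.0, 32.0), (10.5, 13.5, 8.5))},
            seed=17,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    return spec
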