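"""Ground-truth phantoms for end-to-end testing without patient data.

A phantom is the canonical model posed by a known, randomly drawn affine
transform, optionally degraded the way conventional-CT landmark picking
degrades coordinates: by quantizing every coordinate to the 0.3 mm voxel
grid (the dominant error source when landmarks can only be placed on voxel
centers), or by isotropic Gaussian jitter for robustness sweeps.  A binary
voxel mask of the model tube can be rasterized for pipelines that expect a
segmentation volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError
from .landmarks import LandmarkSet, PlacementScheme, place_landmarks
from .model import Centerline, CochlearParams, build_centerline, mean_params
from .registration import AffineParams, apply_transform, compose_transform

__all__ = [
    "PhantomSpec",
    "Phantom",
    "VoxelMask",
    "make_phantom",
    "rasterize_mask",
]

#: Conventional-CT voxel edge length, mm.
DEFAULT_VOXEL_MM = 0.3

_NOISE_KINDS = ("none", "quantize", "gaussian")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom: model, placement scheme, pose ranges, noise.

    Pose ranges: all three rotation angles uniform over the full circle,
    translations uniform in ±20 mm, scales uniform in [0.8, 1.2], shears
    uniform in [−0.2, 0.2] — affine but anatomically plausible.
    """

    params: CochlearParams = field(default_factory=mean_params)
    scheme: PlacementScheme = field(default_factory=PlacementScheme)
    translation_mm: float = 20.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    shear_limit: float = 0.2
    voxel_mm: float = DEFAULT_VOXEL_MM
    noise: str = "none"
    noise_sigma_mm: float = 0.0
    seed: int = 0
    with_mask: bool = False

    def __post_init__(self) -> None:
        if self.noise not in _NOISE_KINDS:
            raise ParameterError(f"noise must be one of {_NOISE_KINDS}, got {self.noise!r}")
        if not self.voxel_mm > 0:
            raise ParameterError("voxel_mm must be positive")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ParameterError(f"scale range must be positive, got {self.scale_range!r}")
        if self.noise == "gaussian" and not self.noise_sigma_mm > 0:
            raise ParameterError("gaussian noise needs noise_sigma_mm > 0")


@dataclass(frozen=True)
class VoxelMask:
    """Binary isotropic voxel grid; voxel (i,j,k) is centered at
    origin + (i,j,k)·spacing, all in mm."""

    data: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        if not self.spacing_mm > 0:
            raise ParameterError("spacing must be positive")
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3 or not data.any():
            raise GeometryError("mask must be 3D with non-empty foreground")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, dtype=float))

    def foreground_bbox_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_corner, max_corner) of foreground voxel centers, mm."""
        idx = np.argwhere(self.data)
        return (
            self.origin_mm + idx.min(axis=0) * self.spacing_mm,
            self.origin_mm + idx.max(axis=0) * self.spacing_mm,
        )


@dataclass(frozen=True)
class Phantom:
    """A generated phantom with its ground truth pose."""

    spec: PhantomSpec
    true_pose: AffineParams
    model_landmarks: LandmarkSet
    target_landmarks: LandmarkSet
    mask: VoxelMask | None = None

    @property
    def true_matrix(self) -> np.ndarray:
        return compose_transform(self.true_pose)


def _sample_pose(spec: PhantomSpec, rng: np.random.Generator) -> AffineParams:
    ang = rng.uniform(-np.pi, np.pi, size=3)
    t = rng.uniform(-spec.translation_mm, spec.translation_mm, size=3)
    c = rng.uniform(*spec.scale_range, size=3)
    s = rng.uniform(-spec.shear_limit, spec.shear_limit, size=3)
    return AffineParams(*ang, *t, *c, *s)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a phantom: pose the model landmarks, then corrupt the target.

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    landmark arrays.  With ``noise='quantize'`` every target coordinate is
    rounded to the nearest multiple of ``voxel_mm`` (so each coordinate moves
    by at most half a voxel); with ``'gaussian'`` isotropic jitter of the
    given sigma is added.
    """
    rng = np.random.default_rng(spec.seed)
    pose = _sample_pose(spec, rng)
    centerline = build_centerline(spec.params)
    l_M = place_landmarks(centerline, spec.scheme)
    target = apply_transform(compose_transform(pose), l_M).points
    if spec.noise == "quantize":
        target = np.round(target / spec.voxel_mm) * spec.voxel_mm
    elif spec.noise == "gaussian":
        target = target + rng.normal(0.0, spec.noise_sigma_mm, size=target.shape)
    l_C = LandmarkSet(target, source="segmented")
    mask = None
    if spec.with_mask:
        mask = rasterize_mask(centerline, 0.6, spec.voxel_mm)
    return Phantom(
        spec=spec,
        true_pose=pose,
        model_landmarks=l_M,
        target_landmarks=l_C,
        mask=mask,
    )


def rasterize_mask(
    centerline: Centerline,
    tube_radius: float | Callable[[float], float],
    voxel_mm: float = DEFAULT_VOXEL_MM,
) -> VoxelMask:
    """Rasterize the centerline as a tube into a binary isotropic voxel grid.

    ``tube_radius`` is either a constant (mm) or a function of the unwound
    angle in degrees, letting the tube taper toward the apex.  A voxel is
    foreground when its center lies within the local tube radius of the
    densely resampled centerline.
    """
    if not voxel_mm > 0:
        raise ParameterError("voxel_mm must be positive")
    angles = centerline.angles_deg
    # dense resampling at ~1° so the tube has no gaps at coarse centerlines
    fine = np.arange(angles[0], angles[-1], 1.0)
    fine = np.append(fine, angles[-1])
    samples = np.column_stack(
        [np.interp(fine, angles, centerline.points[:, k]) for k in range(3)]
    )
    if callable(tube_radius):
        radii = np.asarray([float(tube_radius(a)) for a in fine])
    else:
        radii = np.full(fine.shape, float(tube_radius))
    if np.any(radii <= 0):
        raise ParameterError("tube radius must be positive everywhere")
    rmax = float(radii.max())
    lo = samples.min(axis=0) - rmax - voxel_mm
    hi = samples.max(axis=0) + rmax + voxel_mm
    origin = np.floor(lo / voxel_mm) * voxel_mm
    shape = np.ceil((hi - origin) / voxel_mm).astype(int) + 1
    grid = np.zeros(tuple(shape), dtype=bool)
    centers_idx = np.indices(tuple(shape)).reshape(3, -1).T
    centers = origin + centers_idx * voxel_mm
    tree = cKDTree(centers)
    for pt, r in zip(samples, radii):
        hit = tree.query_ball_point(pt, r)
        if hit:
            flat = np.asarray(hit)
            grid.reshape(-1)[flat] = True
    return VoxelMask(grid, voxel_mm, origin)
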