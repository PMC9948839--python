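"""Deterministic test-time manipulations of labeled volumes.

Rigid 3D rotations (image: trilinear; labels: nearest-neighbor), axis
mirrorings, linear and polynomial intensity transforms, and co-rotation of
diffusion gradient schemes.

Conventions (fixed and logged into every sensitivity-map provenance):

* rotations are extrinsic about the fixed world axes, right-handed, with
  positive angles counter-clockwise when looking down the axis toward the
  origin;
* a combined (x, y) rotation applies the x-rotation first, then the
  y-rotation, i.e. ``R = R_y @ R_x``;
* gradient b-vectors are rotated by the same world-space matrix as the
  volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .volumes import GradientScheme, LabeledVolume

__all__ = [
    "RigidRotation",
    "IntensityAffine",
    "rotation_matrix",
    "rotate_volume",
    "rotation_validity_mask",
    "mirror_volume",
    "apply_intensity_affine",
    "polynomial_intensity_transform",
    "rotate_gradient_scheme",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

CenterMode = Literal["volume_center", "mass_center", "explicit"]


@dataclass(frozen=True)
class RigidRotation:
    """A rigid rotation by Euler angles about the world x, y, z axes.

    ``angles_deg`` applies x first, then y, then z (extrinsic). The
    rotation center is the geometric volume center, the intensity-weighted
    center of mass, or an explicit world-space point in mm.
    """

    angles_deg: tuple[float, float, float]
    center_mode: CenterMode = "volume_center"
    explicit_center_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.angles_deg)
        if len(a) != 3 or not all(np.isfinite(a)):
            raise ValueError(f"angles_deg must be 3 finite values, got {self.angles_deg}")
        if self.center_mode == "explicit" and self.explicit_center_mm is None:
            raise ValueError("center_mode='explicit' requires explicit_center_mm")
        object.__setattr__(self, "angles_deg", a)

    @property
    def is_identity(self) -> bool:
        return all(a % 360.0 == 0.0 for a in self.angles_deg)

    def matrix(self) -> np.ndarray:
        """3x3 world-space rotation matrix (x, then y, then z)."""
        return rotation_matrix(self.angles_deg)

    def inverse(self) -> "RigidRotation":
        """The inverse rotation about the same center.

        Note the inverse of the x-then-y-then-z composition is z-then-y-
        then-x with negated angles; for single-axis rotations this equals
        negating the angle. The matrix of the returned object is the exact
        transpose only for single-axis rotations, so :func:`rotate_volume`
        accepts an explicit matrix override for compositions.
        """
        return replace(self, angles_deg=tuple(-a for a in self.angles_deg))


@dataclass(frozen=True)
class IntensityAffine:
    """Linear voxel-intensity transform i -> scale * i + offset."""

    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and np.isfinite(self.offset)):
            raise ValueError("scale and offset must be finite")
        if self.scale == 0:
            raise ValueError("scale must be non-zero")


def rotation_matrix(angles_deg) -> np.ndarray:
    """Extrinsic x-then-y-then-z rotation matrix, right-handed, degrees."""
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _background_value(image: np.ndarray) -> float:
    """Median intensity of the one-voxel boundary shell, a robust stand-in
    for the background mode of a continuous-valued image."""
    interior = np.zeros(image.shape[:3], dtype=bool)
    if all(s > 2 for s in image.shape[:3]):
        interior[1:-1, 1:-1, 1:-1] = True
    shell = image[~interior] if image.ndim == 3 else image[~interior, ...]
    return float(np.median(shell))


def _resolve_center_vox(v: LabeledVolume, r: RigidRotation) -> np.ndarray:
    shape = np.asarray(v.spatial_shape, dtype=np.float64)
    vs = np.asarray(v.voxel_size)
    if r.center_mode == "volume_center":
        return (shape - 1) / 2.0
    if r.center_mode == "mass_center":
        img3 = v.image if v.image.ndim == 3 else v.image.mean(axis=-1)
        weights = img3 - img3.min()
        total = weights.sum()
        if total == 0:
            return (shape - 1) / 2.0
        return np.array(ndimage.center_of_mass(weights), dtype=np.float64)
    return np.asarray(r.explicit_center_mm, dtype=np.float64) / vs


def _voxel_space_affine(
    v: LabeledVolume, r: RigidRotation, matrix: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Output-to-input voxel mapping (matrix, offset) for ndimage.affine_transform."""
    rot = r.matrix() if matrix is None else np.asarray(matrix, dtype=np.float64)
    vs = np.asarray(v.voxel_size)
    # world = diag(vs) @ voxel; pull-back uses the inverse rotation
    m = np.diag(1.0 / vs) @ rot.T @ np.diag(vs)
    center = _resolve_center_vox(v, r)
    offset = center - m @ center
    return m, offset


def rotate_volume(
    v: LabeledVolume,
    r: RigidRotation,
    pad_value: float | None = None,
    matrix: np.ndarray | None = None,
) -> LabeledVolume:
    """Resample a volume under a rigid rotation, onto the same grid.

    The image is interpolated trilinearly, labels nearest-neighbor (label
    values are preserved exactly; no new IDs appear). Voxels pulled from
    outside the field of view take ``pad_value`` for the image (default:
    the volume's boundary-shell median, i.e. its background level, ~0 after
    z-normalization) and 0 for the labels.

    ``matrix`` overrides the world-space rotation matrix derived from the
    angles (used for exact inverses of composed rotations).
    """
    if r.is_identity and matrix is None:
        return v
    m, offset = _voxel_space_affine(v, r, matrix)
    if pad_value is None:
        pad_value = _background_value(v.image)
    if v.image.ndim == 3:
        image = ndimage.affine_transform(
            v.image, m, offset=offset, order=1, mode="constant", cval=pad_value
        )
    else:
        image = np.stack(
            [
                ndimage.affine_transform(
                    v.image[..., k], m, offset=offset, order=1, mode="constant", cval=pad_value
                )
                for k in range(v.image.shape[-1])
            ],
            axis=-1,
        )
    labels = ndimage.affine_transform(
        v.labels, m, offset=offset, order=0, mode="constant", cval=0,
        output=v.labels.dtype,
    )
    return replace(v, image=image, labels=labels)


def rotation_validity_mask(
    v: LabeledVolume, r: RigidRotation, matrix: np.ndarray | None = None
) -> np.ndarray:
    """Boolean mask of output voxels whose pull-back stays inside the field of view."""
    if r.is_identity and matrix is None:
        return np.ones(v.spatial_shape, dtype=bool)
    m, offset = _voxel_space_affine(v, r, matrix)
    ones = np.ones(v.spatial_shape, dtype=np.uint8)
    inside = ndimage.affine_transform(
        ones, m, offset=offset, order=0, mode="constant", cval=0
    )
    return inside.astype(bool)


def mirror_volume(v: LabeledVolume, axes) -> LabeledVolume:
    """Reverse image and labels along a subset of the spatial axes x, y, z.

    An involution: applying the same axis set twice restores the input
    voxel-exactly.
    """
    idx = sorted({_AXIS_INDEX[a] if isinstance(a, str) else int(a) for a in axes})
    if any(i not in (0, 1, 2) for i in idx):
        raise ValueError(f"axes must be within {{x,y,z}}, got {axes!r}")
    if not idx:
        return v
    return replace(v, image=np.flip(v.image, axis=idx), labels=np.flip(v.labels, axis=idx))


def apply_intensity_affine(v: LabeledVolume, t: IntensityAffine) -> LabeledVolume:
    """Scale then offset every image voxel; labels unchanged."""
    return v.with_image(v.image * t.scale + t.offset)


def polynomial_intensity_transform(v: LabeledVolume, coefficients) -> LabeledVolume:
    """Second-degree polynomial intensity map i -> c1*i² + c2*i + c3.

    ``coefficients`` is the (c1, c2, c3) triple, highest degree first, as
    produced by the augmentation module's transfer-function fit.
    """
    c1, c2, c3 = (float(c) for c in coefficients)
    if not all(np.isfinite([c1, c2, c3])):
        raise ValueError("coefficients must be finite")
    i = v.image
    return v.with_image(c1 * i * i + c2 * i + c3)


def rotate_gradient_scheme(g: GradientScheme, r: RigidRotation) -> GradientScheme:
    """Co-rotate the diffusion-weighting directions with a volume rotation.

    Every non-zero b-vector is multiplied by the same world-space rotation
    matrix applied to the volume; b-values are unchanged and norms are
    preserved exactly (orthogonal matrix).
    """
    rot = r.matrix()
    vecs = g.bvecs.copy()
    nz = np.linalg.norm(vecs, axis=1) > 0
    vecs[nz] = vecs[nz] @ rot.T
    return GradientScheme(bvals=g.bvals, bvecs=vecs)
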