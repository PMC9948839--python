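"""Labeled volumes and diffusion gradient tables.

The central container is :class:`LabeledVolume`: a floating-point image
(3D, or 4D with diffusion volumes stacked on the last axis) together with
an integer label volume on the same spatial grid, the voxel size in mm and
an anatomical orientation code. Images and labels are read and written as
NIfTI-1/2 through nibabel; gradient tables use the FSL bval/bvec text
dialect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "LabeledVolume",
    "GradientScheme",
    "DimensionError",
    "FormatError",
    "DegenerateInputError",
    "read_labeled_volume",
    "write_labeled_volume",
    "read_gradient_scheme",
    "write_gradient_scheme",
    "normalize_volume",
]

log = logging.getLogger(__name__)


class DimensionError(ValueError):
    """Shapes of image and labels (or paired files) do not match."""


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class DegenerateInputError(ValueError):
    """Input is degenerate for the requested operation (e.g. constant image)."""


def _smallest_uint(labels: np.ndarray) -> np.ndarray:
    return labels.astype(np.min_scalar_type(int(labels.max(initial=0))))


@dataclass(frozen=True)
class LabeledVolume:
    """An image volume with its integer label volume and voxel geometry.

    Parameters
    ----------
    image : ndarray
        Floating-point voxel data, shape (nx, ny, nz) or (nx, ny, nz, nvol)
        for diffusion series.
    labels : ndarray
        Non-negative integer labels, spatial shape equal to the image's;
        0 is background.
    voxel_size : tuple of float
        Voxel edge lengths in mm, strictly positive.
    orientation_code : str
        Three-letter anatomical axis code (e.g. ``"LPS"``, ``"PSR"``).
    subject_id : str
        Opaque identifier carried through analyses.
    """

    image: np.ndarray
    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation_code: str = "LPS"
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        image = np.asarray(self.image, dtype=np.float64)
        labels = np.asarray(self.labels)
        if image.ndim not in (3, 4):
            raise DimensionError(f"image must be 3D or 4D, got shape {image.shape}")
        if labels.ndim != 3:
            raise DimensionError(f"labels must be 3D, got shape {labels.shape}")
        if image.shape[:3] != labels.shape:
            raise DimensionError(
                f"spatial shape mismatch: image {image.shape[:3]} vs labels {labels.shape}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if np.abs(labels - rounded).max(initial=0.0) > 1e-6:
                raise FormatError("labels contain non-integer values")
            labels = rounded.astype(np.int64)
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        vs = tuple(float(s) for s in self.voxel_size)
        if len(vs) != 3 or not all(np.isfinite(s) and s > 0 for s in vs):
            raise ValueError(f"voxel_size must be 3 positive finite lengths, got {vs}")
        object.__setattr__(self, "image", image)
        object.__setattr__(self, "labels", _smallest_uint(labels))
        object.__setattr__(self, "voxel_size", vs)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.image.shape[:3]

    @property
    def label_ids(self) -> tuple[int, ...]:
        """Sorted non-background label IDs present in the volume."""
        ids = np.unique(self.labels)
        return tuple(int(i) for i in ids if i != 0)

    def binarize(self, label_id: int) -> np.ndarray:
        """Binary mask of a single label ID."""
        return self.labels == label_id

    def with_image(self, image: np.ndarray) -> "LabeledVolume":
        return replace(self, image=image)

    def with_labels(self, labels: np.ndarray) -> "LabeledVolume":
        return replace(self, labels=labels)


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion-weighting scheme: b-values (s/mm²) and unit direction vectors."""

    bvals: tuple[float, ...]
    bvecs: np.ndarray  # shape (n, 3)
    _norm_tol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        bvals = tuple(float(b) for b in self.bvals)
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=np.float64))
        if bvecs.shape != (len(bvals), 3):
            raise FormatError(
                f"bvecs shape {bvecs.shape} does not match {len(bvals)} b-values"
            )
        if any(b < 0 for b in bvals):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = np.asarray(bvals) > 0
        if np.any(np.abs(norms[weighted] - 1.0) > self._norm_tol):
            raise ValueError("diffusion-weighted b-vectors must have unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)


def _affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    return aff


def read_labeled_volume(image_path, labels_path, subject_id: str | None = None) -> LabeledVolume:
    """Read an image/label NIfTI pair into a :class:`LabeledVolume`.

    Geometry (voxel size, orientation code) is taken from the image header;
    label values are cast to integers with exact value preservation and a
    :class:`FormatError` is raised if any label deviates from an integer by
    more than 1e-6.
    """
    img = nib.load(str(image_path))
    lab = nib.load(str(labels_path))
    image = np.asarray(img.dataobj, dtype=np.float64)
    labels = np.asarray(lab.dataobj)
    if image.shape[:3] != labels.shape[:3] or labels.ndim != 3:
        raise DimensionError(
            f"image shape {image.shape} does not match labels shape {labels.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    code = "".join(nib.aff2axcodes(img.affine))
    if subject_id is None:
        subject_id = str(image_path)
    return LabeledVolume(
        image=image,
        labels=labels,
        voxel_size=tuple(float(z) for z in zooms),
        orientation_code=code,
        subject_id=subject_id,
    )


def write_labeled_volume(v: LabeledVolume, image_path, labels_path) -> None:
    """Write the image and labels of a volume as a NIfTI pair."""
    aff = _affine_from_voxel_size(v.voxel_size)
    nib.save(nib.Nifti1Image(v.image.astype(np.float32), aff), str(image_path))
    nib.save(nib.Nifti1Image(v.labels.astype(np.int32), aff), str(labels_path))


def read_gradient_scheme(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-dialect bval/bvec pair.

    The canonical bvec layout is 3 rows x n columns; a transposed n x 3
    file is accepted with a logged warning. Vectors whose norm is off unity
    by at most 1e-3 are renormalized; larger deviations raise.
    """
    bvals = np.atleast_1d(np.loadtxt(str(bval_path), dtype=np.float64))
    raw = np.loadtxt(str(bvec_path), dtype=np.float64)
    if raw.ndim == 1 and raw.size == 3 and bvals.size == 1:
        raw = raw.reshape(3, 1)  # single-direction file: 3 rows, 1 column
    bvecs = np.atleast_2d(raw)
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        log.warning("bvec file %s is n x 3; transposing to the FSL 3-row layout", bvec_path)
        warnings.warn("bvec file appears transposed (n x 3); accepting", stacklevel=2)
        bvecs = bvecs.T
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have 3 rows (or 3 columns), got shape {bvecs.shape}")
    if bvecs.shape[1] != bvals.size:
        raise FormatError(
            f"{bvals.size} b-values but {bvecs.shape[1]} b-vectors"
        )
    vecs = bvecs.T.copy()
    norms = np.linalg.norm(vecs, axis=1)
    weighted = bvals > 0
    off = np.abs(norms - 1.0)
    if np.any(off[weighted] > 1e-3):
        raise ValueError("b-vector norm deviates from 1 by more than 1e-3")
    nz = weighted & (norms > 0)
    vecs[nz] /= norms[nz, None]
    return GradientScheme(bvals=tuple(bvals.tolist()), bvecs=vecs)


def write_gradient_scheme(g: GradientScheme, bval_path, bvec_path) -> None:
    """Write a gradient scheme in the FSL 3-row bvec dialect."""
    np.savetxt(str(bval_path), np.asarray(g.bvals)[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), g.bvecs.T, fmt="%.8f")


def normalize_volume(v: LabeledVolume) -> LabeledVolume:
    """Z-normalize the image volume-wise to zero mean and unit variance.

    Labels are untouched. A constant image has no defined normalization and
    raises :class:`DegenerateInputError`. Idempotent to float precision.
    """
    image = v.image
    sd = float(image.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("constant image cannot be z-normalized")
    return v.with_image((image - image.mean()) / sd)
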