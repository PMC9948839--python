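"""Synthetic phantoms and toy segmenters.

Every stage of the sensitivity framework can be exercised without any
imaging data: :func:`make_phantom` builds a brain-like labeled volume (an
off-center ellipsoid with a protrusion that breaks every mirror and
rotational self-symmetry, so that orientation-sensitive toy segmenters
genuinely discriminate orientations), and the ``make_*_segmenter``
factories return segmenters with designed sensitivities:

* a threshold segmenter (intensity window + largest connected component)
  that is sensitive to intensity scale/offset perturbations;
* a template segmenter (rigid template matching over a candidate
  orientation bank) that is sensitive to rotations — ``identity_only``
  emulates a network trained without rotation augmentation, a
  multi-orientation bank emulates an augmented one;
* an oracle segmenter returning the correspondingly transformed ground
  truth (upper bound), and a constant-background segmenter (lower bound).

Rater simulation for STAPLE lives in :mod:`segsense.staple`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .transforms import (
    IntensityAffine,
    RigidRotation,
    polynomial_intensity_transform,
    rotate_volume,
)
from .volumes import LabeledVolume

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "inject_orientation_bias",
    "make_threshold_segmenter",
    "make_template_segmenter",
    "make_oracle_segmenter",
    "make_constant_segmenter",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue contrast and noise of a synthetic labeled volume.

    The foreground is an ellipsoid with distinct semi-axes (fractions of
    the volume shape), displaced from the volume center, plus a spherical
    protrusion at one end of its long axis, off the mid-plane — the
    combination has no mirror or rotational self-symmetry.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    ellipsoid_semiaxes_frac: tuple[float, float, float] = (0.30, 0.14, 0.09)
    ellipsoid_center_frac: tuple[float, float, float] = (0.56, 0.55, 0.54)
    protrusion_radius_frac: float = 0.10
    tissue_means: tuple[float, float] = (0.0, 1.0)  # background, foreground
    noise_sigma: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape):
            raise ValueError("shape components must be >= 16")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> LabeledVolume:
    """Generate the phantom volume described by ``spec``.

    Image = per-class mean + additive Gaussian noise, reproducible from
    ``spec.rng_seed``. Foreground (label 1) occupies 1-30% of the volume.
    """
    shape = np.asarray(spec.shape, dtype=np.float64)
    center = shape * np.asarray(spec.ellipsoid_center_frac)
    semi = shape * np.asarray(spec.ellipsoid_semiaxes_frac)
    labels = _ellipsoid_mask(spec.shape, center, semi)
    # protrusion: a ball at the +x tip of the long axis, pushed off the
    # ellipsoid's own mid-planes so 180-degree self-rotations break too
    r_prot = float(min(shape) * spec.protrusion_radius_frac)
    prot_center = center + np.array([semi[0], 0.55 * semi[1], 0.75 * semi[2]])
    labels |= _ellipsoid_mask(spec.shape, prot_center, (r_prot, r_prot, r_prot))
    frac = labels.mean()
    if not 0.01 <= frac <= 0.30:
        raise ValueError(f"foreground fraction {frac:.3f} outside [0.01, 0.30]")
    rng = np.random.default_rng(spec.rng_seed)
    bg, fg = spec.tissue_means
    image = np.where(labels, fg, bg).astype(np.float64)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=labels.shape)
    return LabeledVolume(
        image=image,
        labels=labels.astype(np.uint8),
        voxel_size=(1.0, 1.0, 1.0),
        orientation_code="LPS",
        subject_id=f"phantom-seed{spec.rng_seed}",
    )


def inject_orientation_bias(v: LabeledVolume, angles_deg) -> LabeledVolume:
    """Pre-rotate a volume about the volume center to emulate a
    training-sample orientation bias.

    A template segmenter built from the returned volume performs best on
    inputs rotated by the same angles, so the sensitivity-map argmax lands
    at those angles — the bias diagnostic."""
    rot = RigidRotation(angles_deg=tuple(angles_deg), center_mode="volume_center")
    return rotate_volume(v, rot)


def make_threshold_segmenter(lo: float, hi: float):
    """Segmenter: intensity window [lo, hi] + largest connected component.

    Emulates an intensity-tuned model: performance collapses once an
    intensity scale/offset pushes the target tissue class out of the
    window."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")

    def segment(image: np.ndarray, **_ignored) -> np.ndarray:
        mask = (image >= lo) & (image <= hi)
        out = np.zeros(image.shape, dtype=np.uint8)
        if not mask.any():
            return out
        comp, n = ndimage.label(mask)
        if n == 0:
            return out
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        out[comp == (int(np.argmax(sizes)) + 1)] = 1
        return out

    segment.segmenter_id = f"threshold[{lo:g},{hi:g}]"
    return segment


def make_template_segmenter(
    template: LabeledVolume,
    orientations: Sequence[RigidRotation] | str = "identity_only",
):
    """Segmenter: rigid template matching over a candidate orientation bank.

    For each candidate orientation the template image is pre-rotated; at
    call time the candidate maximizing the normalized cross-correlation
    with the input image wins and its rotated template labels are
    returned. ``"identity_only"`` emulates a model trained without
    rotation augmentation; a bank spanning the perturbation range emulates
    a rotation-augmented model (flatter sensitivity map).
    """
    if orientations == "identity_only":
        bank = [RigidRotation(angles_deg=(0, 0, 0))]
    else:
        bank = list(orientations)
        if not bank:
            raise ValueError("orientation bank must be non-empty")
    entries = []
    for rot in bank:
        tv = rotate_volume(template, rot)
        img = tv.image - tv.image.mean()
        norm = np.linalg.norm(img)
        entries.append((img / norm if norm > 0 else img, tv.labels))

    def segment(image: np.ndarray, **_ignored) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 4:
            img = img.mean(axis=-1)
        img = img - img.mean()
        norm = np.linalg.norm(img)
        if norm > 0:
            img = img / norm
        scores = [float(np.vdot(t_img, img)) for t_img, _ in entries]
        return entries[int(np.argmax(scores))][1]

    segment.segmenter_id = f"template[bank={len(entries)}]"
    return segment


def make_oracle_segmenter(v: LabeledVolume):
    """Segmenter returning the ground truth transformed like its input.

    Receives the applied perturbation from the sensitivity engine (it
    opts in via ``wants_transform``) and emits the stored labels under the
    same transform — the perfect-segmenter upper bound of the map."""

    def segment(image: np.ndarray, transform=None, **_ignored) -> np.ndarray:
        if transform is None or isinstance(transform, IntensityAffine):
            return v.labels
        if isinstance(transform, RigidRotation):
            return rotate_volume(v, transform).labels
        return transform(v).labels

    segment.wants_transform = True
    segment.segmenter_id = "oracle"
    return segment


#: ready-made window segmenter matched to the default phantom's foreground
#: class (mean 1.0), usable as a CLI plugin reference
example_threshold_segmenter = None  # assigned below


def make_constant_segmenter(label: int = 0, shape=None):
    """Segmenter emitting a constant label everywhere (default: background)."""

    def segment(image: np.ndarray, **_ignored) -> np.ndarray:
        sp = image.shape[:3] if shape is None else tuple(shape)
        return np.full(sp, label, dtype=np.uint8)

    segment.segmenter_id = f"constant[{label}]"
    return segment


example_threshold_segmenter = make_threshold_segmenter(0.7, 1.3)
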