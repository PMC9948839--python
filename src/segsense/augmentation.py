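"""Training-time augmentation samplers.

Two families are provided:

* **Rotation augmentation.** Type 1 mirrors the volume about each of the
  x, y, z axes independently with probability 0.5 (configurable); type 2
  additionally draws a random x-axis rotation from a discrete angle set,
  {0°, 30°, 50°} by default — the x-axis because natural head motion
  (nodding) is mostly about it.

* **Intensity augmentation.** Histogram landmarks (intensity quantiles at
  12.5% .. 87.5% in 12.5% steps by default) summarize each dataset's
  intensity distribution. For every ordered pair of datasets a
  second-degree polynomial transfer function i' = C1*i² + C2*i + C3 is
  least-squares fitted mapping one landmark set onto the other; the
  coefficients over all pairs are fitted to per-coefficient normal
  distributions (sample mean, sample std). During training, coefficients
  are drawn from those normals and applied via
  :func:`segsense.transforms.polynomial_intensity_transform`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volumes import DegenerateInputError

__all__ = [
    "DEFAULT_LANDMARK_FRACTIONS",
    "TransferFunctionModel",
    "RotationAugConfig",
    "extract_landmarks",
    "fit_transfer_function",
    "build_transfer_model",
    "sample_intensity_augmentation",
    "sample_rotation_augmentation",
]

#: 12.5% to 87.5% in steps of 12.5% — 7 landmarks.
DEFAULT_LANDMARK_FRACTIONS: tuple[float, ...] = tuple(
    np.round(np.arange(1, 8) * 0.125, 4)
)


@dataclass(frozen=True)
class TransferFunctionModel:
    """Normal-distribution model of polynomial transfer-function coefficients.

    ``mean_c`` and ``std_c`` are the per-coefficient (C1, C2, C3) sample
    means and sample standard deviations over all ordered dataset pairs;
    ``n_pairs`` counts those pairs.
    """

    mean_c: tuple[float, float, float]
    std_c: tuple[float, float, float]
    n_pairs: int
    landmark_fractions: tuple[float, ...] = DEFAULT_LANDMARK_FRACTIONS

    def __post_init__(self) -> None:
        mean_c = tuple(float(c) for c in self.mean_c)
        std_c = tuple(float(c) for c in self.std_c)
        if len(mean_c) != 3 or len(std_c) != 3:
            raise ValueError("mean_c and std_c must be coefficient triples")
        if any(s < 0 for s in std_c):
            raise ValueError("std_c components must be non-negative")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        fr = tuple(float(f) for f in self.landmark_fractions)
        if any(not (0 < f < 1) for f in fr) or any(
            b <= a for a, b in zip(fr, fr[1:])
        ):
            raise ValueError("landmark_fractions must be strictly increasing in (0,1)")
        object.__setattr__(self, "mean_c", mean_c)
        object.__setattr__(self, "std_c", std_c)
        object.__setattr__(self, "landmark_fractions", fr)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_c": list(self.mean_c),
                "std_c": list(self.std_c),
                "n_pairs": self.n_pairs,
                "landmark_fractions": list(self.landmark_fractions),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TransferFunctionModel":
        d = json.loads(text)
        return cls(
            mean_c=tuple(d["mean_c"]),
            std_c=tuple(d["std_c"]),
            n_pairs=int(d["n_pairs"]),
            landmark_fractions=tuple(d["landmark_fractions"]),
        )


@dataclass(frozen=True)
class RotationAugConfig:
    """Configuration of the mirroring / discrete-rotation augmentation."""

    aug_type: str = "type1"
    mirror_probability: float = 0.5
    discrete_x_angles_deg: tuple[float, ...] = (0.0, 30.0, 50.0)

    def __post_init__(self) -> None:
        if self.aug_type not in ("type1", "type2"):
            raise ValueError("aug_type must be 'type1' or 'type2'")
        if not 0.0 <= self.mirror_probability <= 1.0:
            raise ValueError("mirror_probability must be in [0,1]")
        if self.aug_type == "type2" and not self.discrete_x_angles_deg:
            raise ValueError("type2 requires a non-empty angle set")


def extract_landmarks(
    image: np.ndarray, fractions: Sequence[float] = DEFAULT_LANDMARK_FRACTIONS
) -> np.ndarray:
    """Histogram landmarks: intensity quantiles at the given fractions.

    Quantiles use linear interpolation between order statistics and are
    computed over all voxels (no foreground masking). Output is
    non-decreasing by construction.
    """
    image = np.asarray(image, dtype=np.float64)
    fr = np.asarray(fractions, dtype=np.float64)
    if fr.size == 0 or np.any(fr <= 0) or np.any(fr >= 1) or np.any(np.diff(fr) <= 0):
        raise ValueError("fractions must be strictly increasing in (0,1)")
    if image.max() == image.min():
        raise DegenerateInputError("constant image has no informative landmarks")
    return np.quantile(image, fr)


def fit_transfer_function(
    landmarks_a: Sequence[float], landmarks_b: Sequence[float]
) -> tuple[float, float, float]:
    """Least-squares quadratic (C1, C2, C3) mapping landmarks_a onto landmarks_b.

    Exact (zero residual) whenever b is a quadratic function of a.
    """
    a = np.asarray(landmarks_a, dtype=np.float64)
    b = np.asarray(landmarks_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("landmark lists must have equal length >= 3")
    if np.ptp(a) == 0:
        raise np.linalg.LinAlgError("all source landmarks identical: singular fit")
    c1, c2, c3 = np.polyfit(a, b, 2)
    return float(c1), float(c2), float(c3)


def build_transfer_model(
    landmark_sets: Sequence[Sequence[float]],
    fractions: Sequence[float] = DEFAULT_LANDMARK_FRACTIONS,
) -> TransferFunctionModel:
    """Fit transfer functions for all ordered dataset pairs and summarize.

    Every ordered pair (a, b) with a != b contributes one coefficient
    triple; the model records the sample mean and sample standard deviation
    (ddof=1) of each coefficient over the n*(n-1) pairs.
    """
    sets = [np.asarray(s, dtype=np.float64) for s in landmark_sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 landmark sets")
    coeffs = np.array(
        [
            fit_transfer_function(sets[i], sets[j])
            for i in range(len(sets))
            for j in range(len(sets))
            if i != j
        ]
    )
    return TransferFunctionModel(
        mean_c=tuple(coeffs.mean(axis=0)),
        std_c=tuple(coeffs.std(axis=0, ddof=1)),
        n_pairs=coeffs.shape[0],
        landmark_fractions=tuple(float(f) for f in fractions),
    )


def sample_intensity_augmentation(
    model: TransferFunctionModel, rng: np.random.Generator | int | None = None
) -> tuple[float, float, float]:
    """Draw a coefficient triple, each independently from Normal(mean, std).

    A zero standard deviation returns the mean exactly. ``rng`` may be a
    Generator or a seed.
    """
    rng = np.random.default_rng(rng)
    return tuple(
        float(rng.normal(m, s)) if s > 0 else float(m)
        for m, s in zip(model.mean_c, model.std_c)
    )


def sample_rotation_augmentation(
    cfg: RotationAugConfig, rng: np.random.Generator | int | None = None
) -> tuple[frozenset, float]:
    """Draw (mirror axis subset, x-rotation angle in degrees).

    Each of the axes x, y, z is mirrored independently with
    ``mirror_probability``. Type 1 always returns angle 0; type 2 draws one
    angle uniformly from ``discrete_x_angles_deg``.
    """
    rng = np.random.default_rng(rng)
    axes = frozenset(
        ax for ax in "xyz" if rng.random() < cfg.mirror_probability
    )
    angle = 0.0
    if cfg.aug_type == "type2":
        angle = float(rng.choice(np.asarray(cfg.discrete_x_angles_deg, dtype=np.float64)))
    return axes, angle
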