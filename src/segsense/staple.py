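"""Simultaneous Truth and Performance Level Estimation (binary STAPLE).

STAPLE treats a set of candidate binary segmentations ("raters") of the
same scene as noisy observations of a hidden true segmentation and
estimates, by expectation-maximization, both the voxelwise posterior
probability of the hidden truth and each rater's sensitivity p_k
(true-positive rate) and specificity q_k (true-negative rate).

E-step: given (p_k, q_k) and a global foreground prior g, the posterior
foreground probability of voxel i with rater decisions d_ki is

    W_i = g * prod_k p_k^d_ki (1-p_k)^(1-d_ki)
          / [ that + (1-g) * prod_k (1-q_k)^d_ki q_k^(1-d_ki) ]

M-step: p_k = sum_i W_i d_ki / sum_i W_i and
q_k = sum_i (1-W_i)(1-d_ki) / sum_i (1-W_i).

The observed-data log-likelihood is non-decreasing over iterations (an EM
guarantee, checked in tests); iteration stops when the mean absolute
posterior change drops below ``tol``.

The estimate is only as good as the rater set: with mostly-random raters
the consensus degrades — reference building needs a sufficiently high
number of meaningful segmentations in the set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .volumes import DegenerateInputError, DimensionError

__all__ = ["StapleResult", "staple_consensus", "simulate_raters"]

_EPS = 1e-12


@dataclass(frozen=True)
class StapleResult:
    """Output of binary STAPLE.

    ``consensus_probability`` holds the voxelwise posterior foreground
    probability; ``consensus_mask`` is its thresholding at
    ``threshold`` (default 0.5). ``sensitivities``/``specificities`` are
    the per-rater performance estimates, ordered as the input raters.
    """

    consensus_probability: np.ndarray
    consensus_mask: np.ndarray
    sensitivities: tuple[float, ...]
    specificities: tuple[float, ...]
    n_iterations: int
    converged: bool
    log_likelihood: tuple[float, ...] = ()
    threshold: float = 0.5

    def performance_table(self) -> pd.DataFrame:
        """Per-rater sensitivity/specificity as a tidy table."""
        return pd.DataFrame(
            {
                "rater_id": np.arange(len(self.sensitivities)),
                "sensitivity": self.sensitivities,
                "specificity": self.specificities,
            }
        )


def staple_consensus(
    raters: Sequence[np.ndarray],
    prior: float | str = "auto",
    max_iter: int = 100,
    tol: float = 1e-6,
    threshold: float = 0.5,
    valid_mask: np.ndarray | None = None,
) -> StapleResult:
    """Estimate a consensus segmentation and rater performances by EM.

    Parameters
    ----------
    raters : sequence of binary arrays
        At least two candidate segmentations of identical shape.
    prior : float or "auto"
        Global foreground prior probability; "auto" uses the mean
        foreground fraction across raters.
    max_iter, tol : int, float
        EM stops when the mean absolute change of the posterior drops
        below ``tol``, or after ``max_iter`` iterations.
    threshold : float
        Posterior cut for the binary consensus mask.
    valid_mask : boolean array, optional
        Voxels to include in the estimation (e.g. the common field of view
        after back-rotation); excluded voxels get probability 0.

    Raters identical and uniform (all-foreground or all-background
    everywhere) leave the performance parameters unidentifiable and raise
    :class:`DegenerateInputError`.
    """
    if len(raters) < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    shape = np.asarray(raters[0]).shape
    for k, m in enumerate(raters):
        if np.asarray(m).shape != shape:
            raise DimensionError(
                f"rater {k} shape {np.asarray(m).shape} differs from {shape}"
            )
    d_full = np.stack([np.asarray(m).astype(bool).ravel() for m in raters])  # (K, N)
    if valid_mask is not None:
        valid = np.asarray(valid_mask).astype(bool).ravel()
        if valid.size != d_full.shape[1]:
            raise DimensionError("valid_mask shape does not match raters")
        d = d_full[:, valid]
    else:
        valid = None
        d = d_full
    n_on = d.sum()
    if n_on == 0 or n_on == d.size:
        raise DegenerateInputError(
            "raters are uniformly all-background or all-foreground; "
            "performance parameters are unidentifiable"
        )
    k_raters, n_vox = d.shape

    if prior == "auto":
        g = float(d.mean())
    else:
        g = float(prior)
        if not 0.0 < g < 1.0:
            raise ValueError("prior must be in (0,1)")

    p = np.full(k_raters, 0.9999)
    q = np.full(k_raters, 0.9999)
    d_f = d.astype(np.float64)
    w_prev = np.full(n_vox, g)
    ll_trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step in log space for numerical safety
        log_a = np.log(g) + d_f.T @ np.log(p + _EPS) + (1 - d_f).T @ np.log(1 - p + _EPS)
        log_b = (
            np.log(1 - g)
            + d_f.T @ np.log(1 - q + _EPS)
            + (1 - d_f).T @ np.log(q + _EPS)
        )
        m = np.maximum(log_a, log_b)
        denom = np.exp(log_a - m) + np.exp(log_b - m)
        w = np.exp(log_a - m) / denom
        ll_trace.append(float(np.sum(m + np.log(denom))))
        # M-step
        sw = w.sum()
        snw = n_vox - sw
        p = (d_f @ w) / max(sw, _EPS)
        q = ((1 - d_f) @ (1 - w)) / max(snw, _EPS)
        np.clip(p, _EPS, 1 - _EPS, out=p)
        np.clip(q, _EPS, 1 - _EPS, out=q)
        delta = float(np.abs(w - w_prev).mean())
        w_prev = w
        if delta < tol:
            converged = True
            break

    if valid is not None:
        prob = np.zeros(d_full.shape[1])
        prob[valid] = w
    else:
        prob = w
    prob = prob.reshape(shape)
    return StapleResult(
        consensus_probability=prob,
        consensus_mask=prob >= threshold,
        sensitivities=tuple(float(x) for x in p),
        specificities=tuple(float(x) for x in q),
        n_iterations=n_iter,
        converged=converged,
        log_likelihood=tuple(ll_trace),
        threshold=threshold,
    )


def simulate_raters(
    truth: np.ndarray,
    sens: Sequence[float],
    spec: Sequence[float],
    rng: np.random.Generator | int | None = None,
) -> list[np.ndarray]:
    """Simulate independent raters with known sensitivity/specificity.

    Rater k marks each true-foreground voxel with probability ``sens[k]``
    and each true-background voxel with probability ``1 - spec[k]``,
    independently across voxels. Reproducible for a fixed seed.
    """
    sens = list(sens)
    spec = list(spec)
    if len(sens) != len(spec) or not sens:
        raise ValueError("sens and spec must have equal length >= 1")
    if any(not (0 < v <= 1) for v in sens + spec):
        raise ValueError("sensitivities and specificities must lie in (0, 1]")
    truth = np.asarray(truth).astype(bool)
    rng = np.random.default_rng(rng)
    masks = []
    for p_k, q_k in zip(sens, spec):
        u = rng.random(truth.shape)
        masks.append(np.where(truth, u < p_k, u < (1 - q_k)))
    return masks
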