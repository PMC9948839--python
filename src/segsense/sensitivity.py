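"""Performance-sensitivity analysis of segmenters over perturbation grids.

The engine implements a three-step workflow. Step 1 perturbs a test volume
systematically over an N-dimensional parameter grid (rotations about the
x/y axes, or intensity scale/offset). Step 2 feeds every perturbed volume
to a user-supplied segmenter. Step 3 scores each segmentation with the
Dice coefficient against a reference — the correspondingly transformed
ground-truth labels, or, when no ground truth exists, a STAPLE consensus
built from all back-transformed segmentations — and stores the scores at
their grid coordinates. The resulting map is rendered as a heat map in the
2-D case; structure in the map (peaks, ridges, off-center maxima) reveals
which input parameters the segmenter is sensitive to, and the offset of
the argmax from the identity point diagnoses an orientation/intensity bias
of the segmenter's training sample.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import dice, dice_per_label
from .staple import staple_consensus
from .transforms import (
    IntensityAffine,
    RigidRotation,
    apply_intensity_affine,
    rotate_gradient_scheme,
    rotate_volume,
    rotation_validity_mask,
)
from .volumes import DegenerateInputError, GradientScheme, LabeledVolume

__all__ = [
    "ParameterGrid",
    "SensitivityMap",
    "RunOptions",
    "rotation_grid_case1",
    "intensity_grid_case1",
    "rotation_grid_case2",
    "custom_grid",
    "run_sensitivity",
    "aggregate_maps",
    "map_summary",
    "plot_heatmap",
]

#: Scale factors of the intensity grid: 1/5 .. 1/1.5, then 1.0 .. 5.0.
INTENSITY_SCALE_VALUES: tuple[float, ...] = tuple(
    [1 / 5, 1 / 4.5, 1 / 4, 1 / 3.5, 1 / 3, 1 / 2.5, 1 / 2, 1 / 1.5]
    + [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0]
)

ROTATION_CONVENTION = (
    "extrinsic rotations about fixed world axes, x applied first then y, "
    "right-handed, positive counter-clockwise looking down the axis"
)


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered perturbation axes spanning an N-dimensional parameter space."""

    axes: tuple[tuple[str, tuple[float, ...]], ...]
    kind: str = "custom"

    def __post_init__(self) -> None:
        if self.kind not in ("rotation_xy", "intensity_scale_offset", "custom"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        axes = tuple(
            (str(name), tuple(float(x) for x in values)) for name, values in self.axes
        )
        if not axes or any(not values for _, values in axes):
            raise ValueError("grid needs >=1 axis, each with >=1 value")
        names = [name for name, _ in axes]
        if len(set(names)) != len(names):
            raise ValueError(f"axis names must be unique, got {names}")
        object.__setattr__(self, "axes", axes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(values) for _, values in self.axes)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def points(self):
        """Iterate (index tuple, value dict) in row-major order."""
        value_lists = [values for _, values in self.axes]
        for idx in itertools.product(*(range(len(v)) for v in value_lists)):
            yield idx, {
                name: value_lists[i][idx[i]] for i, (name, _) in enumerate(self.axes)
            }

    def identity_index(self) -> tuple[int, ...] | None:
        """Grid index of the unperturbed point, if present on every axis.

        Identity is angle 0 for rotation axes, scale 1 / offset 0 for
        intensity axes, and 0 for custom axes.
        """
        idx = []
        for name, values in self.axes:
            target = 1.0 if name == "scale" else 0.0
            hits = [i for i, v in enumerate(values) if np.isclose(v, target)]
            if not hits:
                return None
            idx.append(hits[0])
        return tuple(idx)

    def identity_values(self) -> tuple[float, ...]:
        return tuple(1.0 if name == "scale" else 0.0 for name in self.names)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "axes": [{"name": n, "values": list(v)} for n, v in self.axes],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterGrid":
        return cls(
            axes=tuple((a["name"], tuple(a["values"])) for a in d["axes"]),
            kind=d.get("kind", "custom"),
        )


def rotation_grid_case1() -> ParameterGrid:
    """Full-circle x/y rotation grid: [-180 : 20 : 180]°, 19 x 19 points."""
    angles = tuple(float(a) for a in range(-180, 181, 20))
    return ParameterGrid(
        axes=(("x_angle_deg", angles), ("y_angle_deg", angles)),
        kind="rotation_xy",
    )


def intensity_grid_case1() -> ParameterGrid:
    """Intensity scale/offset grid: 17 non-linear scales x 17 offsets.

    Scales run from 1/5 to 5 (reciprocal steps below 1, linear 0.5 steps
    above); offsets from -3.0 to 3.0 in linear steps of 3/8.
    """
    offsets = tuple(float(x) for x in np.arange(-8, 9) * (3.0 / 8.0))
    return ParameterGrid(
        axes=(("scale", INTENSITY_SCALE_VALUES), ("offset", offsets)),
        kind="intensity_scale_offset",
    )


def rotation_grid_case2() -> ParameterGrid:
    """Small-angle x/y rotation grid: -16° to 16° in 2° steps, 17 x 17 points."""
    angles = tuple(float(a) for a in range(-16, 17, 2))
    return ParameterGrid(
        axes=(("x_angle_deg", angles), ("y_angle_deg", angles)),
        kind="rotation_xy",
    )


def custom_grid(axes: Mapping[str, Sequence[float]], kind: str = "custom") -> ParameterGrid:
    """Build a grid from a name -> values mapping (insertion-ordered)."""
    return ParameterGrid(
        axes=tuple((name, tuple(values)) for name, values in axes.items()), kind=kind
    )


@dataclass(frozen=True)
class RunOptions:
    """Options of a sensitivity run.

    ``center_mode`` picks the rotation center (resolved once on the
    pristine volume and then held fixed as an explicit point, so forward
    and inverse transforms share the same geometry). ``normalize`` applies
    z-normalization to the pristine volume before the sweep.
    """

    center_mode: str = "volume_center"
    explicit_center_mm: tuple[float, float, float] | None = None
    scheme: GradientScheme | None = None
    normalize: bool = False
    pad_value: float | None = None
    label_ids: tuple[int, ...] | None = None
    staple_prior: float | str = "auto"
    staple_max_iter: int = 100
    staple_tol: float = 1e-6
    staple_threshold: float = 0.5
    seed: int | None = None


@dataclass(frozen=True)
class SensitivityMap:
    """Dice scores over a parameter grid, per label, with provenance."""

    grid: ParameterGrid
    scores: Mapping[object, np.ndarray]
    degenerate: Mapping[object, np.ndarray]
    reference_mode: str
    subject_id: str
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, arr in self.scores.items():
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"score array for label {key!r} has shape {arr.shape}, "
                    f"grid is {self.grid.shape}"
                )

    @property
    def label_keys(self) -> tuple:
        return tuple(self.scores.keys())

    def mean_over_labels(self) -> np.ndarray:
        """Coordinatewise mean DSC across labels, ignoring degenerate cells."""
        stack = np.stack([np.asarray(self.scores[k], dtype=float) for k in self.scores])
        deg = np.stack([self.degenerate[k] for k in self.scores])
        masked = np.where(deg, np.nan, stack)
        with np.errstate(invalid="ignore"):
            out = np.nanmean(masked, axis=0)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (label, grid point)."""
        rows = []
        for key in self.scores:
            sc = self.scores[key]
            dg = self.degenerate[key]
            for idx, values in self.grid.points():
                row = {"subject_id": self.subject_id, "label_id": key}
                row.update(values)
                row["dsc"] = float(sc[idx])
                row["degenerate_flag"] = bool(dg[idx])
                rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def manifest(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "reference_mode": self.reference_mode,
            "subject_id": self.subject_id,
            "provenance": dict(self.provenance),
        }

    def save_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2, default=str))


def _resolve_center_mm(v: LabeledVolume, options: RunOptions) -> tuple[float, ...]:
    probe = RigidRotation(
        angles_deg=(0, 0, 0),
        center_mode=options.center_mode,
        explicit_center_mm=options.explicit_center_mm,
    )
    from .transforms import _resolve_center_vox  # shared geometry

    center_vox = _resolve_center_vox(v, probe)
    return tuple(float(c * s) for c, s in zip(center_vox, v.voxel_size))


def _point_transform(grid: ParameterGrid, values: Mapping[str, float], center_mm):
    if grid.kind == "rotation_xy":
        return RigidRotation(
            angles_deg=(values.get("x_angle_deg", 0.0), values.get("y_angle_deg", 0.0), 0.0),
            center_mode="explicit",
            explicit_center_mm=center_mm,
        )
    if grid.kind == "intensity_scale_offset":
        return IntensityAffine(scale=values["scale"], offset=values["offset"])
    raise ValueError(
        "custom grids need an explicit transform_factory mapping a grid "
        "point to a transform"
    )


def _call_segmenter(seg, image, scheme, transform):
    kwargs = {}
    if scheme is not None:
        kwargs["scheme"] = scheme
    if getattr(seg, "wants_transform", False):
        kwargs["transform"] = transform
    return seg(image, **kwargs)


def _check_prediction(pred, spatial_shape, point_values) -> np.ndarray:
    pred = np.asarray(pred)
    if pred.shape != tuple(spatial_shape):
        raise ValueError(
            f"segmenter output shape {pred.shape} does not match input spatial "
            f"shape {tuple(spatial_shape)} at grid point {point_values}"
        )
    if not np.issubdtype(pred.dtype, np.integer):
        if not np.issubdtype(pred.dtype, np.bool_):
            rounded = np.rint(pred)
            if np.abs(pred - rounded).max(initial=0) > 0:
                raise ValueError("segmenter output must be integer labels")
            pred = rounded
        pred = pred.astype(np.int64)
    if pred.min(initial=0) < 0:
        raise ValueError("segmenter output labels must be non-negative")
    return pred


def run_sensitivity(
    v: LabeledVolume,
    segmenter: Callable,
    grid: ParameterGrid,
    reference_mode: str = "ground_truth",
    options: RunOptions | None = None,
    transform_factory: Callable | None = None,
) -> SensitivityMap:
    """Sweep a segmenter over a perturbation grid and score every point.

    In ``ground_truth`` mode each perturbed segmentation is scored against
    the identically transformed ground-truth labels (rotation grids) or
    the untouched labels (intensity grids). In ``staple`` mode (rotation
    grids) every segmentation is back-rotated into the pristine space with
    the exact inverse rotation (nearest-neighbor), a per-label STAPLE
    consensus over all back-rotated segmentations serves as the reference,
    and scoring is restricted to the common field of view.

    Every grid point starts from the pristine input volume; results do not
    depend on the evaluation order.
    """
    options = options or RunOptions()
    if reference_mode not in ("ground_truth", "staple"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if reference_mode == "staple" and grid.size < 2:
        raise ValueError("staple mode needs a grid of size >= 2")
    from .volumes import normalize_volume

    if options.normalize:
        v = normalize_volume(v)
    label_ids = options.label_ids or v.label_ids
    if reference_mode == "ground_truth" and not label_ids:
        raise ValueError("ground_truth mode requires non-empty labels")
    center_mm = _resolve_center_mm(v, options)
    seg_id = getattr(segmenter, "segmenter_id", getattr(segmenter, "__name__", "segmenter"))
    provenance = {
        "segmenter_id": str(seg_id),
        "rotation_convention": ROTATION_CONVENTION,
        "rotation_center_mm": list(center_mm),
        "center_mode": options.center_mode,
        "pad_value": options.pad_value,
        "seed": options.seed,
        "staple": {
            "prior": options.staple_prior,
            "max_iter": options.staple_max_iter,
            "tol": options.staple_tol,
            "threshold": options.staple_threshold,
        }
        if reference_mode == "staple"
        else None,
    }

    shape = grid.shape
    if reference_mode == "ground_truth":
        scores = {i: np.zeros(shape) for i in label_ids}
        degenerate = {i: np.zeros(shape, dtype=bool) for i in label_ids}
        for idx, values in grid.points():
            t = (
                transform_factory(values)
                if transform_factory is not None
                else _point_transform(grid, values, center_mm)
            )
            if isinstance(t, RigidRotation):
                pv = rotate_volume(v, t, pad_value=options.pad_value)
                ref_labels = pv.labels
                scheme = (
                    rotate_gradient_scheme(options.scheme, t)
                    if options.scheme is not None
                    else None
                )
            elif isinstance(t, IntensityAffine):
                pv = apply_intensity_affine(v, t)
                ref_labels = v.labels
                scheme = options.scheme
            else:
                pv = t(v)
                ref_labels = pv.labels
                scheme = options.scheme
            pred = _check_prediction(
                _call_segmenter(segmenter, pv.image, scheme, t), v.spatial_shape, values
            )
            for lab, score in dice_per_label(ref_labels, pred, label_ids).items():
                scores[lab][idx] = score.dsc
                degenerate[lab][idx] = score.degenerate
        return SensitivityMap(
            grid=grid,
            scores=scores,
            degenerate=degenerate,
            reference_mode=reference_mode,
            subject_id=v.subject_id,
            provenance=provenance,
        )

    # STAPLE mode: segment, back-rotate everything into the pristine space,
    # build the per-label consensus, then score within the common FOV.
    if grid.kind != "rotation_xy":
        raise ValueError("staple reference mode is defined for rotation grids")
    back_preds: list[np.ndarray] = []
    common_valid = np.ones(v.spatial_shape, dtype=bool)
    indices = []
    for idx, values in grid.points():
        rot = _point_transform(grid, values, center_mm)
        pv = rotate_volume(v, rot, pad_value=options.pad_value)
        scheme = (
            rotate_gradient_scheme(options.scheme, rot)
            if options.scheme is not None
            else None
        )
        pred = _check_prediction(
            _call_segmenter(segmenter, pv.image, scheme, rot), v.spatial_shape, values
        )
        inv = rot.inverse()
        inv_matrix = rot.matrix().T
        carrier = v.with_labels(pred)
        back = rotate_volume(carrier, inv, matrix=inv_matrix, pad_value=0.0).labels
        fwd_valid = rotation_validity_mask(v, rot)
        from scipy import ndimage as _ndi

        from .transforms import _voxel_space_affine

        m, offset = _voxel_space_affine(v, inv, inv_matrix)
        round_valid = _ndi.affine_transform(
            fwd_valid.astype(np.uint8), m, offset=offset, order=0, mode="constant", cval=0
        ).astype(bool)
        common_valid &= round_valid
        back_preds.append(back)
        indices.append(idx)

    if not label_ids:
        present = sorted(
            {int(l) for bp in back_preds for l in np.unique(bp) if l != 0}
        )
        label_ids = tuple(present)
    if not label_ids:
        raise DegenerateInputError("all segmentations empty: no labels to build a consensus")

    scores = {i: np.zeros(shape) for i in label_ids}
    degenerate = {i: np.zeros(shape, dtype=bool) for i in label_ids}
    for lab in label_ids:
        raters = [bp == lab for bp in back_preds]
        if not any(r.any() for r in raters):
            for idx in indices:
                scores[lab][idx] = np.nan
                degenerate[lab][idx] = True
            continue
        consensus = staple_consensus(
            raters,
            prior=options.staple_prior,
            max_iter=options.staple_max_iter,
            tol=options.staple_tol,
            threshold=options.staple_threshold,
            valid_mask=common_valid,
        )
        ref = consensus.consensus_mask[common_valid]
        for idx, rater in zip(indices, raters):
            score = dice(ref, rater[common_valid])
            scores[lab][idx] = score.dsc
            degenerate[lab][idx] = score.degenerate
    provenance["common_fov_voxels"] = int(common_valid.sum())
    return SensitivityMap(
        grid=grid,
        scores=scores,
        degenerate=degenerate,
        reference_mode=reference_mode,
        subject_id=v.subject_id,
        provenance=provenance,
    )


def aggregate_maps(maps: Sequence[SensitivityMap], over: str = "subjects") -> SensitivityMap:
    """Coordinatewise mean of sensitivity maps, skipping degenerate cells.

    ``over="subjects"`` averages per label across maps sharing a grid;
    ``over="labels"`` first averages each map across its labels, then
    across maps, yielding a single ``"mean"`` slice.
    """
    if not maps:
        raise ValueError("need at least one map")
    if over not in ("subjects", "labels"):
        raise ValueError(f"unknown aggregation {over!r}")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("all maps must share an identical grid")
    provenance = {
        "aggregated_over": over,
        "constituents": [m.subject_id for m in maps],
    }
    if over == "subjects":
        keys = maps[0].label_keys
        for m in maps[1:]:
            if m.label_keys != keys:
                raise ValueError("maps must share label keys to aggregate over subjects")
        scores, degenerate = {}, {}
        for key in keys:
            stack = np.stack([np.asarray(m.scores[key], dtype=float) for m in maps])
            deg = np.stack([m.degenerate[key] for m in maps])
            masked = np.where(deg, np.nan, stack)
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(masked, axis=0)
            all_deg = deg.all(axis=0)
            scores[key] = np.where(all_deg, np.nan, mean)
            degenerate[key] = all_deg
    else:
        stack = np.stack([m.mean_over_labels() for m in maps])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        all_deg = np.isnan(stack).all(axis=0)
        scores = {"mean": np.where(all_deg, np.nan, mean)}
        degenerate = {"mean": all_deg}
    return SensitivityMap(
        grid=grid,
        scores=scores,
        degenerate=degenerate,
        reference_mode=maps[0].reference_mode,
        subject_id="aggregate(" + ",".join(str(m.subject_id) for m in maps) + ")",
        provenance=provenance,
    )


def map_summary(m: SensitivityMap, label: object | None = None) -> dict:
    """Summary statistics of one map slice (or the label-mean slice).

    Returns the mean and standard deviation (population convention) of the
    non-degenerate scores, the maximum, the argmax grid coordinates, and
    the offset of the argmax from the grid's identity point — the bias
    diagnostic: a non-zero offset means the segmenter performs best on
    inputs perturbed away from their native state. Argmax ties break to
    the first maximum in row-major order; all tied coordinates are listed.
    """
    if label is None:
        arr = m.mean_over_labels()
    else:
        arr = np.where(m.degenerate[label], np.nan, np.asarray(m.scores[label], dtype=float))
    finite = np.isfinite(arr)
    if not finite.any():
        raise DegenerateInputError("map has no non-degenerate scores")
    vals = arr[finite]
    max_val = float(np.nanmax(arr))
    tied = np.argwhere(np.where(finite, arr, -np.inf) == max_val)
    argmax_idx = tuple(int(i) for i in tied[0])
    argmax_values = tuple(
        m.grid.axes[d][1][argmax_idx[d]] for d in range(len(m.grid.axes))
    )
    ident = m.grid.identity_values()
    return {
        "mean": float(vals.mean()),
        "std": float(vals.std()),
        "max": max_val,
        "argmax_index": argmax_idx,
        "argmax_values": argmax_values,
        "argmax_offset": tuple(a - b for a, b in zip(argmax_values, ident)),
        "argmax_ties": [tuple(int(i) for i in t) for t in tied],
        "n_degenerate": int((~finite).sum()),
    }


def plot_heatmap(m: SensitivityMap, label: object | None = None, path=None, ax=None):
    """Render a 2-D map slice as a heat map (axis 0 vertical, axis 1 horizontal)."""
    if len(m.grid.axes) != 2:
        raise ValueError("heat-map rendering is defined for 2-D grids")
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = (
        m.mean_over_labels()
        if label is None
        else np.where(m.degenerate[label], np.nan, np.asarray(m.scores[label], dtype=float))
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    (name0, vals0), (name1, vals1) = m.grid.axes
    im = ax.imshow(arr, origin="lower", vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(vals1)))
    ax.set_xticklabels([f"{v:g}" for v in vals1], rotation=90, fontsize=6)
    ax.set_yticks(range(len(vals0)))
    ax.set_yticklabels([f"{v:g}" for v in vals0], fontsize=6)
    ax.set_xlabel(name1)
    ax.set_ylabel(name0)
    title = f"{m.subject_id}" + (f" / label {label}" if label is not None else "")
    ax.set_title(title, fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="DSC")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
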