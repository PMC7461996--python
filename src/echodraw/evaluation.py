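"""Scoring trained networks: trajectory error, rasterization, classification,
and the separation-scaling (gamma) sweep experiment.

The primary score is the mean squared trajectory error

    d = (1/N_ex) * sum_i sum_j [(x_ij^t - x_ij^a)^2 + (y_ij^t - y_ij^a)^2],

a per-example *sum* over the N_points drawn coordinates, averaged over
examples (coordinates are conventionally in the unit square, so errors are
comparable across fixtures).  Recognizability is scored with a
nearest-template classifier over the same distance; a 28x28 rasterizer is
provided so an external image classifier can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import line as _draw_line

from .exceptions import DataError, ShapeError
from .reservoir import ReservoirParams, WeightSet
from .synthetic import Trajectory2D
from .training import TrainingConfig, _motor_rates, _ordered, train_full
from .separation import LabeledDynamics, scatter_summary, vectorize

__all__ = [
    "ErrorReport",
    "SweepResult",
    "Classification",
    "trajectory_error",
    "rasterize",
    "save_pgm",
    "nearest_template_classify",
    "evaluate_model",
    "gamma_sweep",
]


@dataclass(frozen=True)
class ErrorReport:
    """Mean squared coordinate error d with per-example breakdown."""

    d: float
    per_example: np.ndarray
    n_ex: int
    n_points: int


@dataclass(frozen=True)
class Classification:
    """Nearest-template result: predicted label, margin, tie flag."""

    label: object
    margin: float
    tie: bool


@dataclass
class SweepResult:
    """Per-gamma diagnostics of the separation-scaling sweep."""

    gammas: list
    sp: list
    dr: list
    d: list
    argmin_d_gamma: float
    argmax_dr_gamma: float


def _xy(traj) -> np.ndarray:
    xy = traj.xy if isinstance(traj, Trajectory2D) else np.asarray(traj, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ShapeError(f"trajectory must be (N, 2), got {xy.shape}")
    return xy


def _example_error(actual: np.ndarray, target: np.ndarray) -> float:
    if actual.shape != target.shape:
        raise DataError(
            f"point-count mismatch: {actual.shape} vs {target.shape}"
        )
    return float(np.sum((actual - target) ** 2))


def trajectory_error(actual: Sequence, target: Sequence) -> ErrorReport:
    """Mean over examples of the per-example summed squared coordinate error."""
    if len(actual) != len(target) or not actual:
        raise DataError("actual and target lists must be nonempty and matched")
    per = np.array(
        [_example_error(_xy(a), _xy(t)) for a, t in zip(actual, target)]
    )
    n_points = _xy(actual[0]).shape[0]
    return ErrorReport(
        d=float(per.mean()), per_example=per, n_ex=len(per), n_points=n_points
    )


def rasterize(traj, grid: int = 28, margin: int = 2) -> np.ndarray:
    """Draw a trajectory as a binary ``grid x grid`` image.

    Coordinates are normalized with a common (aspect-preserving) scale into
    the grid minus the margin, centered, then consecutive points are
    connected with line rasterization.  A single-point (or zero-extent)
    trajectory lights one centered pixel.  Row 0 is the top of the image.
    """
    xy = _xy(traj)
    span_x = float(xy[:, 0].max() - xy[:, 0].min())
    span_y = float(xy[:, 1].max() - xy[:, 1].min())
    span = max(span_x, span_y)
    usable = grid - 1 - 2 * margin
    img = np.zeros((grid, grid), dtype=np.uint8)
    if span == 0.0:
        img[grid // 2, grid // 2] = 1
        return img
    # center the shorter extent inside the square box
    off_x = (span - span_x) / 2.0
    off_y = (span - span_y) / 2.0
    cols = margin + (xy[:, 0] - xy[:, 0].min() + off_x) / span * usable
    rows = grid - 1 - margin - (xy[:, 1] - xy[:, 1].min() + off_y) / span * usable
    cols = np.rint(cols).astype(int)
    rows = np.rint(rows).astype(int)
    img[rows[0], cols[0]] = 1
    for k in range(len(xy) - 1):
        rr, cc = _draw_line(rows[k], cols[k], rows[k + 1], cols[k + 1])
        img[rr, cc] = 1
    return img


def save_pgm(image: np.ndarray, path) -> None:
    """Write a binary image as a plain-text portable graymap (P2)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ShapeError(f"image must be 2-D, got shape {image.shape}")
    h, w = image.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n255\n")
        for row in image:
            fh.write(" ".join(str(255 * int(v > 0)) for v in row) + "\n")


def nearest_template_classify(output, targets: Mapping) -> Classification:
    """Label of the target minimizing the per-example squared distance.

    Margin is the runner-up distance minus the best; exact ties resolve to
    the lowest label (sorted order) with ``tie=True``.
    """
    if not targets:
        raise DataError("empty target set")
    xy = _xy(output)
    labels = sorted(targets)
    dists = np.array([_example_error(xy, _xy(targets[lab])) for lab in labels])
    best = int(np.argmin(dists))
    label = labels[best]
    if len(labels) == 1:
        return Classification(label, float("inf"), False)
    others = np.delete(dists, best)
    runner = float(others.min())
    margin = runner - float(dists[best])
    tie = bool(np.isclose(margin, 0.0, atol=1e-12))
    return Classification(label, margin, tie)


def evaluate_model(
    weights: WeightSet,
    dataset,
    targets: Sequence[Mapping],
    params: ReservoirParams,
    config: TrainingConfig | None = None,
) -> dict:
    """Simulate a dataset and score every output pattern.

    Returns ``{"reports": [ErrorReport per pattern], "accuracy": fraction
    of instances whose every pattern classifies to the correct label
    component, "predictions": list of per-instance label tuples}``.
    """
    config = config or TrainingConfig()
    insts = _ordered(dataset)
    if not insts:
        raise DataError("empty evaluation set")
    cache = [_motor_rates(inst, weights, params, config) for inst in insts]
    reports = []
    correct = np.ones(len(insts), dtype=bool)
    predictions = [[] for _ in insts]
    for k in range(len(targets)):
        actual = [Trajectory2D((weights.W_out[k].T @ R).T) for R in cache]
        expected = [targets[k][inst.label[k]] for inst in insts]
        reports.append(trajectory_error(actual, expected))
        for i, (inst, a) in enumerate(zip(insts, actual)):
            cls = nearest_template_classify(a, targets[k])
            predictions[i].append(cls.label)
            correct[i] &= cls.label == inst.label[k]
    return {
        "reports": reports,
        "accuracy": float(correct.mean()),
        "predictions": [tuple(p) for p in predictions],
    }


def _instance_discriminant_ratio(
    weights: WeightSet, dataset, params: ReservoirParams, config: TrainingConfig
) -> tuple[float, float]:
    """(SP, DR) of the motor-phase instance dynamics under given weights."""
    insts = _ordered(dataset)
    items = [
        (inst.label, vectorize(_motor_rates(inst, weights, params, config)))
        for inst in insts
    ]
    summary = scatter_summary(LabeledDynamics.from_pairs(items))
    return summary.S_b_trace, summary.DR


def gamma_sweep(
    dataset,
    targets: Sequence[Mapping],
    params: ReservoirParams,
    base_config: TrainingConfig,
    gammas: Sequence[float],
    eval_dataset=None,
) -> SweepResult:
    """Retrain from scratch at each gamma (shared seed) and score the result.

    Records, per gamma: the attractor SP after step 1, the discriminant
    ratio DR of the trained instance dynamics, and the final word-drawing
    error d on ``eval_dataset`` (the training set if not given).  The
    maximum-DR gamma predicts the minimum-error gamma.
    """
    if len(gammas) < 2:
        raise DataError("gamma sweep needs at least 2 values")
    eval_dataset = eval_dataset if eval_dataset is not None else dataset
    sp_list, dr_list, d_list = [], [], []
    for g in gammas:
        config = replace(base_config, gamma=float(g))
        result = train_full(dataset, targets, params, config)
        _, dr = _instance_discriminant_ratio(
            result.weights, dataset, params, config
        )
        report = evaluate_model(
            result.weights, eval_dataset, targets, params, config
        )["reports"][0]
        sp_list.append(result.sp_history[-1])
        dr_list.append(dr)
        d_list.append(report.d)
    gammas = [float(g) for g in gammas]
    return SweepResult(
        gammas=gammas,
        sp=sp_list,
        dr=dr_list,
        d=d_list,
        argmin_d_gamma=gammas[int(np.argmin(d_list))],
        argmax_dr_gamma=gammas[int(np.argmax(dr_list))],
    )
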