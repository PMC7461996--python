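"""Three-step discrimination-based ESN training.

1. **Separation training** of the input weights: each class template is
   played into the reservoir while the input weights are pushed, via a
   sign-inverted FORCE-style rule, *away* from the frozen attractors of
   every other class.  The update at each step is
   ``W_in += gamma * outer(P @ x_in, 1/e_ij)`` where ``P`` is the running
   inverse correlation matrix of the input and ``1/e_ij`` the element-wise
   (clipped) inverse of the rate error against class j's attractor: small
   differences get large pushes, so subtle inter-class differences in the
   input are exaggerated in the attractors.

2. **Innate (approximation) training** of the recurrent weights with the
   standard FORCE / recursive-least-squares rule: jittered instances are
   played in and ``W_res -= outer(e, P @ r)`` pulls each instance's
   dynamics onto its class attractor.

3. **Readout training**: independent RLS fits of the linear readout blocks
   against target (x, y) drawing coordinates during the motor phase.

All three steps share the Sherman-Morrison running-inverse update
``P <- P - (P v)(P v)^T / (1 + v^T P v)`` with ``P(0) = I / alpha``
(``1/alpha`` is the learning rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    DataError,
    NumericalError,
    ShapeError,
)
from .reservoir import (
    ReservoirParams,
    WeightSet,
    _heun_step,
    eigen_spectrum,
    init_weights,
    readout,
    simulate,
)
from .separation import LabeledDynamics, pairwise_separation, scatter_summary, vectorize
from .signals import TemporalSignal
from .synthetic import Trajectory2D

__all__ = [
    "RLSState",
    "TrainingConfig",
    "ClassTemplates",
    "AttractorSet",
    "TrainResult",
    "rls_p_update",
    "compute_class_templates",
    "capture_attractors",
    "separation_train",
    "innate_train",
    "readout_train",
    "train_full",
    "attractor_separation",
]


@dataclass
class RLSState:
    """Running inverse-correlation matrix with regularizer alpha.

    ``P(0) = I / alpha``; ``delta_steps`` is the number of simulation steps
    between successive weight updates.
    """

    P: np.ndarray
    alpha: float
    delta_steps: int = 1

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ShapeError(f"P must be square, got {self.P.shape}")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if self.delta_steps < 1:
            raise ConfigurationError("delta_steps must be >= 1")

    @classmethod
    def init(cls, dim: int, alpha: float, delta_steps: int = 1) -> "RLSState":
        return cls(np.eye(dim) / alpha, alpha, delta_steps)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the three training steps.

    ``gamma`` scales the separation push; ``alpha_*`` are the inverse
    learning rates of the three RLS stages (separation 500, approximation
    100 by convention; the readout reuses the approximation order of
    magnitude).  ``inv_error_clip`` bounds each component of the
    element-wise inverse error so near-zero errors cannot produce infinite
    updates.
    """

    gamma: float = 0.02
    alpha_sep: float = 500.0
    alpha_approx: float = 100.0
    alpha_readout: float = 100.0
    epochs_separation: int = 10
    epochs_innate: int = 20
    epochs_readout: int = 10
    delta_steps: int = 1
    inv_error_clip: float = 1e3
    noise_amp: float = 0.0
    skip_separation: bool = False
    innate_window: str = "full"  # "full" (sensory+motor) or "motor"
    alignment: str = "rescale"  # "rescale" or "pad"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ConfigurationError("gamma must be >= 0")
        if min(self.alpha_sep, self.alpha_approx, self.alpha_readout) <= 0:
            raise ConfigurationError("inverse learning rates must be > 0")
        if self.inv_error_clip <= 0:
            raise ConfigurationError("inv_error_clip must be > 0")
        if self.delta_steps < 1:
            raise ConfigurationError("delta_steps must be >= 1")
        if self.innate_window not in ("full", "motor"):
            raise ConfigurationError(f"unknown innate_window {self.innate_window!r}")
        if self.alignment not in ("rescale", "pad"):
            raise ConfigurationError(f"unknown alignment {self.alignment!r}")


@dataclass
class ClassTemplates:
    """Per-class mean input pattern (channels x sensory steps)."""

    templates: dict  # label -> np.ndarray
    dt: float

    @property
    def labels(self) -> list:
        return sorted(self.templates)

    def signal(self, label) -> TemporalSignal:
        return TemporalSignal(self.templates[label], self.dt)


@dataclass
class AttractorSet:
    """Per-class innate rate trajectories (the training targets).

    Captured from zero initial state with zero noise, so the set is
    regenerable deterministically from the templates and weights.
    """

    attractors: dict  # label -> TemporalSignal (n_res x T, with boundary)

    @property
    def labels(self) -> list:
        return sorted(self.attractors)

    def __getitem__(self, label) -> TemporalSignal:
        return self.attractors[label]


@dataclass
class TrainResult:
    """Trained weights plus the per-step diagnostic histories."""

    weights: WeightSet
    sp_history: list
    distance_history: list
    errors: list  # final mean squared trajectory error per output pattern
    eig_before: np.ndarray
    eig_after: np.ndarray
    templates: ClassTemplates
    attractors: AttractorSet


def rls_p_update(P: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Sherman-Morrison rank-1 update of the running inverse correlation.

    ``P' = P - (P v)(P v)^T / (1 + v^T P v)``; symmetry is preserved by
    construction and ``v = 0`` leaves P unchanged.
    """
    P = np.asarray(P, dtype=float)
    v = np.asarray(v, dtype=float)
    if P.shape[0] != P.shape[1] or v.shape != (P.shape[0],):
        raise ShapeError(f"P {P.shape} and v {v.shape} do not conform")
    Pv = P @ v
    denom = 1.0 + float(v @ Pv)
    return P - np.outer(Pv, Pv) / denom


def _align_length(values: np.ndarray, n_T: int, mode: str) -> np.ndarray:
    """Align a channels x T pattern to length n_T by rescaling or padding."""
    C, T = values.shape
    if T == n_T:
        return values
    if mode == "pad":
        if T > n_T:
            return values[:, :n_T]
        return np.pad(values, ((0, 0), (0, n_T - T)))
    src = np.linspace(0.0, 1.0, T)
    dst = np.linspace(0.0, 1.0, n_T)
    return np.array([np.interp(dst, src, row) for row in values])


def _ordered(dataset) -> list:
    """Dataset instances in a fixed deterministic order."""
    insts = list(getattr(dataset, "instances", dataset))
    return sorted(
        insts, key=lambda inst: (inst.label, getattr(inst, "index", 0))
    )


def compute_class_templates(
    dataset,
    params: ReservoirParams,
    alignment: str = "rescale",
    classes: Sequence | None = None,
) -> ClassTemplates:
    """Element-wise mean input per class over length-aligned instances.

    Instances whose sensory length differs from ``params.sensory_steps``
    are aligned first (linear time rescaling by default, zero padding as
    the alternative).
    """
    groups: dict = {}
    for inst in _ordered(dataset):
        sig = inst.signal
        values = sig.sensory()
        groups.setdefault(inst.label, []).append(
            _align_length(values, params.sensory_steps, alignment)
        )
    if classes is not None:
        for lab in classes:
            if lab not in groups or not groups[lab]:
                raise DataError(f"class {lab!r} has no instances")
    if not groups:
        raise DataError("dataset is empty")
    templates = {
        lab: np.mean(stack, axis=0) for lab, stack in sorted(groups.items())
    }
    return ClassTemplates(templates, params.dt)


def capture_attractors(
    templates: ClassTemplates, weights: WeightSet, params: ReservoirParams
) -> AttractorSet:
    """Innate dynamics per class: simulate each template from x=0, no noise."""
    attractors = {}
    for lab in templates.labels:
        attractors[lab] = simulate(
            templates.signal(lab), weights, params, x0=None, noise_amp=0.0
        )
    return AttractorSet(attractors)


def attractor_separation(attractors: AttractorSet, window: str = "full") -> float:
    """SP = trace of S_b over the vectorized per-class attractors.

    By default the full trial (sensory + motor) enters — the quantity the
    separation step actually drives, since errors are taken against the
    full-length attractors; pass ``window="motor"`` to restrict to the
    drawing phase.  Equal class priors.
    """
    items = []
    for lab in attractors.labels:
        sig = attractors[lab]
        part = sig.motor() if window == "motor" else sig.values
        items.append((lab, vectorize(part)))
    data = LabeledDynamics.from_pairs(items)
    return scatter_summary(data).S_b_trace


def _clipped_inverse(e: np.ndarray, clip: float) -> np.ndarray:
    """Element-wise 1/e with each component's magnitude capped at ``clip``."""
    with np.errstate(divide="ignore"):
        inv = np.where(e != 0.0, 1.0 / np.where(e != 0.0, e, 1.0), clip)
    return np.clip(inv, -clip, clip)


def separation_train(
    weights: WeightSet,
    templates: ClassTemplates,
    params: ReservoirParams,
    config: TrainingConfig,
) -> tuple[WeightSet, list]:
    """Step 1: push class attractors apart by training the input weights.

    For each epoch, classes are visited in fixed (sorted) order.  The
    class template is played into the reservoir online (updates take effect
    immediately); at every ``delta_steps``-th sensory step the input weight
    matrix receives, for each other class j in fixed order, the update
    ``gamma * outer(P @ x_in, clip(1/e_ij))`` against that class's frozen
    attractor.  Attractors are re-captured once per epoch; the returned
    history holds SP = tr(S_b) of the attractors at epoch 0 and after each
    epoch.
    """
    labels = templates.labels
    if len(labels) < 2:
        raise DataError("separation training needs at least 2 classes")
    weights = weights.copy()
    attractors = capture_attractors(templates, weights, params)
    sp_history = [attractor_separation(attractors)]
    rls = RLSState.init(params.n_in, config.alpha_sep, config.delta_steps)
    P = rls.P
    noise_rng = (
        np.random.default_rng([config.seed, 101])
        if config.noise_amp > 0.0
        else None
    )
    T_s = params.sensory_steps
    for epoch in range(config.epochs_separation):
        for lab in labels:
            u_seq = templates.templates[lab]
            targets = {
                j: attractors[j].values for j in labels if j != lab
            }
            x = np.zeros(params.n_res)
            for t in range(T_s):
                u = u_seq[:, t]
                noise: np.ndarray | float = 0.0
                if noise_rng is not None:
                    noise = config.noise_amp * noise_rng.standard_normal(
                        params.n_res
                    )
                x = _heun_step(
                    x, u, weights.W_res, weights.W_in, params.leak,
                    params.tau, params.dt, noise,
                )
                if (t + 1) % config.delta_steps == 0:
                    r = np.tanh(x)
                    P = rls_p_update(P, u)
                    Pu = P @ u
                    for j in labels:
                        if j == lab:
                            continue
                        e = r - targets[j][:, t]
                        inv = _clipped_inverse(e, config.inv_error_clip)
                        weights.W_in += config.gamma * np.outer(Pu, inv)
        if not np.all(np.isfinite(weights.W_in)):
            raise NumericalError(
                f"non-finite input weights after separation epoch {epoch}"
            )
        attractors = capture_attractors(templates, weights, params)
        sp_history.append(attractor_separation(attractors))
    return weights, sp_history


def _mean_distance_to_attractors(
    weights: WeightSet,
    dataset,
    attractors: AttractorSet,
    params: ReservoirParams,
) -> float:
    dists = []
    for inst in _ordered(dataset):
        values = _align_length(
            inst.signal.sensory(), params.sensory_steps, "rescale"
        )
        rates = simulate(TemporalSignal(values, params.dt), weights, params)
        dists.append(
            pairwise_separation(rates.values, attractors[inst.label].values)
        )
    return float(np.mean(dists))


def innate_train(
    weights: WeightSet,
    attractors: AttractorSet,
    dataset,
    params: ReservoirParams,
    config: TrainingConfig,
) -> tuple[WeightSet, list]:
    """Step 2: FORCE the recurrent weights so instances track their attractor.

    Instances are played in a fixed order each epoch; at every
    ``delta_steps``-th step in the training window the error
    ``e = r - r_attractor`` drives ``W_res -= outer(e, P r / (1 + r P r))``
    with P updated by the Sherman-Morrison rule.  The returned history has
    the pre-training mean distance-to-attractor first, then the mean online
    distance for each epoch.
    """
    insts = _ordered(dataset)
    for inst in insts:
        if inst.label not in attractors.attractors:
            raise DataError(f"no attractor for class {inst.label!r}")
    weights = weights.copy()
    history = [
        _mean_distance_to_attractors(weights, dataset, attractors, params)
    ]
    P = RLSState.init(params.n_res, config.alpha_approx, config.delta_steps).P
    noise_rng = (
        np.random.default_rng([config.seed, 202])
        if config.noise_amp > 0.0
        else None
    )
    pb = params.sensory_steps
    T = params.total_steps
    for epoch in range(config.epochs_innate):
        epoch_dists = []
        for inst in insts:
            target = attractors[inst.label].values
            full = np.concatenate(
                [
                    _align_length(
                        inst.signal.sensory(), pb, config.alignment
                    ),
                    np.zeros((params.n_in, params.motor_steps)),
                ],
                axis=1,
            )
            x = np.zeros(params.n_res)
            dist = 0.0
            for t in range(T):
                noise: np.ndarray | float = 0.0
                if noise_rng is not None:
                    noise = config.noise_amp * noise_rng.standard_normal(
                        params.n_res
                    )
                x = _heun_step(
                    x, full[:, t], weights.W_res, weights.W_in, params.leak,
                    params.tau, params.dt, noise,
                )
                r = np.tanh(x)
                e = r - target[:, t]
                dist += float(np.linalg.norm(e))
                in_window = config.innate_window == "full" or t >= pb
                if in_window and (t + 1) % config.delta_steps == 0:
                    Pv = P @ r
                    denom = 1.0 + float(r @ Pv)
                    P = P - np.outer(Pv, Pv) / denom
                    weights.W_res -= np.outer(e, Pv / denom)
            epoch_dists.append(dist / T)
        if not np.all(np.isfinite(weights.W_res)):
            raise NumericalError(
                f"non-finite reservoir weights after innate epoch {epoch}"
            )
        history.append(float(np.mean(epoch_dists)))
    return weights, history


def _motor_rates(
    inst, weights: WeightSet, params: ReservoirParams, config: TrainingConfig
) -> np.ndarray:
    sig = inst.signal
    values = _align_length(sig.sensory(), params.sensory_steps, config.alignment)
    rates = simulate(TemporalSignal(values, params.dt), weights, params)
    return rates.values[:, rates.phase_boundary :]


def readout_train(
    weights: WeightSet,
    dataset,
    targets: Sequence[Mapping],
    params: ReservoirParams,
    config: TrainingConfig,
) -> WeightSet:
    """Step 3: RLS fit of each readout block during the motor phase.

    ``targets`` is one mapping per output pattern (e.g. word shapes, then
    attribute marks); the k-th component of an instance label selects its
    target in the k-th mapping.  Each block keeps its own P and updates
    independently from the shared reservoir rates.  Targets must be
    resampled to exactly ``params.motor_steps`` points.
    """
    insts = _ordered(dataset)
    weights = weights.copy()
    n_patterns = len(targets)
    if len(weights.W_out) < n_patterns:
        weights.W_out = [
            np.zeros((params.n_res, params.n_out)) for _ in range(n_patterns)
        ]
    for mapping in targets:
        for lab, traj in mapping.items():
            xy = traj.xy if isinstance(traj, Trajectory2D) else np.asarray(traj)
            if xy.shape != (params.motor_steps, params.n_out):
                raise DataError(
                    f"target for {lab!r} has {xy.shape[0]} points, expected "
                    f"{params.motor_steps}"
                )
    # reservoir weights are frozen in this step, so rates can be cached
    cache = [
        _motor_rates(inst, weights, params, config) for inst in insts
    ]
    Ps = [
        RLSState.init(params.n_res, config.alpha_readout, config.delta_steps).P
        for _ in range(n_patterns)
    ]
    for _epoch in range(config.epochs_readout):
        for inst, R in zip(insts, cache):
            tgt = []
            for k in range(n_patterns):
                traj = targets[k][inst.label[k]]
                tgt.append(
                    traj.xy if isinstance(traj, Trajectory2D) else np.asarray(traj)
                )
            for t in range(params.motor_steps):
                if (t + 1) % config.delta_steps != 0:
                    continue
                r = R[:, t]
                for k in range(n_patterns):
                    Pv = Ps[k] @ r
                    denom = 1.0 + float(r @ Pv)
                    Ps[k] = Ps[k] - np.outer(Pv, Pv) / denom
                    e = weights.W_out[k].T @ r - tgt[k][t]
                    weights.W_out[k] -= np.outer(Pv / denom, e)
    return weights


def train_full(
    dataset,
    targets: Sequence[Mapping],
    params: ReservoirParams,
    config: TrainingConfig,
) -> TrainResult:
    """Run separation -> innate -> readout training and collect diagnostics.

    Returns the trained weights together with the SP history (step 1), the
    distance-to-attractor history (step 2), the final mean squared
    trajectory error per output pattern on the training set, and the
    eigen-spectra of the recurrent matrix before and after training.
    """
    from .evaluation import trajectory_error  # local import to avoid a cycle

    labels = sorted({inst.label for inst in _ordered(dataset)})
    if len(labels) < 2:
        raise DataError("training needs at least 2 classes")
    weights = init_weights(params, rng_seed=config.seed, n_patterns=len(targets))
    eig_before = eigen_spectrum(weights.W_res)
    templates = compute_class_templates(dataset, params, config.alignment)
    if config.skip_separation:
        attractors = capture_attractors(templates, weights, params)
        sp_history = [attractor_separation(attractors)]
    else:
        weights, sp_history = separation_train(weights, templates, params, config)
        attractors = capture_attractors(templates, weights, params)
    weights, distance_history = innate_train(
        weights, attractors, dataset, params, config
    )
    attractors = capture_attractors(templates, weights, params)
    weights = readout_train(weights, dataset, targets, params, config)
    insts = _ordered(dataset)
    cache = [_motor_rates(inst, weights, params, config) for inst in insts]
    errors = []
    for k in range(len(targets)):
        actual = [Trajectory2D((weights.W_out[k].T @ R).T) for R in cache]
        expected = [targets[k][inst.label[k]] for inst in insts]
        errors.append(trajectory_error(actual, expected).d)
    eig_after = eigen_spectrum(weights.W_res)
    return TrainResult(
        weights=weights,
        sp_history=sp_history,
        distance_history=distance_history,
        errors=errors,
        eig_before=eig_before,
        eig_after=eig_after,
        templates=templates,
        attractors=attractors,
    )
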