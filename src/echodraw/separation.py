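"""Separation and approximation metrics for reservoir dynamics.

Quantifies how well a reservoir keeps different input classes apart
(separation) and same-class instances together (approximation):

* pairwise separation — time-averaged Euclidean distance between two state
  trajectories;
* linear separation rank — rank of the matrix of reservoir states sampled
  at one time point, one column per input (kernel quality);
* scatter traces — trace of the between-class scatter matrix S_b (the
  separation property SP) and of the within-class scatter S_w, plus their
  ratio, the discriminant ratio DR = tr(S_b)/tr(S_w), which predicts the
  accuracy-optimal amount of separation;
* the D metric (R_S - R_G)/R_S combining separation and generalization
  ranks.

Trajectories are compared after flattening each ``n_res x T`` rate matrix
into a single vector (neuron-major), so a "data point" for the scatter
statistics is the concatenated temporal activity of every neuron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import DataError, ShapeError, UndefinedMetricError

__all__ = [
    "LabeledDynamics",
    "ScatterSummary",
    "RankReport",
    "pairwise_separation",
    "linear_separation_rank",
    "scatter_summary",
    "kernel_quality_D",
    "rank_report",
    "vectorize",
    "pca_project",
]


@dataclass
class LabeledDynamics:
    """Flattened dynamics vectors with class labels and class priors.

    ``vectors`` has one row per item; ``priors`` defaults to the empirical
    class frequencies and must sum to 1.
    """

    labels: list
    vectors: np.ndarray
    priors: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self.labels) != self.vectors.shape[0]:
            raise ShapeError(
                f"{len(self.labels)} labels for {self.vectors.shape[0]} vectors"
            )
        if not self.labels:
            raise DataError("LabeledDynamics needs at least one item")
        counts: dict = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        if self.priors is None:
            n = len(self.labels)
            self.priors = {lab: c / n for lab, c in counts.items()}
        else:
            if set(self.priors) != set(counts):
                raise DataError("priors must cover exactly the observed classes")
            total = sum(self.priors.values())
            if abs(total - 1.0) > 1e-12:
                raise DataError(f"priors sum to {total}, expected 1")

    @property
    def classes(self) -> list:
        return sorted(set(self.labels))

    @property
    def L(self) -> int:
        return len(self.classes)

    @classmethod
    def from_pairs(cls, items: Sequence[tuple], priors: dict | None = None):
        """Build from ``(label, vector)`` pairs."""
        labels = [lab for lab, _ in items]
        vectors = np.array([np.ravel(v) for _, v in items], dtype=float)
        return cls(labels, vectors, priors)


@dataclass(frozen=True)
class ScatterSummary:
    """Traces of the between/within-class scatter matrices and their ratio."""

    S_b_trace: float
    S_w_trace: float
    DR: float


@dataclass(frozen=True)
class RankReport:
    """Separation rank R_S, generalization rank R_G and D = (R_S-R_G)/R_S."""

    R_S: int
    R_G: int
    D: float


def pairwise_separation(traj_u: np.ndarray, traj_v: np.ndarray) -> float:
    """Mean over sample points of ``||x_u(t_n) - x_v(t_n)||`` (Euclidean).

    Both trajectories must be ``n_res x N_samples`` arrays of equal shape.
    """
    traj_u = np.asarray(traj_u, dtype=float)
    traj_v = np.asarray(traj_v, dtype=float)
    if traj_u.shape != traj_v.shape:
        raise ShapeError(
            f"trajectory shapes differ: {traj_u.shape} vs {traj_v.shape}"
        )
    return float(np.mean(np.linalg.norm(traj_u - traj_v, axis=0)))


def linear_separation_rank(states: np.ndarray, tol: float | None = None) -> int:
    """Numerical rank of the state matrix (count of s.v. > tol * largest).

    ``states`` is the ``N x m`` matrix whose columns are reservoir states at
    a common sample time, one column per input.  The default tolerance is
    ``max(N, m) * machine_eps`` (relative to the largest singular value).
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.size == 0:
        raise ShapeError("states must be a nonempty 2-D matrix")
    s = np.linalg.svd(states, compute_uv=False)
    if s[0] == 0.0:
        return 0
    if tol is None:
        tol = max(states.shape) * np.finfo(float).eps
    return int(np.sum(s > tol * s[0]))


def scatter_summary(data: LabeledDynamics, eps: float = 1e-12) -> ScatterSummary:
    """Traces of S_b and S_w and the discriminant ratio, without forming DxD.

    ``tr(S_b) = sum_i P(w_i) ||mu_i - mu_g||^2`` with mu_g the prior-weighted
    global mean; ``tr(S_w) = sum_i P(w_i) tr(Sigma_i)`` with Sigma_i the
    unbiased sample covariance of class i (classes with a single member
    contribute zero).  ``DR = tr(S_b) / max(tr(S_w), eps)``.
    """
    classes = data.classes
    if len(classes) < 2:
        warnings.warn("scatter_summary with a single class: S_b trace is 0")
    mus = {}
    sw = 0.0
    for lab in classes:
        mask = np.array([l == lab for l in data.labels])
        block = data.vectors[mask]
        mus[lab] = block.mean(axis=0)
        if block.shape[0] > 1:
            # trace of the sample covariance = sum of per-dimension variances
            sw += data.priors[lab] * float(np.sum(np.var(block, axis=0, ddof=1)))
    mu_g = np.sum(
        [data.priors[lab] * mus[lab] for lab in classes], axis=0
    )
    sb = float(
        sum(
            data.priors[lab] * np.sum((mus[lab] - mu_g) ** 2)
            for lab in classes
        )
    )
    dr = sb / max(sw, eps)
    return ScatterSummary(S_b_trace=sb, S_w_trace=sw, DR=dr)


def kernel_quality_D(R_S: int, R_G: int) -> float:
    """The combined kernel-quality metric ``D = (R_S - R_G) / R_S``."""
    if R_S < 1:
        raise UndefinedMetricError("D is undefined for R_S = 0")
    return (R_S - R_G) / R_S


def rank_report(
    states_distinct: np.ndarray,
    states_jittered: np.ndarray,
    tol: float | None = None,
) -> RankReport:
    """Separation/generalization ranks and D from two state matrices.

    ``states_distinct`` holds reservoir states at a common sample time for
    distinct inputs (one column each); ``states_jittered`` the states for
    jittered versions of the inputs.  High R_S and low R_G mean the
    reservoir separates classes while generalizing within them.
    """
    R_S = linear_separation_rank(states_distinct, tol)
    R_G = linear_separation_rank(states_jittered, tol)
    return RankReport(R_S=R_S, R_G=R_G, D=kernel_quality_D(R_S, R_G))


def vectorize(rates: np.ndarray) -> np.ndarray:
    """Flatten an ``n_res x T`` rate trajectory neuron-major.

    The result has length ``n_res * T`` with each neuron's full time series
    contiguous (row-major ravel); ``reshape(n_res, T)`` inverts it exactly.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ShapeError("cannot vectorize an empty trajectory")
    return rates.ravel(order="C")


def pca_project(data: LabeledDynamics, n_components: int = 2) -> np.ndarray:
    """Project items onto the top principal components (default 2-D).

    Centered projection, deterministic up to axis sign; the sign of each
    component is fixed so that its largest-magnitude loading is positive.
    Returns an ``(n_items, n_components)`` coordinate array.
    """
    if data.vectors.shape[0] < n_components:
        raise DataError(
            f"need at least {n_components} items, got {data.vectors.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(data.vectors)
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1.0
    return coords
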