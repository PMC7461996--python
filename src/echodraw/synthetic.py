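"""Synthetic class-structured temporal patterns and 2-D motor targets.

Stands in for cochleagram speech data: each class has a smooth
multi-channel base pattern (per-channel sums of random-phase, band-limited
sinusoids under a bell-shaped channel envelope, so patterns are slow
relative to the integration step and channels carry a spectral profile).
Classes are factored as ``word x attribute`` mirroring a word-by-gender
design: the word component selects the base waveform, the attribute group
applies a spectral tilt plus a small additive component, so a network can
be asked to report both factors simultaneously.

Instances add within-class variability: a scalar amplitude jitter, a
smooth monotone time warp with fixed endpoints (utterance-duration
variability), and additive white noise.  ``class_similarity`` blends every
word base toward a shared pattern, producing "hard" datasets whose classes
differ only subtly.

Motor targets are single-stroke 2-D shapes in the unit square, resampled
to points equally spaced in arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, InvalidParameterError, ShapeError
from .signals import TemporalSignal

__all__ = [
    "Jitter",
    "SynthSpec",
    "Instance",
    "Dataset",
    "Trajectory2D",
    "generate_dataset",
    "downsample_time",
    "make_target_trajectory",
    "resample_uniform",
]


@dataclass(frozen=True)
class Jitter:
    """Within-class variability: amplitude scale SD, warp SD, noise SD."""

    amplitude_sd: float = 0.1
    warp_sd: float = 0.05
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.amplitude_sd, self.warp_sd, self.noise_sd) < 0:
            raise InvalidParameterError("jitter SDs must be >= 0")


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration.

    ``n_words * n_attributes`` classes of ``n_channels x duration_steps``
    patterns at time step ``dt`` ms.  Defaults mirror the reference task
    shape: 39 channels and a 300-step sensory pattern.
    """

    n_words: int = 10
    n_attributes: int = 2
    n_channels: int = 39
    duration_steps: int = 300
    instances_per_class: int = 8
    dt: float = 1.0
    jitter: Jitter = field(default_factory=Jitter)
    class_similarity: float = 0.0
    attribute_tilt: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_words,
            self.n_attributes,
            self.n_channels,
            self.duration_steps,
            self.instances_per_class,
        ) < 1:
            raise InvalidParameterError("all counts must be >= 1")
        if not 0.0 <= self.class_similarity < 1.0:
            raise InvalidParameterError("class_similarity must be in [0, 1)")

    @property
    def n_classes(self) -> int:
        return self.n_words * self.n_attributes


@dataclass
class Instance:
    """One labeled input: ``label = (word, attribute)`` and its signal."""

    label: tuple
    signal: TemporalSignal
    index: int = 0


@dataclass
class Dataset:
    """Generated instances plus the ground-truth class base patterns."""

    instances: list
    bases: dict
    spec: SynthSpec

    def by_class(self) -> dict:
        out: dict = {}
        for inst in self.instances:
            out.setdefault(inst.label, []).append(inst)
        return out

    @property
    def labels(self) -> list:
        return sorted({inst.label for inst in self.instances})

    def split(self, n_train: int) -> tuple["Dataset", "Dataset"]:
        """Per-class split into the first ``n_train`` and remaining instances."""
        train, test = [], []
        for label, insts in sorted(self.by_class().items()):
            insts = sorted(insts, key=lambda i: i.index)
            if not 0 < n_train < len(insts):
                raise DataError(
                    f"cannot take {n_train} training instances from class "
                    f"{label} with {len(insts)} instances"
                )
            train.extend(insts[:n_train])
            test.extend(insts[n_train:])
        return (
            Dataset(train, self.bases, self.spec),
            Dataset(test, self.bases, self.spec),
        )


@dataclass
class Trajectory2D:
    """Ordered (x, y) motor coordinates, equally spaced in arc length."""

    xy: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ShapeError(f"trajectory must be (N, 2), got {self.xy.shape}")

    @property
    def n_points(self) -> int:
        return self.xy.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]


_K_SINUSOIDS = 3


def _smooth_pattern(rng: np.random.Generator, spec: SynthSpec) -> np.ndarray:
    """A smooth multi-channel pattern: banded sinusoids x channel envelope."""
    T = spec.duration_steps
    C = spec.n_channels
    t = np.linspace(0.0, 1.0, T)
    pattern = np.zeros((C, T))
    for c in range(C):
        freqs = rng.uniform(0.5, 3.0, _K_SINUSOIDS)  # cycles per pattern
        phases = rng.uniform(0.0, 2.0 * np.pi, _K_SINUSOIDS)
        amps = rng.uniform(0.3, 1.0, _K_SINUSOIDS) / _K_SINUSOIDS
        pattern[c] = np.sum(
            amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None]),
            axis=0,
        )
    center = rng.uniform(0.2, 0.8) * (C - 1)
    width = rng.uniform(0.25, 0.5) * C
    envelope = np.exp(-(((np.arange(C) - center) / width) ** 2))
    pattern *= envelope[:, None]
    peak = np.max(np.abs(pattern))
    if peak > 0:
        pattern *= 0.8 / peak
    return pattern


def _class_base(spec: SynthSpec, word: int, attr: int) -> np.ndarray:
    common = _smooth_pattern(np.random.default_rng([spec.seed, 7919]), spec)
    word_pat = _smooth_pattern(np.random.default_rng([spec.seed, 1 + word]), spec)
    attr_pat = _smooth_pattern(
        np.random.default_rng([spec.seed, 5000 + attr]), spec
    )
    s = spec.class_similarity
    base = np.sqrt(s) * common + np.sqrt(1.0 - s) * word_pat
    # attribute group: spectral tilt (multiplicative, survives any amount of
    # word-base blending) plus a small additive signature
    C = spec.n_channels
    ramp = (np.arange(C) / max(C - 1, 1)) - 0.5
    sign = 1.0 if attr % 2 == 0 else -1.0
    base = base * (1.0 + sign * spec.attribute_tilt * ramp)[:, None]
    base = base + 0.15 * attr_pat
    return base


def _smooth_warp(rng: np.random.Generator, T: int, warp_sd: float) -> np.ndarray:
    """Monotone smooth time map on [0, 1] with fixed endpoints."""
    t = np.linspace(0.0, 1.0, T)
    if warp_sd == 0.0:
        return t
    phi = t.copy()
    for k in range(1, 4):
        c = warp_sd * rng.standard_normal() / (k * np.pi)
        phi = phi + c * np.sin(k * np.pi * t)
    # enforce monotonicity and fixed endpoints even for extreme draws
    phi = np.maximum.accumulate(phi)
    phi = (phi - phi[0]) / max(phi[-1] - phi[0], 1e-12)
    return phi


def generate_dataset(spec: SynthSpec) -> Dataset:
    """Generate the labeled instances and ground-truth class bases.

    Deterministic per seed: every class and instance draws from its own RNG
    substream, so datasets are reproducible and distinct classes use
    distinct streams.
    """
    bases: dict = {}
    instances: list = []
    t_grid = np.linspace(0.0, 1.0, spec.duration_steps)
    for word in range(spec.n_words):
        for attr in range(spec.n_attributes):
            label = (word, attr)
            base = _class_base(spec, word, attr)
            bases[label] = base
            for idx in range(spec.instances_per_class):
                rng = np.random.default_rng([spec.seed, word, attr, idx])
                amp = 1.0 + spec.jitter.amplitude_sd * rng.standard_normal()
                phi = _smooth_warp(rng, spec.duration_steps, spec.jitter.warp_sd)
                values = np.empty_like(base)
                for c in range(spec.n_channels):
                    values[c] = np.interp(phi, t_grid, base[c])
                values *= amp
                if spec.jitter.noise_sd > 0.0:
                    values = values + spec.jitter.noise_sd * rng.standard_normal(
                        values.shape
                    )
                instances.append(
                    Instance(label, TemporalSignal(values, spec.dt), idx)
                )
    return Dataset(instances, bases, spec)


def downsample_time(signal: TemporalSignal, factor: int = 4) -> TemporalSignal:
    """Non-overlapping block means along time; ``dt`` is multiplied by factor.

    A trailing remainder shorter than ``factor`` is dropped.
    """
    if factor < 1:
        raise InvalidParameterError(f"factor must be >= 1, got {factor}")
    if factor > signal.n_steps:
        raise DataError(
            f"factor {factor} exceeds signal length {signal.n_steps}"
        )
    if factor == 1:
        return signal.copy()
    n_blocks = signal.n_steps // factor
    trimmed = signal.values[:, : n_blocks * factor]
    values = trimmed.reshape(signal.n_channels, n_blocks, factor).mean(axis=2)
    pb = None
    if signal.phase_boundary is not None:
        pb = signal.phase_boundary // factor
    return TemporalSignal(values, signal.dt * factor, pb)


def resample_uniform(
    points: np.ndarray, n_points: int, closed: bool | None = None
) -> np.ndarray:
    """Resample a polyline to points equally spaced in arc length.

    Closed curves (first point equals last) are resampled with ``n_points``
    over the full loop excluding the duplicate endpoint; open curves include
    both endpoints with spacing ``L / (n_points - 1)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ShapeError("polyline must be an (N>=2, 2) array")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise DataError("degenerate zero-length path")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if closed is None:
        closed = bool(np.allclose(pts[0], pts[-1]))
    if closed:
        s = np.linspace(0.0, total, n_points, endpoint=False)
    else:
        s = np.linspace(0.0, total, n_points)
    out = np.column_stack(
        [np.interp(s, cum, pts[:, 0]), np.interp(s, cum, pts[:, 1])]
    )
    return out


_DENSE = 2048


def _shape_polyline(shape: str) -> np.ndarray:
    t = np.linspace(0.0, 1.0, _DENSE)
    if shape == "circle":
        ang = 2.0 * np.pi * t
        return np.column_stack(
            [0.5 + 0.4 * np.cos(ang), 0.5 + 0.4 * np.sin(ang)]
        )
    if shape == "eight":
        ang = 2.0 * np.pi * t
        return np.column_stack(
            [0.5 + 0.38 * np.sin(ang), 0.5 + 0.38 * np.sin(ang) * np.cos(ang)]
        )
    if shape == "ell":
        return np.array([[0.25, 0.9], [0.25, 0.1], [0.8, 0.1]])
    if shape == "zigzag":
        return np.array(
            [[0.1, 0.8], [0.35, 0.2], [0.6, 0.8], [0.85, 0.2]]
        )
    raise DataError(f"unknown shape id {shape!r}")


def make_target_trajectory(shape, n_points: int) -> Trajectory2D:
    """Build a single-stroke 2-D target, uniformly resampled in arc length.

    ``shape`` is a built-in id (``circle``, ``eight``, ``ell``, ``zigzag``)
    or an ``(N, 2)`` polyline drawn without lifting the hand.
    """
    if isinstance(shape, str):
        poly = _shape_polyline(shape)
    else:
        poly = np.asarray(shape, dtype=float)
    return Trajectory2D(resample_uniform(poly, n_points))
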