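"""Standard desk-scale benchmark fixtures shared by tests, scripts and docs.

The standard fixture is a 4-class task (2 words x 2 attribute groups) of
39-channel smooth patterns over a 300 ms sensory phase, driving a 100-neuron
reservoir that draws one of two word shapes (circle, figure-eight) plus an
attribute mark (L-path, zigzag) over a 300 ms motor phase at dt = 1 ms.
The "hard" variant blends 85% of a shared pattern into every word base, so
classes differ only subtly and the separation step has real work to do.
"""

from __future__ import annotations

from .reservoir import ReservoirParams
from .synthetic import (
    Jitter,
    SynthSpec,
    generate_dataset,
    make_target_trajectory,
)
from .training import TrainingConfig

__all__ = ["standard_spec", "standard_targets", "standard_fixture", "GAMMA_GRID"]

WORD_SHAPES = ["circle", "eight"]
ATTRIBUTE_SHAPES = ["ell", "zigzag"]

# separation-scaling grid of the standard sweep experiment (tiny .. huge)
GAMMA_GRID = [0.001, 0.005, 0.02, 0.1, 0.5]


def standard_spec(seed: int = 0, hard: bool = False, n_instances: int = 9) -> SynthSpec:
    """The 4-class generator configuration of the standard fixture."""
    return SynthSpec(
        n_words=2,
        n_attributes=2,
        n_channels=39,
        duration_steps=300,
        instances_per_class=n_instances,
        jitter=Jitter(amplitude_sd=0.1, warp_sd=0.05, noise_sd=0.02),
        class_similarity=0.85 if hard else 0.0,
        seed=seed,
    )


def standard_targets(motor_steps: int = 300) -> list:
    """Word and attribute target shapes resampled to the motor step count."""
    word = {
        k: make_target_trajectory(shape, motor_steps)
        for k, shape in enumerate(WORD_SHAPES)
    }
    attr = {
        k: make_target_trajectory(shape, motor_steps)
        for k, shape in enumerate(ATTRIBUTE_SHAPES)
    }
    return [word, attr]


def standard_fixture(
    seed: int = 0, hard: bool = False, n_train: int = 6, n_test: int = 3
):
    """(train, test, targets, params, config) for the standard benchmark."""
    spec = standard_spec(seed=seed, hard=hard, n_instances=n_train + n_test)
    train, test = generate_dataset(spec).split(n_train)
    params = ReservoirParams(
        n_res=100,
        n_in=spec.n_channels,
        n_out=2,
        tau=40.0,
        leak=0.8,
        dt=1.0,
        spectral_radius=1.5,
        sensory_ms=300.0,
        motor_ms=300.0,
        seed=seed,
    )
    targets = standard_targets(params.motor_steps)
    config = TrainingConfig(
        gamma=0.02,
        epochs_separation=10,
        epochs_innate=10,
        epochs_readout=5,
        seed=seed,
    )
    return train, test, targets, params, config
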