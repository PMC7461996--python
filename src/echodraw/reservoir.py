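"""Leaky-integrate rate-neuron reservoir: dynamics, weights, simulation.

The network is an echo state network (ESN): a pool of ``n_res`` fully
connected analog neurons whose state ``x(t)`` obeys

    tau * dx/dt = -alpha_l * x + W_res @ r + W_in.T @ u + noise,
    r = tanh(x),

integrated with Heun's predictor-corrector method at a fixed step ``dt``.
``W_in`` (input -> reservoir) and ``W_res`` (recurrent) are drawn from a
standard normal distribution; ``W_res`` is rescaled so its spectral radius
hits a configured target (default 1.5, the edge-of-chaos regime that keeps
an "echo" of the input ringing through the motor phase after the input is
detached).  Linear readouts ``y = W_out.T @ r`` draw the motor output.

There are no output-to-reservoir feedback connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidParameterError, ShapeError
from .signals import TemporalSignal

__all__ = [
    "ReservoirParams",
    "WeightSet",
    "NetworkState",
    "init_weights",
    "rescale_spectral_radius",
    "step",
    "simulate",
    "readout",
    "eigen_spectrum",
]


def _check_positive_multiple(name: str, value: float, dt: float) -> int:
    steps = value / dt
    rounded = round(steps)
    if rounded < 1 or abs(steps - rounded) > 1e-9:
        raise InvalidParameterError(
            f"{name}={value} ms must be a positive multiple of dt={dt} ms"
        )
    return int(rounded)


@dataclass(frozen=True)
class ReservoirParams:
    """All network hyper-parameters.

    Units: ``tau``, ``dt`` and the phase durations are in milliseconds;
    ``leak`` (the leak coefficient alpha_l) and ``spectral_radius`` are
    dimensionless.  Defaults follow the reference configuration: 39 input
    channels, 2 output coordinates per drawing, tau = 40 ms, leak = 0.8,
    dt = 1 ms, spectral radius 1.5, and 300 ms sensory + 300 ms motor
    phases.
    """

    n_res: int = 2000
    n_in: int = 39
    n_out: int = 2
    tau: float = 40.0
    leak: float = 0.8
    dt: float = 1.0
    spectral_radius: float = 1.5
    sensory_ms: float = 300.0
    motor_ms: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res < 1 or self.n_in < 1 or self.n_out < 1:
            raise InvalidParameterError("network dimensions must be >= 1")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if self.tau <= 0:
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")
        if not 0 < self.leak <= 1:
            raise InvalidParameterError(f"leak must be in (0, 1], got {self.leak}")
        if self.spectral_radius <= 0:
            raise InvalidParameterError("spectral_radius must be > 0")
        _check_positive_multiple("sensory_ms", self.sensory_ms, self.dt)
        _check_positive_multiple("motor_ms", self.motor_ms, self.dt)

    @property
    def sensory_steps(self) -> int:
        return _check_positive_multiple("sensory_ms", self.sensory_ms, self.dt)

    @property
    def motor_steps(self) -> int:
        return _check_positive_multiple("motor_ms", self.motor_ms, self.dt)

    @property
    def total_steps(self) -> int:
        return self.sensory_steps + self.motor_steps


@dataclass
class WeightSet:
    """The trainable connection matrices.

    ``W_in`` has shape ``(n_in, n_res)`` and enters the dynamics as
    ``W_in.T @ u``; ``W_res`` has shape ``(n_res, n_res)`` (row =
    postsynaptic neuron); ``W_out`` is a list of ``(n_res, n_out)``
    matrices, one per output pattern (e.g. word drawing and speaker
    attribute drawing), each used as ``y = W_out.T @ r``.
    """

    W_in: np.ndarray
    W_res: np.ndarray
    W_out: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.W_res = np.asarray(self.W_res, dtype=float)
        if self.W_res.ndim != 2 or self.W_res.shape[0] != self.W_res.shape[1]:
            raise ShapeError(f"W_res must be square, got {self.W_res.shape}")
        if self.W_in.ndim != 2 or self.W_in.shape[1] != self.W_res.shape[0]:
            raise ShapeError(
                f"W_in shape {self.W_in.shape} inconsistent with W_res "
                f"{self.W_res.shape}"
            )
        self.W_out = [np.asarray(w, dtype=float) for w in self.W_out]
        for w in self.W_out:
            if w.shape[0] != self.W_res.shape[0]:
                raise ShapeError(
                    f"W_out shape {w.shape} inconsistent with n_res "
                    f"{self.W_res.shape[0]}"
                )

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.W_in.copy(), self.W_res.copy(), [w.copy() for w in self.W_out]
        )


@dataclass
class NetworkState:
    """Instantaneous reservoir state ``x`` and firing rate ``r = tanh(x)``."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)

    @property
    def r(self) -> np.ndarray:
        return np.tanh(self.x)


def rescale_spectral_radius(W: np.ndarray, target: float) -> np.ndarray:
    """Rescale a square matrix so its spectral radius equals ``target``.

    Idempotent: rescaling an already-rescaled matrix is a multiplication by
    a factor within one ulp of 1.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ShapeError(f"expected a square matrix, got shape {W.shape}")
    radius = float(np.max(np.abs(np.linalg.eigvals(W))))
    if radius == 0.0:
        raise InvalidParameterError("matrix has zero spectral radius; cannot rescale")
    return W * (target / radius)


def init_weights(
    params: ReservoirParams, rng_seed: int | None = None, n_patterns: int = 2
) -> WeightSet:
    """Draw standard-normal ``W_in``/``W_res``, scale ``W_res``, zero ``W_out``.

    The same seed yields bit-identical weights.  ``n_patterns`` readout
    blocks of shape ``(n_res, n_out)`` are initialized to zero.
    """
    seed = params.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    W_in = rng.standard_normal((params.n_in, params.n_res))
    W_res = rng.standard_normal((params.n_res, params.n_res))
    if params.n_res == 1:
        W_res = np.array([[np.sign(W_res[0, 0]) * params.spectral_radius]])
        if W_res[0, 0] == 0.0:
            W_res[0, 0] = params.spectral_radius
    else:
        W_res = rescale_spectral_radius(W_res, params.spectral_radius)
    W_out = [np.zeros((params.n_res, params.n_out)) for _ in range(n_patterns)]
    return WeightSet(W_in, W_res, W_out)


def _heun_step(
    x: np.ndarray,
    u: np.ndarray,
    W_res: np.ndarray,
    W_in: np.ndarray,
    leak: float,
    tau: float,
    dt: float,
    noise: np.ndarray | float = 0.0,
) -> np.ndarray:
    """One Heun (predictor-corrector) step on the raw state vector.

    The input ``u`` and the noise current are held constant over the step.
    """
    drive = u @ W_in + noise
    k1 = (-leak * x + W_res @ np.tanh(x) + drive) / tau
    x_pred = x + dt * k1
    k2 = (-leak * x_pred + W_res @ np.tanh(x_pred) + drive) / tau
    return x + 0.5 * dt * (k1 + k2)


def step(
    state: NetworkState,
    u_t: np.ndarray,
    weights: WeightSet,
    params: ReservoirParams,
    noise_amp: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance the reservoir by one time step.

    The noise term is an i.i.d. Gaussian current with standard deviation
    ``noise_amp``, drawn once per step and held constant across the
    predictor and corrector evaluations; ``noise_amp = 0`` is fully
    deterministic.
    """
    u_t = np.asarray(u_t, dtype=float)
    if u_t.shape != (params.n_in,):
        raise ShapeError(f"input has shape {u_t.shape}, expected ({params.n_in},)")
    if state.x.shape != (params.n_res,):
        raise ShapeError(
            f"state has shape {state.x.shape}, expected ({params.n_res},)"
        )
    noise: np.ndarray | float = 0.0
    if noise_amp > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        noise = noise_amp * rng.standard_normal(params.n_res)
    x_new = _heun_step(
        state.x, u_t, weights.W_res, weights.W_in, params.leak, params.tau,
        params.dt, noise,
    )
    return NetworkState(x_new)


def _full_input(input_signal: TemporalSignal, params: ReservoirParams):
    """Sensory input extended with a zero motor phase; returns (array, pb).

    During the motor phase the input is detached, so any values beyond the
    phase boundary are forced to zero.
    """
    if abs(input_signal.dt - params.dt) > 1e-12:
        raise ConfigurationError(
            f"input dt={input_signal.dt} does not match params dt={params.dt}"
        )
    if input_signal.n_channels != params.n_in:
        raise ShapeError(
            f"input has {input_signal.n_channels} channels, expected {params.n_in}"
        )
    if input_signal.phase_boundary is None:
        pb = input_signal.n_steps
        full = np.concatenate(
            [input_signal.values, np.zeros((params.n_in, params.motor_steps))],
            axis=1,
        )
    else:
        pb = input_signal.phase_boundary
        full = input_signal.values.copy()
        full[:, pb:] = 0.0
    return full, pb


def simulate(
    input_signal: TemporalSignal,
    weights: WeightSet,
    params: ReservoirParams,
    x0: np.ndarray | None = None,
    noise_amp: float = 0.0,
    rng_seed: int | None = None,
) -> TemporalSignal:
    """Run the reservoir over the sensory + motor horizon; return rates.

    The returned signal has shape ``(n_res, T)`` with the phase boundary of
    the run.  With ``x0 = 0`` and ``noise_amp = 0`` the result is
    deterministic (the "innate dynamics" of the input).
    """
    full, pb = _full_input(input_signal, params)
    T = full.shape[1]
    x = np.zeros(params.n_res) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (params.n_res,):
        raise ShapeError(f"x0 has shape {x.shape}, expected ({params.n_res},)")
    rng = np.random.default_rng(rng_seed) if noise_amp > 0.0 else None
    rates = np.empty((params.n_res, T))
    for t in range(T):
        noise: np.ndarray | float = 0.0
        if rng is not None:
            noise = noise_amp * rng.standard_normal(params.n_res)
        x = _heun_step(
            x, full[:, t], weights.W_res, weights.W_in, params.leak, params.tau,
            params.dt, noise,
        )
        rates[:, t] = np.tanh(x)
    return TemporalSignal(rates, params.dt, pb)


def readout(rates: TemporalSignal | np.ndarray, W_out: np.ndarray) -> TemporalSignal:
    """Linear readout ``y(t) = W_out.T @ r(t)`` applied at every step."""
    if isinstance(rates, TemporalSignal):
        R, dt, pb = rates.values, rates.dt, rates.phase_boundary
    else:
        R, dt, pb = np.asarray(rates, dtype=float), 1.0, None
    W_out = np.asarray(W_out, dtype=float)
    if W_out.shape[0] != R.shape[0]:
        raise ShapeError(
            f"W_out shape {W_out.shape} incompatible with rates {R.shape}"
        )
    return TemporalSignal(W_out.T @ R, dt, pb)


def eigen_spectrum(W: np.ndarray) -> np.ndarray:
    """All eigenvalues of a square weight matrix (for stability diagnostics).

    Training compresses the spectrum of ``W_res`` relative to the uniform
    disc of the random initialization; comparing pre/post spectra is the
    standard stability check.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ShapeError(f"expected a square matrix, got shape {W.shape}")
    return np.linalg.eigvals(W)
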