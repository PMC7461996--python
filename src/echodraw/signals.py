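"""Multi-channel temporal signals and their plain-text serialization.

A :class:`TemporalSignal` is the common currency of the package: a real
``channels x timesteps`` matrix sampled at a fixed time step ``dt`` (in
milliseconds).  Input signals carry the sensory drive (one row per input
channel); simulated reservoir activity uses one row per neuron; readout
output uses one row per output coordinate.  The optional ``phase_boundary``
marks the first time step of the motor phase, i.e. the step at which the
input is detached and the readout starts drawing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, ShapeError

__all__ = [
    "TemporalSignal",
    "save_signal",
    "load_signal",
    "save_signal_npz",
    "load_signal_npz",
]


@dataclass
class TemporalSignal:
    """A real-valued channels-by-time signal with time step in ms.

    Parameters
    ----------
    values
        Array of shape ``(n_channels, n_steps)``.
    dt
        Sampling interval in milliseconds.
    phase_boundary
        Index of the first motor-phase step, or ``None`` for a pure
        (sensory-only) input signal.  Must lie in ``[0, n_steps]``.
    """

    values: np.ndarray
    dt: float
    phase_boundary: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"signal values must be 2-D, got {self.values.ndim}-D")
        if self.values.shape[1] < 1:
            raise ShapeError("signal must contain at least one time step")
        if self.dt <= 0:
            raise DataError(f"dt must be positive, got {self.dt}")
        if self.phase_boundary is not None:
            pb = int(self.phase_boundary)
            if not 0 <= pb <= self.n_steps:
                raise DataError(
                    f"phase_boundary {pb} outside [0, {self.n_steps}]"
                )
            self.phase_boundary = pb

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt

    def sensory(self) -> np.ndarray:
        """The sensory-phase portion (everything before ``phase_boundary``)."""
        if self.phase_boundary is None:
            return self.values
        return self.values[:, : self.phase_boundary]

    def motor(self) -> np.ndarray:
        """The motor-phase portion (from ``phase_boundary`` on)."""
        if self.phase_boundary is None:
            raise DataError("signal has no phase boundary")
        return self.values[:, self.phase_boundary :]

    def copy(self) -> "TemporalSignal":
        return TemporalSignal(self.values.copy(), self.dt, self.phase_boundary)


def save_signal(signal: TemporalSignal, path) -> None:
    """Write a signal as delimited text; round-trips bit-exactly.

    Format: one header line ``# dt=<dt> phase_boundary=<int|none>`` followed
    by one tab-separated row per channel, with values printed at full
    (17 significant digit) precision.
    """
    pb = "none" if signal.phase_boundary is None else str(signal.phase_boundary)
    with open(path, "w") as fh:
        fh.write(f"# dt={signal.dt!r} phase_boundary={pb}\n")
        for row in signal.values:
            fh.write("\t".join(f"{v:.17g}" for v in row))
            fh.write("\n")


def save_signal_npz(signal: TemporalSignal, path) -> None:
    """Write a signal to an array container (.npz); round-trips bit-exactly."""
    pb = -1 if signal.phase_boundary is None else signal.phase_boundary
    np.savez(path, values=signal.values, dt=signal.dt, phase_boundary=pb)


def load_signal_npz(path) -> TemporalSignal:
    """Read a signal written by :func:`save_signal_npz`."""
    with np.load(path, allow_pickle=False) as z:
        pb = int(z["phase_boundary"])
        return TemporalSignal(
            z["values"], float(z["dt"]), None if pb < 0 else pb
        )


def load_signal(path) -> TemporalSignal:
    """Read a signal written by :func:`save_signal`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise DataError(f"{path}: missing signal header line")
        fields = dict(tok.split("=", 1) for tok in header[1:].split())
        dt = float(fields["dt"])
        pb_tok = fields.get("phase_boundary", "none")
        pb = None if pb_tok == "none" else int(pb_tok)
        rows = [
            [float(v) for v in line.split("\t")]
            for line in fh
            if line.strip()
        ]
    return TemporalSignal(np.array(rows, dtype=float), dt, pb)
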