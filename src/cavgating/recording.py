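"""In-memory containers for multi-sweep voltage-clamp recordings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import segment_sample_counts
from .protocols import VoltageProtocol

__all__ = ["Sweep", "Recording", "command_waveform"]


def command_waveform(segments, dt: float) -> np.ndarray:
    """Sampled command voltage (mV) for a piecewise-constant segment list."""
    counts = segment_sample_counts(segments, dt)
    parts = [np.full(n, v, dtype=float) for n, (_d, v) in zip(counts, segments)]
    return np.concatenate(parts)


@dataclass
class Sweep:
    """One sweep: command segments (nominal mV) plus the sampled current (pA).

    ``test_window``/``control_window`` give (start, end) times in ms of the
    analysis pulses; ``subsweeps`` holds the four P/4 leak-correction traces
    when the protocol recorded them online.
    """

    segments: list  # [(duration_ms, nominal_mV), ...]
    current: np.ndarray
    kind: str  # 'iv' | 'ssi' | 'inact' | 'leak_ref'
    test_voltage: float | None = None
    test_window: tuple[float, float] | None = None
    control_window: tuple[float, float] | None = None
    conditioning_voltage: float | None = None
    subsweeps: list = field(default_factory=list)  # list of np.ndarray
    sub_segments: list = field(default_factory=list)  # matching segment lists

    def waveform(self, dt: float) -> np.ndarray:
        return command_waveform(self.segments, dt)


@dataclass
class Recording:
    """A set of sweeps from one cell under one protocol.

    All sweeps of the main family share ``dt`` and a common length; a
    separate hyperpolarising reference sweep (``leak_ref``) is attached when
    offline leak subtraction was requested.  Voltages stored here are
    nominal; ``ljp`` records the junction correction to apply downstream.
    """

    sweeps: list
    dt: float
    c_m: float
    protocol: VoltageProtocol
    cell_id: str
    construct: str
    seed: int
    ljp: float = -9.3
    leak_ref: Sweep | None = None

    def __post_init__(self) -> None:
        lengths = {len(s.current) for s in self.sweeps}
        if len(lengths) > 1:
            raise ValueError("all sweeps of a recording must share one length")

    def copy_with_currents(self, currents, leak_ref_current=None) -> "Recording":
        sweeps = [replace(s, current=c) for s, c in zip(self.sweeps, currents)]
        ref = self.leak_ref
        if ref is not None and leak_ref_current is not None:
            ref = replace(ref, current=leak_ref_current)
        return replace(self, sweeps=sweeps, leak_ref=ref)
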