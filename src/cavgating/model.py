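"""Deterministic conductance model of a Cav1.3-like calcium current.

The channel is described by a Boltzmann activation gate ``m`` and a
bi-exponential inactivation gate ``h`` with a non-inactivating plateau.
Channel current uses an ohmic driving force,

    I_chan(t) = g_max * m(t) * h(t) * (V(t) - v_rev)   [pA = nS * mV]

which is the same linear-driving-force form used to fit the peak I-V
relationship downstream, so the simulator and the estimators are
self-consistent by construction.  Units throughout: mV, ms, nS, pA, pF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ActivationParams",
    "InactivationParams",
    "PassiveParams",
    "ChannelParams",
    "steady_state_activation",
    "steady_state_availability",
    "simulate_sweep",
]


def _require_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ActivationParams:
    """Voltage-dependent activation: Boltzmann steady state + single-exponential kinetics.

    v_half : half-maximal activation voltage (mV)
    slope  : Boltzmann slope factor k (mV, > 0); smaller = steeper
    g_max  : maximal conductance (nS, > 0)
    v_rev  : reversal potential of the ohmic driving force (mV)
    tau_act: activation time constant (ms, > 0)
    """

    v_half: float
    slope: float
    g_max: float
    v_rev: float
    tau_act: float = 0.5

    def __post_init__(self) -> None:
        _require_finite("ActivationParams", [self.v_half, self.slope, self.g_max, self.v_rev, self.tau_act])
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if self.g_max <= 0:
            raise ValueError(f"g_max must be > 0, got {self.g_max}")
        if self.tau_act <= 0:
            raise ValueError(f"tau_act must be > 0, got {self.tau_act}")


@dataclass(frozen=True)
class InactivationParams:
    """Voltage-dependent inactivation with a non-inactivating plateau.

    Steady-state availability follows the modified Boltzmann
    ``h_inf(V) = (1 - plateau)/(1 + exp((V - v_half)/slope)) + plateau``;
    the gate relaxes toward it as a weighted sum of two exponentials
    (``frac_fast`` with ``tau_fast``, the rest with ``tau_slow``).
    ``plateau`` is the fraction of current that never inactivates
    (reported downstream as "non-inactivating %").
    """

    v_half: float
    slope: float
    plateau: float
    tau_fast: float = 80.0
    tau_slow: float = 1000.0
    frac_fast: float = 0.55

    def __post_init__(self) -> None:
        _require_finite(
            "InactivationParams",
            [self.v_half, self.slope, self.plateau, self.tau_fast, self.tau_slow, self.frac_fast],
        )
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not 0.0 <= self.plateau <= 1.0:
            raise ValueError(f"plateau must lie in [0, 1], got {self.plateau}")
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("inactivation time constants must be > 0")
        if self.tau_fast > self.tau_slow:
            raise ValueError("tau_fast must not exceed tau_slow")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError(f"frac_fast must lie in [0, 1], got {self.frac_fast}")


@dataclass(frozen=True)
class PassiveParams:
    """Linear membrane properties of the recorded cell.

    g_leak  : ohmic leak conductance (nS, >= 0)
    e_leak  : leak reversal potential (mV)
    c_m     : membrane capacitance (pF, > 0); used for pA/pF normalisation
    tau_cap : decay time constant of the capacitive transient at step edges (ms)
    noise_sd: SD of additive white Gaussian current noise (pA, >= 0)
    """

    g_leak: float = 1.0
    e_leak: float = 0.0
    c_m: float = 20.0
    tau_cap: float = 0.2
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        _require_finite("PassiveParams", [self.g_leak, self.e_leak, self.c_m, self.tau_cap, self.noise_sd])
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")
        if self.tau_cap <= 0:
            raise ValueError("tau_cap must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ChannelParams:
    """Full parameter set of one virtual cell (gating + passive membrane)."""

    act: ActivationParams
    inact: InactivationParams
    passive: PassiveParams

    def with_passive(self, **kwargs) -> "ChannelParams":
        return replace(self, passive=replace(self.passive, **kwargs))


def steady_state_activation(v, act: ActivationParams):
    """Normalised steady-state activation m_inf(V) = 1/(1 + exp(-(V - v_half)/k)).

    Strictly increasing in V; equals 0.5 exactly at ``act.v_half``.
    """
    v = np.asarray(v, dtype=float)
    _require_finite("v", v)
    out = 1.0 / (1.0 + np.exp(-(v - act.v_half) / act.slope))
    return float(out) if out.ndim == 0 else out


def steady_state_availability(v, inact: InactivationParams):
    """Steady-state availability h_inf(V) = (1 - p)/(1 + exp((V - v_half)/k)) + p.

    Decreases from 1 (hyperpolarised) to the non-inactivating plateau ``p``.
    """
    v = np.asarray(v, dtype=float)
    _require_finite("v", v)
    p = inact.plateau
    out = (1.0 - p) / (1.0 + np.exp((v - inact.v_half) / inact.slope)) + p
    return float(out) if out.ndim == 0 else out


def segment_sample_counts(segments, dt: float) -> list[int]:
    """Number of samples per piecewise-constant segment (sample k sits at t = k*dt)."""
    counts = []
    for dur, _v in segments:
        if dt >= dur:
            raise ValueError(f"dt = {dt} ms must be shorter than every segment (got {dur} ms)")
        counts.append(int(round(dur / dt)))
    return counts


def simulate_sweep(segments, params: ChannelParams, dt: float, rng=None) -> np.ndarray:
    """Simulate one sweep of membrane current for a piecewise-constant voltage command.

    Parameters
    ----------
    segments : sequence of (duration_ms, voltage_mV)
        The command waveform, expressed as the actual membrane potential
        (i.e. already corrected for any junction potential).
    params : ChannelParams
    dt : sampling interval (ms); must be shorter than every segment
    rng : None, int seed, or numpy Generator
        Source of the Gaussian current noise.  The same seed yields a
        bit-identical trace.  Ignored when ``noise_sd == 0``.

    Returns
    -------
    np.ndarray of current in pA, one sample per ``dt`` starting at t = 0.

    Notes
    -----
    Within each segment the gates relax exponentially toward their
    steady-state targets, so the trace is evaluated in closed form (no ODE
    integration error).  A capacitive transient
    ``c_m * dV / tau_cap * exp(-(t - t_edge)/tau_cap)`` is added at every
    voltage step edge, plus the ohmic leak ``g_leak * (V - e_leak)``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    segments = [(float(d), float(v)) for d, v in segments]
    for _d, v in segments:
        _require_finite("segment voltage", v)
    counts = segment_sample_counts(segments, dt)
    n_total = int(np.sum(counts))
    out = np.empty(n_total, dtype=float)

    act, inact, passive = params.act, params.inact, params.passive
    m = steady_state_activation(segments[0][1], act)
    h_target0 = steady_state_availability(segments[0][1], inact)
    hf = hs = h_target0

    pos = 0
    edges = []  # (sample_index, dV)
    prev_v = segments[0][1]
    for (dur, v), n_seg in zip(segments, counts):
        if pos > 0 and v != prev_v:
            edges.append((pos, v - prev_v))
        t_loc = np.arange(n_seg) * dt
        m_inf = steady_state_activation(v, act)
        h_inf = steady_state_availability(v, inact)
        m_t = m_inf + (m - m_inf) * np.exp(-t_loc / act.tau_act)
        hf_t = h_inf + (hf - h_inf) * np.exp(-t_loc / inact.tau_fast)
        hs_t = h_inf + (hs - h_inf) * np.exp(-t_loc / inact.tau_slow)
        h_t = inact.frac_fast * hf_t + (1.0 - inact.frac_fast) * hs_t
        out[pos : pos + n_seg] = act.g_max * m_t * h_t * (v - act.v_rev) + passive.g_leak * (
            v - passive.e_leak
        )
        # exact state at the segment end feeds the next segment
        m = m_inf + (m - m_inf) * np.exp(-dur / act.tau_act)
        hf = h_inf + (hf - h_inf) * np.exp(-dur / inact.tau_fast)
        hs = h_inf + (hs - h_inf) * np.exp(-dur / inact.tau_slow)
        prev_v = v
        pos += n_seg

    t = np.arange(n_total) * dt
    for idx, dv in edges:
        amp = passive.c_m * dv / passive.tau_cap
        out[idx:] += amp * np.exp(-(t[idx:] - t[idx]) / passive.tau_cap)

    if passive.noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        out += gen.normal(0.0, passive.noise_sd, n_total)
    return out
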