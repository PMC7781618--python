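"""Synthetic cohorts of virtual cells.

Builds populations of cells around a mean parameter set with between-cell
variability, runs the voltage protocols through the conductance model and
emits :class:`~cavgating.recording.Recording` sets — the stand-in for raw
patch-clamp data.  Everything is reproducible from ``(seed, cell_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import preprocess, protocols as proto
from .model import ChannelParams, simulate_sweep, steady_state_activation
from .protocols import VoltageProtocol
from .recording import Recording, Sweep

__all__ = [
    "CellVariability",
    "CohortSpec",
    "draw_cell_params",
    "simulate_cell",
    "simulate_cohort",
    "analytic_v_max",
]

C_M_MEAN_PF = 20.0  # typical HEK-cell capacitance
C_M_MIN_PF = 5.0
MIN_SLOPE_MV = 0.5


@dataclass(frozen=True)
class CellVariability:
    """Between-cell SDs; additive normal for voltages/slopes, multiplicative
    log-normal sigma for g_max and the inactivation time constants."""

    v_half_act_sd: float = 0.0
    slope_act_sd: float = 0.0
    v_rev_sd: float = 0.0
    v_half_inact_sd: float = 0.0
    slope_inact_sd: float = 0.0
    plateau_sd: float = 0.0
    g_max_sigma: float = 0.0
    tau_sigma: float = 0.0
    frac_fast_sd: float = 0.0
    c_m_sd: float = 4.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """One construct's cohort: label, size, mean parameters and variability.

    ``qc_outlier_fraction`` pushes that fraction of cells outside the
    100-1000 pA QC window (by scaling g_max), to exercise the exclusion
    logic; it is 0 by default.
    """

    construct: str
    n_cells: int
    mean_params: ChannelParams
    variability: CellVariability = field(default_factory=CellVariability)
    seed: int = 0
    qc_outlier_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0.0 <= self.qc_outlier_fraction <= 1.0:
            raise ValueError("qc_outlier_fraction must lie in [0, 1]")


def _cell_rng(seed: int, cell_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(cell_index), int(stream)]))


def draw_cell_params(spec: CohortSpec, cell_index: int) -> ChannelParams:
    """Draw one cell's parameters; deterministic in (spec.seed, cell_index).

    Voltage-type parameters are normal around the mean; g_max and the
    inactivation time constants are log-normal with mean-preserving offset
    (-sigma^2/2); slopes are truncated at 0.5 mV, fractions clipped to
    [0, 1]; c_m is normal(mean, c_m_sd) truncated above 5 pF.
    """
    if not 0 <= cell_index < spec.n_cells:
        raise ValueError(f"cell_index {cell_index} outside cohort of {spec.n_cells}")
    rng = _cell_rng(spec.seed, cell_index)
    m, var = spec.mean_params, spec.variability

    v_half_a = rng.normal(m.act.v_half, var.v_half_act_sd)
    slope_a = max(MIN_SLOPE_MV, rng.normal(m.act.slope, var.slope_act_sd))
    v_rev = rng.normal(m.act.v_rev, var.v_rev_sd)
    g_factor = (
        np.exp(rng.normal(-0.5 * var.g_max_sigma**2, var.g_max_sigma)) if var.g_max_sigma > 0 else 1.0
    )
    v_half_i = rng.normal(m.inact.v_half, var.v_half_inact_sd)
    slope_i = max(MIN_SLOPE_MV, rng.normal(m.inact.slope, var.slope_inact_sd))
    plateau = float(np.clip(rng.normal(m.inact.plateau, var.plateau_sd), 0.0, 1.0))
    tau_factor = (
        np.exp(rng.normal(-0.5 * var.tau_sigma**2, var.tau_sigma)) if var.tau_sigma > 0 else 1.0
    )
    frac_fast = float(np.clip(rng.normal(m.inact.frac_fast, var.frac_fast_sd), 0.0, 1.0))
    c_m = max(C_M_MIN_PF, rng.normal(m.passive.c_m, var.c_m_sd))

    g_max = m.act.g_max * g_factor
    if spec.qc_outlier_fraction > 0 and rng.uniform() < spec.qc_outlier_fraction:
        g_max *= 0.1 if rng.uniform() < 0.5 else 4.0

    return ChannelParams(
        act=replace(m.act, v_half=v_half_a, slope=slope_a, v_rev=v_rev, g_max=g_max),
        inact=replace(
            m.inact,
            v_half=v_half_i,
            slope=slope_i,
            plateau=plateau,
            tau_fast=m.inact.tau_fast * tau_factor,
            tau_slow=m.inact.tau_slow * tau_factor,
            frac_fast=frac_fast,
        ),
        passive=replace(m.passive, c_m=c_m),
    )


def analytic_v_max(params: ChannelParams, protocol: VoltageProtocol, ljp: float = proto.LJP_DEFAULT) -> float:
    """Nominal step voltage maximising |m_inf(V) (V - v_rev)| on the protocol grid."""
    v_nom = np.array(protocol.step_voltages())
    v_act = v_nom + ljp
    drive = steady_state_activation(v_act, params.act) * (v_act - params.act.v_rev)
    return float(v_nom[int(np.argmax(np.abs(drive)))])


def _shifted(segments, ljp):
    return [(d, v + ljp) for d, v in segments]


def _iv_sweep(v_step: float, protocol: VoltageProtocol) -> Sweep:
    hp = protocol.holding_potential
    segs = [(proto.IV_PRE_MS, hp), (protocol.step_duration, v_step), (proto.IV_POST_MS, hp)]
    return Sweep(
        segments=segs,
        current=np.empty(0),
        kind="iv",
        test_voltage=v_step,
        test_window=(proto.IV_PRE_MS, proto.IV_PRE_MS + protocol.step_duration),
    )


def _p4_segments(main: Sweep, hp: float) -> list:
    """Four inverted quarter-amplitude subsweeps (standard -P/4 from HP)."""
    subs = []
    for _ in range(4):
        segs = [(d, hp - (v - hp) / 4.0) for d, v in main.segments]
        subs.append(segs)
    return subs


def _ssi_sweep(v_cond: float, v_max: float, protocol: VoltageProtocol) -> Sweep:
    hp = protocol.holding_potential
    pulse = protocol.step_duration
    segs = [
        (proto.IV_PRE_MS, hp),
        (pulse, v_max),
        (proto.SSI_GAP_MS, hp),
        (protocol.conditioning_duration, v_cond),
        (pulse, v_max),
        (proto.IV_POST_MS, hp),
    ]
    t_ctrl = proto.IV_PRE_MS
    t_test = proto.IV_PRE_MS + pulse + proto.SSI_GAP_MS + protocol.conditioning_duration
    return Sweep(
        segments=segs,
        current=np.empty(0),
        kind="ssi",
        test_voltage=v_max,
        control_window=(t_ctrl, t_ctrl + pulse),
        test_window=(t_test, t_test + pulse),
        conditioning_voltage=v_cond,
    )


def _inact_sweep(v_max: float, protocol: VoltageProtocol) -> Sweep:
    hp = protocol.holding_potential
    segs = [(proto.INACT_PRE_MS, hp), (protocol.step_duration, v_max), (proto.INACT_POST_MS, hp)]
    return Sweep(
        segments=segs,
        current=np.empty(0),
        kind="inact",
        test_voltage=v_max,
        test_window=(proto.INACT_PRE_MS, proto.INACT_PRE_MS + protocol.step_duration),
    )


def _leak_ref_sweep() -> Sweep:
    segs = [
        (proto.LEAK_REF_PRE_MS, proto.LEAK_REF_FROM_MV),
        (proto.LEAK_REF_STEP_MS, proto.LEAK_REF_TO_MV),
        (proto.LEAK_REF_POST_MS, proto.LEAK_REF_FROM_MV),
    ]
    return Sweep(segments=segs, current=np.empty(0), kind="leak_ref")


def simulate_recording(
    params: ChannelParams,
    protocol: VoltageProtocol,
    *,
    dt: float = 0.05,
    ljp: float = proto.LJP_DEFAULT,
    rng=None,
    v_max: float | None = None,
    leak_mode: str = "offline",
    cell_id: str = "",
    construct: str = "",
    seed: int = 0,
) -> Recording:
    """Simulate one cell under one protocol.

    ``v_max`` (nominal mV) must be supplied for SSI/INACT5S protocols.
    ``leak_mode`` 'offline' attaches the hyperpolarising reference sweep,
    'p4' records four inverted quarter-amplitude subsweeps per main sweep,
    'none' records neither.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if protocol.kind == "IV":
        sweeps = [_iv_sweep(v, protocol) for v in protocol.step_voltages()]
    elif protocol.kind == "SSI":
        if v_max is None:
            raise ValueError("SSI protocol requires v_max")
        sweeps = [_ssi_sweep(vc, v_max, protocol) for vc in protocol.step_voltages()]
    elif protocol.kind == "INACT5S":
        if v_max is None:
            raise ValueError("INACT5S protocol requires v_max")
        sweeps = [_inact_sweep(v_max, protocol)]
    else:  # pragma: no cover - guarded by VoltageProtocol
        raise ValueError(protocol.kind)

    for sw in sweeps:
        sw.current = simulate_sweep(_shifted(sw.segments, ljp), params, dt, gen)
        if leak_mode == "p4":
            sw.sub_segments = _p4_segments(sw, protocol.holding_potential)
            sw.subsweeps = [
                simulate_sweep(_shifted(segs, ljp), params, dt, gen) for segs in sw.sub_segments
            ]
    leak_ref = None
    if leak_mode == "offline":
        leak_ref = _leak_ref_sweep()
        leak_ref.current = simulate_sweep(_shifted(leak_ref.segments, ljp), params, dt, gen)

    return Recording(
        sweeps=sweeps,
        dt=dt,
        c_m=params.passive.c_m,
        protocol=protocol,
        cell_id=cell_id,
        construct=construct,
        seed=seed,
        ljp=ljp,
        leak_ref=leak_ref,
    )


def simulate_cell(
    spec: CohortSpec,
    cell_index: int,
    protocol_list,
    *,
    dt: float = 0.05,
    ljp: float = proto.LJP_DEFAULT,
    leak_mode: str = "offline",
) -> list:
    """All recordings for one cell; V_max for SSI/INACT5S is located from the
    cell's own simulated I-V family (falling back to the analytic optimum if
    no IV protocol is in the list)."""
    params = draw_cell_params(spec, cell_index)
    cell_id = f"{spec.construct}/c{cell_index:03d}"
    by_kind = {p.kind: p for p in protocol_list}
    recs = []
    v_max_nominal = None
    order = sorted(protocol_list, key=lambda p: 0 if p.kind == "IV" else 1)
    for k, protocol in enumerate(order):
        stream = 1 + list(protocol_list).index(protocol)
        gen = _cell_rng(spec.seed, cell_index, stream)
        if protocol.kind != "IV" and v_max_nominal is None:
            if "IV" in by_kind:
                # locate V_max from this cell's own IV recording
                iv_rec = next(r for r in recs if r.protocol.kind == "IV")
                pt = preprocess.extract_peaks(preprocess.leak_subtract(iv_rec, "auto"))
                v_max_nominal = pt.v_max - ljp
            else:
                v_max_nominal = analytic_v_max(params, proto.default_protocols()[0], ljp)
        rec = simulate_recording(
            params,
            protocol,
            dt=dt,
            ljp=ljp,
            rng=gen,
            v_max=v_max_nominal,
            leak_mode=leak_mode,
            cell_id=cell_id,
            construct=spec.construct,
            seed=spec.seed,
        )
        recs.append(rec)
    return recs


def simulate_cohort(
    spec: CohortSpec,
    protocol_list,
    *,
    dt: float = 0.05,
    ljp: float = proto.LJP_DEFAULT,
    leak_mode: str = "offline",
) -> list:
    """One Recording per (cell, protocol), fully determined by the spec."""
    out = []
    for i in range(spec.n_cells):
        out.extend(simulate_cell(spec, i, protocol_list, dt=dt, ljp=ljp, leak_mode=leak_mode))
    return out
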