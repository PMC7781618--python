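"""Trace conditioning: junction-potential correction, leak subtraction,
peak extraction, capacitance normalisation and QC exclusion.

Sign convention: inward Ca2+ currents are negative.  "Peak" means the
sample of largest magnitude inside the search window (the most-negative
sample on the inward limb, the most-positive one beyond the reversal
potential), earliest sample on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .recording import Recording, Sweep, command_waveform

__all__ = [
    "correct_ljp",
    "leak_subtract_offline",
    "leak_subtract_p4",
    "extract_peaks",
    "qc_filter",
    "PeakTable",
    "QC_MIN_PA",
    "QC_MAX_PA",
]

QC_MIN_PA = 100.0
QC_MAX_PA = 1000.0
SETTLE_MS_DEFAULT = 2.5
SMOOTH_MS_DEFAULT = 0.2


def correct_ljp(nominal_v, ljp: float = -9.3):
    """Liquid-junction-potential correction: corrected = nominal + ljp (mV)."""
    v = np.asarray(nominal_v, dtype=float)
    if not (np.all(np.isfinite(v)) and np.isfinite(ljp)):
        raise ValueError("voltages and ljp must be finite")
    out = v + ljp
    return float(out) if out.ndim == 0 else out


def _baseline_window(segments, dt: float) -> tuple[int, int]:
    """Sample range inside the initial holding segment used as baseline."""
    pre = segments[0][0]
    lo = int(round(min(1.0, 0.2 * pre) / dt))
    hi = int(round((pre - 0.5) / dt)) if pre > 1.5 else int(round(0.9 * pre / dt))
    if hi <= lo:
        lo, hi = 0, max(1, int(round(pre / dt)) - 1)
    return lo, hi


def _baseline(trace: np.ndarray, segments, dt: float) -> float:
    lo, hi = _baseline_window(segments, dt)
    return float(np.mean(trace[lo:hi]))


def estimate_leak_conductance(ref: Sweep, dt: float) -> float:
    """Leak conductance (nS) from the 50-ms hyperpolarising reference step.

    The channel is closed at both levels of the -80 to -90 mV step, so the
    steady current difference across the step is purely ohmic:
    g_leak = dI / dV.
    """
    pre, step = ref.segments[0], ref.segments[1]
    dv = step[1] - pre[1]
    if dv == 0:
        raise ValueError("reference step has zero amplitude")
    i_base = _baseline(ref.current, ref.segments, dt)
    # steady window: skip 5 ms of capacitive settling, stop short of the edge
    t0 = pre[0] + 5.0
    t1 = pre[0] + step[0] - 0.5
    i_step = float(np.mean(ref.current[int(round(t0 / dt)) : int(round(t1 / dt))]))
    return (i_step - i_base) / dv


def leak_subtract_offline(rec: Recording) -> Recording:
    """Offline leak subtraction using the hyperpolarising reference sweep.

    Estimates g_leak from the reference step, then removes the per-sweep
    holding baseline plus ``g_leak * (V(t) - V_hold)`` from every sweep.
    Exact for a linear leak; capacitive step transients are *not* removed
    (the peak-search window skips them).
    """
    if rec.leak_ref is None:
        raise ValueError("recording has no leak reference sweep; cannot leak-subtract offline")
    g_leak = estimate_leak_conductance(rec.leak_ref, rec.dt)
    new_currents = []
    for sw in rec.sweeps:
        wave = sw.waveform(rec.dt)
        dv = wave - sw.segments[0][1]
        base = _baseline(sw.current, sw.segments, rec.dt)
        new_currents.append(sw.current - base - g_leak * dv)
    ref = rec.leak_ref
    ref_wave = ref.waveform(rec.dt)
    ref_corr = ref.current - _baseline(ref.current, ref.segments, rec.dt) - g_leak * (
        ref_wave - ref.segments[0][1]
    )
    return rec.copy_with_currents(new_currents, leak_ref_current=ref_corr)


def leak_subtract_p4(
    main_current: np.ndarray,
    subsweeps,
    *,
    main_segments,
    sub_segments,
    dt: float,
) -> np.ndarray:
    """P/4 leak subtraction: main sweep minus the summed scaled subsweeps.

    The four quarter-amplitude subsweeps may be of either polarity; the
    scale factor (+/-1 for exact quarter steps) is inferred from the stored
    command waveforms, so linear leak *and* capacitive transients cancel
    exactly.  Each trace is referenced to its own holding baseline first.
    """
    if len(subsweeps) != 4:
        raise ValueError(f"P/4 subtraction requires exactly 4 subsweeps, got {len(subsweeps)}")
    main_wave = command_waveform(main_segments, dt)
    dv_main = main_wave - main_segments[0][1]
    dv_sub_sum = np.zeros_like(dv_main)
    for segs in sub_segments:
        dv_sub_sum += command_waveform(segs, dt) - segs[0][1]
    k = int(np.argmax(np.abs(dv_main)))
    if dv_main[k] == 0:  # sweep never leaves the holding level: nothing to correct
        return main_current - _baseline(main_current, main_segments, dt)
    if dv_sub_sum[k] == 0:
        raise ValueError("subsweep commands carry no excursion; cannot scale")
    scale = dv_main[k] / dv_sub_sum[k]
    out = main_current - _baseline(main_current, main_segments, dt)
    for sub, segs in zip(subsweeps, sub_segments):
        out = out - scale * (sub - _baseline(sub, segs, dt))
    return out


def leak_subtract(rec: Recording, method: str = "auto") -> Recording:
    """Apply leak subtraction to a whole recording.

    method: 'offline' (reference-step scaling), 'p4' (online subsweeps),
    'auto' (offline if a reference sweep exists, else p4 if subsweeps
    exist, else baseline-only) or 'none'.
    """
    if method == "auto":
        if rec.leak_ref is not None:
            method = "offline"
        elif rec.sweeps and rec.sweeps[0].subsweeps:
            method = "p4"
        else:
            method = "none"
    if method == "offline":
        return leak_subtract_offline(rec)
    if method == "p4":
        currents = [
            leak_subtract_p4(
                sw.current,
                sw.subsweeps,
                main_segments=sw.segments,
                sub_segments=sw.sub_segments,
                dt=rec.dt,
            )
            for sw in rec.sweeps
        ]
        return rec.copy_with_currents(currents)
    if method == "none":
        currents = [sw.current - _baseline(sw.current, sw.segments, rec.dt) for sw in rec.sweeps]
        return rec.copy_with_currents(currents)
    raise ValueError(f"unknown leak subtraction method {method!r}")


def smoothed(trace: np.ndarray, dt: float, smooth_ms: float = SMOOTH_MS_DEFAULT) -> np.ndarray:
    """+/- smooth_ms moving average used for peak *measurement* only."""
    half = int(round(smooth_ms / dt))
    if half < 1:
        return trace
    return uniform_filter1d(trace, size=2 * half + 1, mode="nearest")


def peak_in_window(
    trace: np.ndarray,
    dt: float,
    window: tuple[float, float],
    settle_ms: float = SETTLE_MS_DEFAULT,
    smooth_ms: float = SMOOTH_MS_DEFAULT,
) -> tuple[float, float]:
    """(peak_pA, peak_time_ms) of the largest-|I| smoothed sample in the window.

    The search starts ``settle_ms`` after the window (step) onset so the
    capacitive transient never masquerades as the peak.
    """
    i0 = int(round((window[0] + settle_ms) / dt))
    i1 = int(round(window[1] / dt))
    if i0 >= i1 or i1 > len(trace):
        raise ValueError(f"peak window {window} (settle {settle_ms} ms) outside the sweep")
    # smooth within the window only, so the capacitive spikes at the step
    # edges can never bleed into the search region
    seg = smoothed(trace[i0:i1], dt, smooth_ms)
    k = int(np.argmax(np.abs(seg)))  # argmax -> earliest sample on ties
    return float(seg[k]), (i0 + k) * dt


@dataclass
class PeakTable:
    """Per-sweep peak currents of an I-V family for one cell.

    data : DataFrame with columns ``voltage`` (mV, LJP-corrected, strictly
        increasing), ``peak_pa`` and ``peak_pa_pf`` (peak / c_m).
    qc_status : 'pending' | 'included' | 'excluded'
    """

    data: pd.DataFrame
    c_m: float
    cell_id: str = ""
    construct: str = ""
    qc_status: str = "pending"
    qc_reason: str | None = None

    @property
    def v_max(self) -> float:
        """Test potential (corrected, mV) of maximal inward current."""
        idx = int(np.argmax(np.abs(self.data["peak_pa"].to_numpy())))
        return float(self.data["voltage"].iloc[idx])

    @property
    def peak_at_v_max(self) -> float:
        idx = int(np.argmax(np.abs(self.data["peak_pa"].to_numpy())))
        return float(self.data["peak_pa"].iloc[idx])


def extract_peaks(
    rec: Recording,
    settle_ms: float = SETTLE_MS_DEFAULT,
    smooth_ms: float = SMOOTH_MS_DEFAULT,
) -> PeakTable:
    """Peak current per sweep, with LJP-corrected voltages and pA/pF column."""
    rows = []
    for sw in rec.sweeps:
        if sw.test_window is None or sw.test_voltage is None:
            continue
        peak, _t = peak_in_window(sw.current, rec.dt, sw.test_window, settle_ms, smooth_ms)
        rows.append((correct_ljp(sw.test_voltage, rec.ljp), peak))
    if not rows:
        raise ValueError("recording contains no analysable test sweeps")
    df = pd.DataFrame(rows, columns=["voltage", "peak_pa"]).sort_values("voltage", ignore_index=True)
    if df["voltage"].duplicated().any():
        raise ValueError("duplicate test voltages in recording")
    df["peak_pa_pf"] = df["peak_pa"] / rec.c_m
    return PeakTable(data=df, c_m=rec.c_m, cell_id=rec.cell_id, construct=rec.construct)


def qc_filter(peaks: PeakTable) -> PeakTable:
    """Prospective exclusion of cells with |peak| < 100 pA or > 1000 pA at V_max."""
    amp = abs(peaks.peak_at_v_max)
    if amp < QC_MIN_PA:
        return replace(peaks, qc_status="excluded", qc_reason=f"too small (|I| = {amp:.1f} pA < {QC_MIN_PA:.0f})")
    if amp > QC_MAX_PA:
        return replace(peaks, qc_status="excluded", qc_reason=f"too large (|I| = {amp:.1f} pA > {QC_MAX_PA:.0f})")
    return replace(peaks, qc_status="included", qc_reason=None)
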