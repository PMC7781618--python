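"""End-to-end per-cell analysis: recordings -> fitted-parameter rows.

One row per cell, carrying QC status, the I-V/G-V activation fit, the
steady-state inactivation fit and the 5-s inactivation r-values; this is
the table that cohort statistics aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from . import gating, preprocess

__all__ = ["AnalysisOptions", "ssi_ratios", "analyze_cell", "analyze_recordings"]

RESULT_COLUMNS = [
    "construct", "cell_id", "c_m_pf", "qc_status", "qc_reason",
    "v_max", "peak_at_v_max_pa", "peak_at_v_max_pa_pf",
    "v_half_act", "slope_act", "g_max_ns", "v_rev", "act_converged",
    "v_half_inact", "slope_inact", "non_inactivating_pct", "ssi_converged",
    "r50", "r100", "r250", "r500", "r1000", "r5000",
]


@dataclass(frozen=True)
class AnalysisOptions:
    """Preprocessing/fitting knobs shared across the pipeline.

    ljp is applied once here; all reported voltages are corrected.
    """

    leak: str = "auto"  # 'offline' | 'p4' | 'none' | 'auto'
    settle_ms: float = 2.5
    smooth_ms: float = 0.2
    min_peak_pa: float = 20.0


def ssi_ratios(rec, opts: AnalysisOptions = AnalysisOptions()) -> pd.DataFrame:
    """Per-sweep test/control peak ratio vs conditioning voltage (corrected mV)."""
    sub = preprocess.leak_subtract(rec, opts.leak)
    rows = []
    for sw in sub.sweeps:
        if sw.kind != "ssi":
            continue
        ctrl, _ = preprocess.peak_in_window(sw.current, rec.dt, sw.control_window, opts.settle_ms, opts.smooth_ms)
        test, _ = preprocess.peak_in_window(sw.current, rec.dt, sw.test_window, opts.settle_ms, opts.smooth_ms)
        if abs(ctrl) < opts.min_peak_pa:
            raise ValueError("control-pulse peak below the noise floor; SSI ratio undefined")
        rows.append((preprocess.correct_ljp(sw.conditioning_voltage, rec.ljp), test / ctrl))
    if not rows:
        raise ValueError("recording contains no SSI sweeps")
    return pd.DataFrame(rows, columns=["voltage", "ratio"]).sort_values("voltage", ignore_index=True)


def analyze_cell(recordings, opts: AnalysisOptions = AnalysisOptions()) -> dict:
    """Analyse all recordings of one cell; returns one result row (dict)."""
    row = {c: np.nan for c in RESULT_COLUMNS}
    row.update(qc_status="pending", qc_reason=None, act_converged=False, ssi_converged=False)
    iv_rec = next((r for r in recordings if r.protocol.kind == "IV"), None)
    ssi_rec = next((r for r in recordings if r.protocol.kind == "SSI"), None)
    inact_rec = next((r for r in recordings if r.protocol.kind == "INACT5S"), None)
    any_rec = recordings[0]
    row["construct"] = any_rec.construct
    row["cell_id"] = any_rec.cell_id
    row["c_m_pf"] = any_rec.c_m

    if iv_rec is not None:
        sub = preprocess.leak_subtract(iv_rec, opts.leak)
        peaks = preprocess.qc_filter(preprocess.extract_peaks(sub, opts.settle_ms, opts.smooth_ms))
        row["qc_status"] = peaks.qc_status
        row["qc_reason"] = peaks.qc_reason
        row["v_max"] = peaks.v_max
        row["peak_at_v_max_pa"] = peaks.peak_at_v_max
        row["peak_at_v_max_pa_pf"] = peaks.peak_at_v_max / peaks.c_m
        try:
            ivfit = gating.fit_iv(peaks)
            gv = gating.gv_transform(peaks, ivfit.v_rev)
            gvfit = gating.fit_gv(gv)
            row.update(
                v_half_act=gvfit.v_half,
                slope_act=gvfit.slope,
                g_max_ns=ivfit.g_max,
                v_rev=ivfit.v_rev,
                act_converged=ivfit.converged and gvfit.converged,
            )
        except ValueError as exc:
            row["act_converged"] = False
            row["qc_reason"] = row["qc_reason"] or f"activation fit failed: {exc}"

    if ssi_rec is not None:
        try:
            table = ssi_ratios(ssi_rec, opts)
            fit = gating.fit_ssi(table)
            row.update(
                v_half_inact=fit.v_half,
                slope_inact=fit.slope,
                non_inactivating_pct=fit.non_inactivating_pct,
                ssi_converged=fit.converged,
            )
        except ValueError:
            row["ssi_converged"] = False

    if inact_rec is not None:
        sub = preprocess.leak_subtract(inact_rec, opts.leak)
        sw = sub.sweeps[0]
        try:
            kin = gating.inactivation_kinetics(
                sw.current,
                sub.dt,
                onset_ms=sw.test_window[0],
                pulse_ms=sw.test_window[1] - sw.test_window[0],
                v_max=preprocess.correct_ljp(sw.test_voltage, sub.ljp),
                settle_ms=opts.settle_ms,
                smooth_ms=opts.smooth_ms,
                min_peak_pa=opts.min_peak_pa,
            )
            for name, val in zip(("r50", "r100", "r250", "r500", "r1000", "r5000"), kin.as_array()):
                row[name] = val
        except ValueError:
            pass
    return row


def analyze_recordings(recordings, opts: AnalysisOptions = AnalysisOptions()) -> pd.DataFrame:
    """Group recordings by cell, analyse each, return the per-cell results table."""
    by_cell = defaultdict(list)
    for rec in recordings:
        by_cell[rec.cell_id].append(rec)
    rows = [analyze_cell(recs, opts) for recs in by_cell.values()]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
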