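"""Trace conditioning: LJP, leak subtraction, peak extraction, QC."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cavgating as cg
from cavgating import reference as ref
from cavgating.cohort import CohortSpec, CellVariability, simulate_cohort, simulate_recording
from cavgating.model import ActivationParams, ChannelParams, InactivationParams
from cavgating.preprocess import (
    PeakTable,
    correct_ljp,
    extract_peaks,
    leak_subtract,
    leak_subtract_offline,
    leak_subtract_p4,
    qc_filter,
)
from cavgating.protocols import default_protocols
from conftest import idealize, quiet_passive


IV = default_protocols()[0]


def one_cell_recording(params, leak_mode="offline", seed=0):
    spec = CohortSpec("x", 1, params, CellVariability(c_m_sd=0.0), seed=seed)
    return simulate_cohort(spec, [IV], leak_mode=leak_mode)[0]


def edge_mask(rec, margin_ms=10.0):
    """True away from every step edge (capacitive transients excluded)."""
    n = len(rec.sweeps[0].current)
    t = np.arange(n) * rec.dt
    mask = np.ones(n, dtype=bool)
    edges = np.cumsum([d for d, _ in rec.sweeps[-1].segments[:-1]])
    for e in edges:
        mask &= ~((t >= e - 2 * rec.dt) & (t <= e + margin_ms))
    return mask


class TestCorrectLjp:
    def test_holding_potential(self):
        assert correct_ljp(-80.0) == pytest.approx(-89.3)

    def test_zero_is_identity(self):
        assert correct_ljp(12.5, 0.0) == 12.5

    def test_arithmetic(self):
        assert correct_ljp(10.0, -9.3) == pytest.approx(0.7)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=-150, max_value=150))
    def test_pure_shift(self, v):
        assert correct_ljp(v, -9.3) - v == pytest.approx(-9.3, abs=1e-12)


class TestLeakSubtraction:
    def test_offline_pure_leak_cancels_exactly(self, params_8b43s):
        # leak only: make the channel invisible by zeroing driving force
        p = idealize(params_8b43s)
        p = ChannelParams(replace(p.act, g_max=1e-12), p.inact, replace(p.passive, g_leak=2.0))
        rec = one_cell_recording(p)
        sub = leak_subtract_offline(rec)
        mask = edge_mask(rec)
        for sw in sub.sweeps:
            assert np.max(np.abs(sw.current[mask])) < 1e-9

    def test_p4_pure_leak_cancels_exactly(self, params_8b43s):
        p = idealize(params_8b43s)
        p = ChannelParams(replace(p.act, g_max=1e-12), p.inact, replace(p.passive, g_leak=2.0))
        rec = one_cell_recording(p, leak_mode="p4")
        sub = leak_subtract(rec, "p4")
        for sw in sub.sweeps:
            assert np.max(np.abs(sw.current)) < 1e-9  # transients cancel too

    def test_offline_recovers_leak_free_peaks(self, params_8b43s):
        rec = one_cell_recording(idealize(params_8b43s).with_passive(g_leak=2.0))
        rec0 = one_cell_recording(idealize(params_8b43s))
        pt = extract_peaks(leak_subtract_offline(rec))
        pt0 = extract_peaks(leak_subtract(rec0, "none"))
        # the leak estimate absorbs the ~0.1 pA residual channel current at
        # holding, leaving errors of order 1 pA at the range extremes
        assert np.allclose(pt.data["peak_pa"], pt0.data["peak_pa"], atol=1.5)

    def test_p4_matches_offline_on_same_cell(self, params_8b43s):
        p = ref.channel_params_from_row(ref.TABLE_GATING_8B8A["8b 43S"])
        rec_p4 = one_cell_recording(p.with_passive(g_leak=1.5), leak_mode="p4", seed=4)
        rec_off = one_cell_recording(p.with_passive(g_leak=1.5), leak_mode="offline", seed=4)
        pk_p4 = extract_peaks(leak_subtract(rec_p4, "p4")).data["peak_pa"]
        pk_off = extract_peaks(leak_subtract(rec_off, "offline")).data["peak_pa"]
        # same cell, independent noise realisations: agree within noise
        assert np.allclose(pk_p4, pk_off, atol=30.0)

    def test_zero_leak_subtraction_is_noop(self, params_8b43s):
        rec = one_cell_recording(idealize(params_8b43s))
        sub = leak_subtract_offline(rec)
        for sw, sw0 in zip(sub.sweeps, rec.sweeps):
            assert np.allclose(sw.current, sw0.current, atol=1.5)

    def test_missing_reference_sweep_raises(self, params_8b43s):
        rec = one_cell_recording(idealize(params_8b43s), leak_mode="none")
        with pytest.raises(ValueError, match="reference"):
            leak_subtract_offline(rec)

    def test_p4_requires_four_subsweeps(self, params_8b43s):
        rec = one_cell_recording(idealize(params_8b43s), leak_mode="p4")
        sw = rec.sweeps[5]
        with pytest.raises(ValueError, match="4 subsweeps"):
            leak_subtract_p4(sw.current, sw.subsweeps[:3], main_segments=sw.segments,
                             sub_segments=sw.sub_segments[:3], dt=rec.dt)

    def test_p4_preserves_channel_current(self, params_8b43s):
        # subsweeps stay below the activation threshold, so the channel
        # current of the main sweep survives the correction unchanged
        p = idealize(params_8b43s).with_passive(g_leak=2.0)
        rec = one_cell_recording(p, leak_mode="p4")
        rec0 = one_cell_recording(idealize(params_8b43s), leak_mode="none")
        sub = leak_subtract(rec, "p4")
        i = [s.test_voltage for s in rec.sweeps].index(-10.0)
        sub0 = leak_subtract(rec0, "none")
        # P/4 cancels the capacitive transients, the uncorrected reference
        # keeps them: compare away from the step edges
        mask = edge_mask(rec, margin_ms=0.5)
        assert np.allclose(sub.sweeps[i].current[mask], sub0.sweeps[i].current[mask], atol=0.5)


class TestExtractPeaks:
    def test_zero_at_reversal(self, params_8b43s):
        p = idealize(params_8b43s)
        rec = one_cell_recording(p)
        pt = extract_peaks(leak_subtract(rec, "none"))
        near = pt.data.iloc[(pt.data["voltage"] - p.act.v_rev).abs().idxmin()]
        assert abs(near["peak_pa"]) < 0.05 * abs(pt.peak_at_v_max)

    def test_quasi_steady_peaks_match_closed_form(self, ideal_8b43s):
        rec = one_cell_recording(ideal_8b43s)
        pt = extract_peaks(leak_subtract(rec, "none"))
        act = ideal_8b43s.act
        v = pt.data["voltage"].to_numpy()
        expected = act.g_max * cg.steady_state_activation(v, act) * (v - act.v_rev)
        assert np.allclose(pt.data["peak_pa"], expected, rtol=5e-3, atol=0.5)

    def test_capacitance_normalisation(self):
        df = pd.DataFrame({"voltage": [-10.0], "peak_pa": [-400.0]})
        df["peak_pa_pf"] = df["peak_pa"] / 20.0
        assert df["peak_pa_pf"].iloc[0] == pytest.approx(-20.0)

    def test_window_outside_sweep_raises(self, ideal_8b43s):
        rec = one_cell_recording(ideal_8b43s)
        from cavgating.preprocess import peak_in_window

        with pytest.raises(ValueError):
            peak_in_window(rec.sweeps[0].current, rec.dt, (0.0, 1e5))


class TestQcFilter:
    def _table(self, peak):
        df = pd.DataFrame({"voltage": [-10.0, 0.0], "peak_pa": [peak, peak / 2], "peak_pa_pf": [0, 0]})
        return PeakTable(data=df, c_m=20.0)

    @pytest.mark.parametrize(
        "peak,status,reason_part",
        [(-400.0, "included", None), (-99.0, "excluded", "small"), (-1001.0, "excluded", "large"),
         (-100.5, "included", None), (999.0, "included", None)],
    )
    def test_thresholds(self, peak, status, reason_part):
        out = qc_filter(self._table(peak))
        assert out.qc_status == status
        if reason_part:
            assert reason_part in out.qc_reason

    def test_idempotent(self):
        once = qc_filter(self._table(-99.0))
        twice = qc_filter(once)
        assert (twice.qc_status, twice.qc_reason) == (once.qc_status, once.qc_reason)
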