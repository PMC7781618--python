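"""Boltzmann fitting, SSI fitting and r-value kinetics."""

import numpy as np
import pandas as pd
import pytest

import cavgating as cg
from cavgating.gating import (
    R_VALUE_TIMES_MS,
    fit_gv,
    fit_iv,
    fit_rvalue_decay,
    fit_ssi,
    gv_transform,
    inactivation_kinetics,
)
from cavgating.model import ActivationParams, ChannelParams, InactivationParams, simulate_sweep
from conftest import quiet_passive


# activation parameters of the exon-11 short wild-type construct
VH, K, VREV, GMAX = -13.40, 7.60, 64.75, 8.0
V_GRID = np.arange(-89.3, 71.0, 5.0)


def exact_iv_table(vh=VH, k=K, vrev=VREV, gmax=GMAX, v=V_GRID, scale=1.0):
    i = scale * gmax * (v - vrev) / (1.0 + np.exp(-(v - vh) / k))
    return pd.DataFrame({"voltage": v, "peak_pa": i})


class TestFitIV:
    def test_exact_recovery(self):
        fit = fit_iv(exact_iv_table())
        assert fit.converged
        assert fit.v_half == pytest.approx(VH, abs=1e-4)
        assert fit.slope == pytest.approx(K, abs=1e-4)
        assert fit.v_rev == pytest.approx(VREV, abs=1e-4)
        assert fit.g_max == pytest.approx(GMAX, rel=1e-5)

    def test_scale_equivariance(self):
        a = fit_iv(exact_iv_table())
        b = fit_iv(exact_iv_table(scale=2.5))
        assert b.g_max == pytest.approx(2.5 * a.g_max, rel=1e-6)
        assert b.v_half == pytest.approx(a.v_half, abs=1e-6)
        assert b.slope == pytest.approx(a.slope, abs=1e-6)
        assert b.v_rev == pytest.approx(a.v_rev, abs=1e-6)

    def test_translation_equivariance(self):
        df = exact_iv_table()
        shifted = df.copy()
        shifted["voltage"] += 7.0
        a, b = fit_iv(df), fit_iv(shifted)
        assert b.v_half - a.v_half == pytest.approx(7.0, abs=1e-5)
        assert b.v_rev - a.v_rev == pytest.approx(7.0, abs=1e-5)
        assert b.slope == pytest.approx(a.slope, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_iv(exact_iv_table(v=np.array([-40.0, -30, -20, -10, 0, 10, 20])))


class TestGVTransform:
    def test_algebraic_cancellation(self):
        df = exact_iv_table()
        gv = gv_transform(df, VREV)
        m_inf = 1.0 / (1.0 + np.exp(-(gv["voltage"] - VH) / K))
        assert np.allclose(gv["g"] / GMAX, m_inf, atol=1e-12)

    def test_midpoint_is_half_gmax(self):
        gv = gv_transform(exact_iv_table(v=np.array([VH, -40.0, 0.0, 20.0])), VREV)
        g_at_vh = gv.loc[gv["voltage"] == VH, "g"].iloc[0]
        assert g_at_vh / GMAX == pytest.approx(0.5, abs=1e-12)

    def test_zero_current_gives_zero_conductance(self):
        df = exact_iv_table(scale=0.0)
        gv = gv_transform(df, VREV)
        assert np.allclose(gv["g"], 0.0)

    def test_points_near_vrev_dropped(self):
        gv = gv_transform(exact_iv_table(), VREV)
        assert (np.abs(gv["voltage"] - VREV) >= 5.0).all()

    def test_empty_after_exclusion_raises(self):
        df = exact_iv_table(v=np.array([VREV - 1.0, VREV + 1.0]))
        with pytest.raises(ValueError):
            gv_transform(df, VREV)


class TestFitGV:
    def test_exact_recovery(self):
        gv = gv_transform(exact_iv_table(), VREV)
        fit = fit_gv(gv)
        assert fit.converged
        assert fit.v_half == pytest.approx(VH, abs=1e-6)
        assert fit.slope == pytest.approx(K, abs=1e-6)

    def test_translation_equivariance(self):
        gv = gv_transform(exact_iv_table(), VREV)
        shifted = pd.DataFrame({"voltage": gv["voltage"] + 11.0, "g": gv["g"], "drive": gv["drive"]})
        a, b = fit_gv(gv), fit_gv(shifted)
        assert b.v_half - a.v_half == pytest.approx(11.0, abs=1e-4)
        assert b.slope == pytest.approx(a.slope, abs=1e-4)

    def test_iv_gv_self_consistency(self):
        # fitting the conductance transform of exact I-V data returns the
        # I-V fit's own v_half and slope
        ivfit = fit_iv(exact_iv_table())
        gvfit = fit_gv(gv_transform(exact_iv_table(), ivfit.v_rev))
        assert gvfit.v_half == pytest.approx(ivfit.v_half, abs=0.01)
        assert gvfit.slope == pytest.approx(ivfit.slope, abs=0.01)

    def test_agrees_with_brute_force_grid_search(self):
        # independent oracle: exhaustive 0.01-mV grid over (v_half, slope)
        # with the scale profiled out analytically
        rng = np.random.default_rng(7)
        v = np.linspace(-60.0, 40.0, 201)
        g_true = GMAX / (1.0 + np.exp(-(v - VH) / K))
        g = g_true + rng.normal(0, 0.1, v.size)
        table = pd.DataFrame({"voltage": v, "g": g})
        fit = fit_gv(table)

        vh_grid = np.arange(VH - 1.0, VH + 1.0, 0.01)
        k_grid = np.arange(K - 1.0, K + 1.0, 0.01)
        best = (np.inf, None, None)
        for vh in vh_grid:
            b = 1.0 / (1.0 + np.exp(-(v[None, :] - vh) / k_grid[:, None]))
            a = (b @ g) / np.sum(b * b, axis=1)  # optimal scale per slope
            sse = np.sum((a[:, None] * b - g[None, :]) ** 2, axis=1)
            j = int(np.argmin(sse))
            if sse[j] < best[0]:
                best = (sse[j], vh, k_grid[j])
        assert fit.v_half == pytest.approx(best[1], abs=0.02)
        assert fit.slope == pytest.approx(best[2], abs=0.02)


class TestFitSSI:
    @staticmethod
    def exact_table(vh=-39.94, k=4.94, p=0.1082, v=None):
        if v is None:
            v = np.arange(-119.3, 2.0, 10.0)
        r = (1.0 - p) / (1.0 + np.exp((v - vh) / k)) + p
        return pd.DataFrame({"voltage": v, "ratio": r})

    def test_exact_recovery(self):
        fit = fit_ssi(self.exact_table())
        assert fit.converged
        assert fit.v_half == pytest.approx(-39.94, abs=1e-4)
        assert fit.slope == pytest.approx(4.94, abs=1e-4)
        assert fit.plateau == pytest.approx(0.1082, abs=1e-4)
        assert fit.non_inactivating_pct == pytest.approx(10.82, abs=1e-2)

    def test_flat_input_flagged_degenerate(self):
        df = pd.DataFrame({"voltage": np.arange(-119.3, 2.0, 10.0), "ratio": 1.0})
        fit = fit_ssi(df)
        assert not fit.converged

    def test_most_negative_conditioning_ratio_near_one(self):
        table = self.exact_table()
        assert table["ratio"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_too_few_voltages_rejected(self):
        with pytest.raises(ValueError):
            fit_ssi(self.exact_table(v=np.array([-100.0, -60, -40, -20, 0.0])))


class TestInactivationKinetics:
    def _trace(self, inact, v_step=0.0, noise=0.0, seed=0):
        act = ActivationParams(v_half=-13.4, slope=7.6, g_max=8.0, v_rev=64.75, tau_act=0.01)
        p = ChannelParams(act, inact, quiet_passive(noise_sd=noise))
        return simulate_sweep([(10, -89.3), (5010, v_step), (10, -89.3)], p, 0.05, rng=seed)

    def test_mono_exponential_r500_is_e_inverse(self):
        inact = InactivationParams(v_half=-60.0, slope=5.0, plateau=0.0,
                                   tau_fast=500.0, tau_slow=500.0, frac_fast=1.0)
        kin = inactivation_kinetics(self._trace(inact), 0.05, onset_ms=10.0, pulse_ms=5010.0)
        assert kin.r500 == pytest.approx(100 * np.exp(-1.0), abs=0.5)

    def test_constant_current_gives_all_100(self):
        inact = InactivationParams(v_half=-60.0, slope=5.0, plateau=1.0)
        kin = inactivation_kinetics(self._trace(inact), 0.05, onset_ms=10.0, pulse_ms=5010.0)
        assert np.allclose(kin.as_array(), 100.0, atol=0.1)

    def test_monotone_decreasing_on_noiseless_trace(self):
        inact = InactivationParams(v_half=-40.0, slope=5.0, plateau=0.1)
        kin = inactivation_kinetics(self._trace(inact), 0.05, onset_ms=10.0, pulse_ms=5010.0)
        r = kin.as_array()
        assert np.all(np.diff(r) <= 1e-9)
        assert r[0] <= 100.0 and r[-1] >= 0.0

    def test_noise_floor_raises(self):
        inact = InactivationParams(v_half=-40.0, slope=5.0, plateau=0.1)
        tiny = self._trace(inact) * 1e-3
        with pytest.raises(ValueError, match="noise floor"):
            inactivation_kinetics(tiny, 0.05, onset_ms=10.0, pulse_ms=5010.0)

    def test_short_pulse_rejected(self):
        inact = InactivationParams(v_half=-40.0, slope=5.0, plateau=0.1)
        with pytest.raises(ValueError):
            inactivation_kinetics(self._trace(inact), 0.05, onset_ms=10.0, pulse_ms=1000.0)


class TestFitRvalueDecay:
    def test_roundtrip_on_exact_biexponential(self):
        f, tf, ts, p = 0.6, 90.0, 900.0, 0.08
        t = np.array(R_VALUE_TIMES_MS)
        r = 100 * ((1 - p) * (f * np.exp(-t / tf) + (1 - f) * np.exp(-t / ts)) + p)
        f2, tf2, ts2, p2 = fit_rvalue_decay(t, r)
        assert f2 == pytest.approx(f, abs=1e-3)
        assert tf2 == pytest.approx(tf, rel=1e-3)
        assert ts2 == pytest.approx(ts, rel=1e-3)
        assert p2 == pytest.approx(p, abs=1e-4)

    def test_published_rvalues_reproduced_within_two_points(self):
        from cavgating import reference as ref

        kin = ref.TABLE_KINETICS_R498L["8a 42"]
        f, tf, ts, p = fit_rvalue_decay(R_VALUE_TIMES_MS, kin.r)
        t = np.array(R_VALUE_TIMES_MS)
        pred = 100 * ((1 - p) * (f * np.exp(-t / tf) + (1 - f) * np.exp(-t / ts)) + p)
        assert np.max(np.abs(pred - np.array(kin.r))) < 2.0
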