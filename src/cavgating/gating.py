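"""Gating parameter estimation.

Implements the four estimators the per-cell analysis reports:

* peak I-V fit:      I(V) = G_max (V - V_rev) / (1 + exp[-(V - V_0.5)/k])
* G-V Boltzmann:     G(V) = G_max / (1 + exp[-(V - V_0.5)/k])
  after the conductance transform G = I / (V - V_rev)
* steady-state inactivation (modified Boltzmann with a non-inactivating
  plateau):          I(V)/I_ctrl = (1 - p) / (1 + exp[(V - V_0.5)/k]) + p
* r-value kinetics:  percentage of peak current remaining at fixed times
  during a 5-s depolarisation to V_max.

All fits are deterministic: fixed data-driven initialisation, bounded
Levenberg/trust-region least squares, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .preprocess import PeakTable, peak_in_window, smoothed

__all__ = [
    "IVFit",
    "GVFit",
    "SSIFit",
    "KineticsResult",
    "fit_iv",
    "gv_transform",
    "fit_gv",
    "fit_ssi",
    "inactivation_kinetics",
    "fit_rvalue_decay",
    "R_VALUE_TIMES_MS",
]

SLOPE_BOUNDS = (0.5, 30.0)  # mV; fits pinned at a bound are flagged
GV_EXCLUSION_MV = 5.0  # drop points this close to V_rev (0/0 amplification)
R_VALUE_TIMES_MS = (50.0, 100.0, 250.0, 500.0, 1000.0, 5000.0)
R_VALUE_HALF_WINDOW_MS = 2.0


def _at_bound(x, lo, hi, tol=1e-6) -> bool:
    return x <= lo * (1 + tol) + tol or x >= hi * (1 - tol) - tol


@dataclass
class IVFit:
    v_half: float
    slope: float
    g_max: float
    v_rev: float
    residual_sse: float
    converged: bool


@dataclass
class GVFit:
    v_half: float
    slope: float
    g_max: float
    residual_sse: float
    converged: bool


@dataclass
class SSIFit:
    v_half: float
    slope: float
    plateau: float
    residual_sse: float
    converged: bool

    @property
    def non_inactivating_pct(self) -> float:
        return 100.0 * self.plateau


@dataclass
class KineticsResult:
    """Remaining current (percent of peak) at the six standard time points."""

    r50: float
    r100: float
    r250: float
    r500: float
    r1000: float
    r5000: float
    v_max_used: float = float("nan")

    def as_array(self) -> np.ndarray:
        return np.array([self.r50, self.r100, self.r250, self.r500, self.r1000, self.r5000])


def _iv_model(theta, v):
    g_max, v_rev, v_half, slope = theta
    return g_max * (v - v_rev) / (1.0 + np.exp(-(v - v_half) / slope))


def _interp_crossing(v, y, level):
    """Voltage where y first crosses `level` (linear interpolation), else None."""
    s = y - level
    for j in range(1, len(v)):
        if s[j - 1] == 0:
            return float(v[j - 1])
        if s[j - 1] * s[j] < 0:
            f = s[j - 1] / (s[j - 1] - s[j])
            return float(v[j - 1] + f * (v[j] - v[j - 1]))
    return None


def _iv_init(v, i):
    """Deterministic initialisation (protocol independent).

    v_rev from the zero crossing of the positive limb, v_half from the
    half-maximal inward current on the hyperpolarised limb, slope 8 mV,
    g_max from |I_min| over the driving-force magnitude.
    """
    k_min = int(np.argmin(i))
    i_min = i[k_min]
    vr = _interp_crossing(v[k_min:], i[k_min:], 0.0)
    if vr is None:
        vr = float(v[-1]) + 10.0
    vh = _interp_crossing(v[: k_min + 1], i[: k_min + 1], i_min / 2.0)
    if vh is None:
        vh = float(v[k_min]) - 10.0
    g0 = abs(i_min) / max(abs(vr - vh), 1.0)
    return np.array([max(g0, 1e-3), vr, vh, 8.0])


def fit_iv(peaks: PeakTable | pd.DataFrame) -> IVFit:
    """Nonlinear least-squares fit of the peak I-V relationship.

    Requires >= 8 voltage points spanning both sides of the I-V minimum.
    Deterministic given the data; ``converged`` is False when the optimiser
    fails or the slope sits at its bound.
    """
    df = peaks.data if isinstance(peaks, PeakTable) else peaks
    v = df["voltage"].to_numpy(dtype=float)
    i = df["peak_pa"].to_numpy(dtype=float)
    if len(v) < 8:
        raise ValueError(f"I-V fit requires >= 8 points, got {len(v)}")
    k_min = int(np.argmin(i))
    if k_min == 0 or k_min == len(v) - 1:
        raise ValueError("I-V minimum must be interior to the voltage range")
    theta0 = _iv_init(v, i)
    scale = max(np.max(np.abs(i)), 1.0)
    lo = [1e-6, v.min() - 50.0, v.min() - 50.0, SLOPE_BOUNDS[0]]
    hi = [np.inf, v.max() + 100.0, v.max() + 50.0, SLOPE_BOUNDS[1]]
    theta0 = np.clip(theta0, lo, hi)
    res = least_squares(
        lambda th: (_iv_model(th, v) - i) / scale,
        theta0,
        bounds=(lo, hi),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    g_max, v_rev, v_half, slope = res.x
    sse = float(np.sum((_iv_model(res.x, v) - i) ** 2))
    converged = bool(res.success) and not _at_bound(slope, *SLOPE_BOUNDS)
    return IVFit(v_half=float(v_half), slope=float(slope), g_max=float(g_max), v_rev=float(v_rev),
                 residual_sse=sse, converged=converged)


def gv_transform(peaks: PeakTable | pd.DataFrame, v_rev: float) -> pd.DataFrame:
    """Conductance transform G = I/(V - V_rev).

    Points within 5 mV of V_rev are dropped (near-zero driving force
    amplifies noise).  Returns a DataFrame with ``voltage`` and ``g`` (nS).
    """
    df = peaks.data if isinstance(peaks, PeakTable) else peaks
    keep = np.abs(df["voltage"] - v_rev) >= GV_EXCLUSION_MV
    out = df.loc[keep, ["voltage"]].copy()
    if out.empty:
        raise ValueError("no points remain after excluding the neighbourhood of v_rev")
    out["g"] = df.loc[keep, "peak_pa"] / (df.loc[keep, "voltage"] - v_rev)
    out["drive"] = np.abs(df.loc[keep, "voltage"] - v_rev)
    return out.reset_index(drop=True)


def fit_gv(gv_table: pd.DataFrame) -> GVFit:
    """Boltzmann fit of the G-V curve with free scale G_max.

    The reported activation V_0.5 and slope come from this fit.
    """
    v = gv_table["voltage"].to_numpy(dtype=float)
    g = gv_table["g"].to_numpy(dtype=float)
    if len(v) < 6:
        raise ValueError(f"G-V fit requires >= 6 points, got {len(v)}")
    # weight by driving force: peak-current noise is roughly homoscedastic,
    # so var(G) ~ 1/(V - V_rev)^2 and WLS with w = |V - V_rev| restores the
    # current-space noise model (points near V_rev otherwise dominate)
    if "drive" in gv_table:
        w = gv_table["drive"].to_numpy(dtype=float)
        w = w / np.max(w)
    else:
        w = np.ones_like(v)
    a0 = max(float(np.mean(np.sort(g)[-3:])), 1e-6)
    vh0 = _interp_crossing(v, g, a0 / 2.0)
    if vh0 is None:
        vh0 = float(np.median(v))
    lo = [1e-9, v.min() - 100.0, SLOPE_BOUNDS[0]]
    hi = [np.inf, v.max() + 100.0, SLOPE_BOUNDS[1]]
    theta0 = np.clip([a0, vh0, 8.0], lo, hi)
    res = least_squares(
        lambda th: w * (th[0] / (1.0 + np.exp(-(v - th[1]) / th[2])) - g),
        theta0,
        bounds=(lo, hi),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        x_scale=[max(a0, 1e-6), 10.0, 5.0],
    )
    a, vh, k = res.x
    sse = float(np.sum(res.fun**2))
    converged = bool(res.success) and not _at_bound(k, *SLOPE_BOUNDS)
    return GVFit(v_half=float(vh), slope=float(k), g_max=float(a), residual_sse=sse, converged=converged)


def _ssi_model(theta, v):
    vh, k, p = theta
    return (1.0 - p) / (1.0 + np.exp((v - vh) / k)) + p


def fit_ssi(ssi_table: pd.DataFrame) -> SSIFit:
    """Fit of the steady-state inactivation curve (modified Boltzmann).

    ``ssi_table`` holds one row per conditioning voltage with columns
    ``voltage`` (mV, corrected) and ``ratio`` (test-peak / control-peak).
    The plateau is bounded to [0, 1]; an essentially flat input (no
    inactivation) is flagged non-converged.
    """
    v = ssi_table["voltage"].to_numpy(dtype=float)
    r = ssi_table["ratio"].to_numpy(dtype=float)
    if len(v) < 6:
        raise ValueError(f"SSI fit requires >= 6 conditioning voltages, got {len(v)}")
    order = np.argsort(v)
    v, r = v[order], r[order]
    if float(np.ptp(r)) < 0.05:
        return SSIFit(v_half=float("nan"), slope=float("nan"), plateau=float(np.clip(np.mean(r), 0, 1)),
                      residual_sse=float("nan"), converged=False)
    p0 = float(np.clip(np.min(r), 0.0, 0.99))
    vh0 = _interp_crossing(v, r, (1.0 + p0) / 2.0)
    if vh0 is None:
        vh0 = float(np.median(v))
    lo = [v.min() - 100.0, SLOPE_BOUNDS[0], 0.0]
    hi = [v.max() + 100.0, SLOPE_BOUNDS[1], 1.0]
    theta0 = np.clip([vh0, 5.0, p0], lo, hi)
    res = least_squares(
        lambda th: _ssi_model(th, v) - r,
        theta0,
        bounds=(lo, hi),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        x_scale=[10.0, 5.0, 0.1],
    )
    vh, k, p = res.x
    sse = float(np.sum(res.fun**2))
    converged = bool(res.success) and not _at_bound(k, *SLOPE_BOUNDS)
    return SSIFit(v_half=float(vh), slope=float(k), plateau=float(p), residual_sse=sse, converged=converged)


def inactivation_kinetics(
    trace: np.ndarray,
    dt: float,
    *,
    onset_ms: float,
    pulse_ms: float = 5000.0,
    v_max: float = float("nan"),
    settle_ms: float = 2.5,
    smooth_ms: float = 0.2,
    min_peak_pa: float = 20.0,
) -> KineticsResult:
    """r-values: remaining current (% of peak) at 50...5000 ms into the pulse.

    Each r_t is the mean current over t +/- 2 ms (times measured from pulse
    onset), expressed as a percentage of the peak current located as in
    peak extraction.  Raises when the pulse is shorter than 5 s or the peak
    is below ``min_peak_pa`` (noise floor).
    """
    if pulse_ms < R_VALUE_TIMES_MS[-1]:
        raise ValueError("inactivation kinetics require a pulse of at least 5000 ms")
    peak, _tpk = peak_in_window(trace, dt, (onset_ms, onset_ms + pulse_ms), settle_ms, smooth_ms)
    if abs(peak) < min_peak_pa:
        raise ValueError(f"peak current {peak:.1f} pA below the {min_peak_pa:.0f} pA noise floor")
    rs = []
    for t in R_VALUE_TIMES_MS:
        # +/- 2 ms average on the raw trace, clipped to the pulse interior so
        # the end-of-pulse capacitive transient never enters the window
        lo = onset_ms + t - R_VALUE_HALF_WINDOW_MS
        hi = min(onset_ms + t + R_VALUE_HALF_WINDOW_MS, onset_ms + pulse_ms - 0.25)
        i0, i1 = int(round(lo / dt)), int(round(hi / dt)) + 1
        if i1 > len(trace) or i1 <= i0:
            raise ValueError(f"r-value time {t} ms outside the recorded sweep")
        rs.append(100.0 * abs(float(np.mean(trace[i0:i1]))) / abs(peak))
    return KineticsResult(*rs, v_max_used=v_max)


def fit_rvalue_decay(times_ms, r_percent) -> tuple[float, float, float, float]:
    """Least-squares bi-exponential-plus-plateau fit to a set of r-values.

    Returns (frac_fast, tau_fast_ms, tau_slow_ms, plateau) such that
    ``r(t)/100 = (1 - p) [f exp(-t/tau_f) + (1 - f) exp(-t/tau_s)] + p``.
    Used to turn a printed r-value row into simulator kinetics.
    """
    t = np.asarray(times_ms, dtype=float)
    y = np.asarray(r_percent, dtype=float) / 100.0

    def model(th):
        f, ltf, lts, p = th
        tf, ts = np.exp(ltf), np.exp(lts)
        return (1.0 - p) * (f * np.exp(-t / tf) + (1.0 - f) * np.exp(-t / ts)) + p

    lo = [0.0, np.log(5.0), np.log(100.0), 0.0]
    hi = [1.0, np.log(2000.0), np.log(20000.0), 1.0]
    theta0 = [0.5, np.log(100.0), np.log(1500.0), max(float(y[-1]) * 0.8, 1e-3)]
    res = least_squares(lambda th: model(th) - y, theta0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    f, ltf, lts, p = res.x
    tf, ts = float(np.exp(ltf)), float(np.exp(lts))
    if tf > ts:  # keep the fast/slow labelling canonical
        tf, ts = ts, tf
        f = 1.0 - f
    return float(f), tf, ts, float(p)
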