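"""Simulate-then-recover harness.

Builds a cohort whose ground-truth means are a published table row (between-
cell SD = SEM * sqrt(n)), pushes it through the full pipeline (simulation,
leak subtraction, peak extraction, fitting) and reports the recovered cohort
means.  This is how the package checks itself against the printed values in
the absence of raw recordings.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import reference as ref
from .cohort import simulate_cohort
from .gating import R_VALUE_TIMES_MS, fit_rvalue_decay
from .model import ChannelParams
from .pipeline import AnalysisOptions, analyze_recordings
from .protocols import default_protocols
from .stats import included_values

__all__ = [
    "recover_activation_mean",
    "recover_inactivation_means",
    "recover_r50_mean",
    "recover_gating_shifts",
]

_OPTS = AnalysisOptions()


def _cohort_means(spec, protocols, parameters):
    res = analyze_recordings(simulate_cohort(spec, protocols), _OPTS)
    out = {}
    for p in parameters:
        vals = included_values(res, spec.construct, p)
        out[p] = {"mean": float(np.mean(vals)), "n": int(len(vals))}
    return out


def recover_activation_mean(row: ref.GatingRow, n_cells: int, seed: int) -> dict:
    """Cohort-mean fitted V0.5,act for a cohort generated from ``row``.

    Simulates the I-V protocol (20-ms steps, 5 mV increments, 5 pA noise,
    offline leak subtraction) for ``n_cells`` virtual cells and returns the
    mean of the per-cell G-V Boltzmann midpoints over QC-included,
    converged cells.
    """
    iv = default_protocols()[0]
    spec = ref.cohort_spec_from_row("cohort", row, n_cells=n_cells, seed=seed)
    return _cohort_means(spec, [iv], ["v_half_act"])["v_half_act"]


def recover_inactivation_means(row: ref.GatingRow, n_cells: int, seed: int) -> dict:
    """Cohort-mean V0.5,inact and non-inactivating % via the 5-s SSI protocol."""
    iv, ssi, _ = default_protocols()
    spec = ref.cohort_spec_from_row("cohort", row, n_cells=n_cells, seed=seed)
    return _cohort_means(spec, [iv, ssi], ["v_half_inact", "non_inactivating_pct"])


def kinetics_params_from_rvalues(kin_row: ref.KineticsRow, act_row: ref.GatingRow) -> ChannelParams:
    """Mean cell parameters whose 5-s decay reproduces a printed r-value row.

    The bi-exponential-plus-plateau decay fitted to the six r-values defines
    (frac_fast, tau_fast, tau_slow, plateau); the availability midpoint is
    placed far below V_max so the long-time limit of the simulated decay is
    exactly the fitted plateau.
    """
    f, tf, ts, p = fit_rvalue_decay(R_VALUE_TIMES_MS, kin_row.r)
    params = ref.channel_params_from_row(act_row, tau_fast=tf, tau_slow=ts, frac_fast=f)
    return ChannelParams(
        act=params.act,
        inact=replace(params.inact, v_half=-60.0, slope=5.0, plateau=p),
        passive=params.passive,
    )


def recover_r50_mean(
    kin_row: ref.KineticsRow,
    act_row: ref.GatingRow,
    n_cells: int,
    seed: int,
    which: str = "r50",
) -> dict:
    """Cohort-mean r-value from simulated noisy 5-s depolarisations to V_max.

    Between-cell variability: common log-normal factor (sigma 0.25) on both
    inactivation time constants, SD 0.05 on frac_fast, and a plateau SD
    implied by the printed r5000 SEM.
    """
    iv, _, inact5s = default_protocols()
    mean_params = kinetics_params_from_rvalues(kin_row, act_row)
    base = ref.cohort_spec_from_row("cohort", act_row, n_cells=n_cells, seed=seed)
    variability = replace(
        base.variability,
        v_half_inact_sd=0.0,
        slope_inact_sd=0.0,
        plateau_sd=kin_row.sem[5] * np.sqrt(kin_row.n) / 100.0,
        tau_sigma=0.25,
        frac_fast_sd=0.05,
    )
    spec = replace(base, mean_params=mean_params, variability=variability)
    return _cohort_means(spec, [iv, inact5s], [which])[which]


def recover_gating_shifts(
    row_ref: ref.GatingRow,
    row_test: ref.GatingRow,
    seed: int,
    n_replicates: int = 1,
) -> dict:
    """Mean recovered (test - reference) shifts of V0.5,act and V0.5,inact.

    Each replicate simulates both cohorts at their published n and subtracts
    the recovered cohort means; with ``n_replicates > 1`` the shifts are
    averaged over seeded replicate pairs.
    """
    iv, ssi, _ = default_protocols()
    act_shifts, inact_shifts = [], []
    for k in range(n_replicates):
        means = []
        for j, row in enumerate((row_ref, row_test)):
            spec = ref.cohort_spec_from_row(
                "cohort", row, n_cells=row.n_act, seed=seed + 10_000 * j + k
            )
            means.append(_cohort_means(spec, [iv, ssi], ["v_half_act", "v_half_inact"]))
        act_shifts.append(means[1]["v_half_act"]["mean"] - means[0]["v_half_act"]["mean"])
        inact_shifts.append(means[1]["v_half_inact"]["mean"] - means[0]["v_half_inact"]["mean"])
    return {
        "act_shift": float(np.mean(act_shifts)),
        "inact_shift": float(np.mean(inact_shifts)),
        "n": int(row_ref.n_act + row_test.n_act),
    }
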