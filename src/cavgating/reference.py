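"""Published per-construct gating parameters used to seed synthetic cohorts.

These are the mean +/- SEM rows of the Cav1.3 splice-variant / mutant
characterisation (activation and inactivation Boltzmann parameters, and the
5-s inactivation r-values).  They serve as ground-truth inputs for the
cohort generator: the between-cell SD is reconstructed as SEM * sqrt(n),
which reproduces the dispersion the printed SEMs imply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CellVariability, CohortSpec
from .model import ActivationParams, ChannelParams, InactivationParams, PassiveParams
from .protocols import LJP_DEFAULT, default_protocols

__all__ = [
    "GatingRow",
    "KineticsRow",
    "TABLE_GATING_8B8A",
    "TABLE_GATING_S652L",
    "TABLE_GATING_R498L",
    "TABLE_KINETICS_R498L",
    "GATING_TABLES",
    "peak_scaled_g_max",
    "channel_params_from_row",
    "cohort_spec_from_row",
]

TARGET_PEAK_PA = 400.0  # mid QC window; typical design peak amplitude
G_MAX_SIGMA_DEFAULT = 0.3


@dataclass(frozen=True)
class GatingRow:
    """One construct's activation + inactivation summary (mean, SEM, n)."""

    v_half_act: float
    v_half_act_sem: float
    slope_act: float
    slope_act_sem: float
    v_rev: float
    v_rev_sem: float
    n_act: int
    v_half_inact: float
    v_half_inact_sem: float
    slope_inact: float
    slope_inact_sem: float
    non_inactivating_pct: float
    non_inactivating_pct_sem: float
    n_inact: int


@dataclass(frozen=True)
class KineticsRow:
    """One construct's r-value summary (percent remaining, mean, SEM, n)."""

    r: tuple  # (r50, r100, r250, r500, r1000, r5000)
    sem: tuple
    n: int


# Short C-terminal (43S) splice variants, exon 8b / 8a backbones.
TABLE_GATING_8B8A = {
    "8b 43S": GatingRow(-10.21, 0.62, 8.51, 0.17, 65.70, 0.88, 25, -35.71, 0.83, 5.52, 0.20, 17.84, 1.98, 22),
    "8b 11 43S": GatingRow(-13.40, 0.63, 7.60, 0.15, 64.75, 0.72, 29, -39.94, 0.97, 4.94, 0.19, 10.82, 0.78, 21),
    "8b 32 43S": GatingRow(-13.58, 0.55, 8.36, 0.15, 63.21, 0.84, 16, -41.53, 1.08, 5.21, 0.25, 13.74, 2.23, 12),
    "8b 11 32 43S": GatingRow(-12.79, 0.58, 8.33, 0.12, 65.23, 0.91, 19, -39.54, 1.00, 4.90, 0.16, 10.80, 1.19, 17),
    "8a 43S": GatingRow(-10.99, 0.63, 8.28, 0.16, 65.67, 0.92, 24, -34.79, 0.90, 4.67, 0.19, 10.65, 0.87, 15),
    "8a 11 43S": GatingRow(-13.21, 0.63, 7.60, 0.14, 63.75, 0.91, 19, -37.99, 1.31, 4.43, 0.18, 14.23, 2.43, 10),
    "8a 32 43S": GatingRow(-13.03, 0.47, 7.97, 0.13, 63.80, 0.64, 16, -38.82, 0.92, 5.04, 0.19, 12.04, 1.28, 13),
    "8a 11 32 43S": GatingRow(-12.65, 0.76, 8.23, 0.16, 64.58, 0.81, 17, -37.15, 1.36, 4.91, 0.10, 15.36, 2.14, 13),
}

# Wild-type vs the S652L disease variant on the exon-11 short backbone.
TABLE_GATING_S652L = {
    "8b 11 43S": TABLE_GATING_8B8A["8b 11 43S"],
    "S652L 8b 11 43S": GatingRow(-25.50, 0.74, 7.61, 0.14, 58.26, 0.71, 18, -58.92, 0.77, 4.93, 0.24, 7.57, 1.37, 13),
}

# C-terminally long (42) constructs around the R498L variant.
TABLE_GATING_R498L = {
    "8a 42": GatingRow(0.45, 0.90, 9.51, 0.15, 66.56, 0.86, 44, -17.35, 0.76, 6.02, 0.18, 19.56, 1.25, 33),
    "8a 11 42": GatingRow(-1.31, 0.88, 9.32, 0.20, 63.75, 0.97, 25, -17.63, 0.81, 6.01, 0.30, 15.94, 1.76, 17),
    "R498L 8a 11 42": GatingRow(0.04, 1.03, 9.28, 0.11, 66.14, 1.04, 30, -16.48, 0.88, 6.03, 0.37, 17.79, 1.62, 23),
}

TABLE_KINETICS_R498L = {
    "8a 42": KineticsRow((69.41, 57.47, 39.14, 26.48, 17.72, 8.05), (2.54, 2.65, 2.35, 1.94, 1.56, 0.94), 28),
    "8a 11 42": KineticsRow((72.97, 61.20, 40.67, 25.87, 15.61, 6.47), (3.29, 3.12, 2.69, 2.13, 1.80, 1.25), 13),
    "R498L 8a 11 42": KineticsRow((70.66, 60.22, 42.17, 27.64, 16.67, 6.90), (2.88, 3.00, 2.93, 2.46, 1.72, 0.84), 22),
}

GATING_TABLES = {
    "splice_43S": TABLE_GATING_8B8A,
    "S652L": TABLE_GATING_S652L,
    "R498L": TABLE_GATING_R498L,
}


def peak_scaled_g_max(
    v_half: float,
    slope: float,
    v_rev: float,
    target_peak_pa: float = TARGET_PEAK_PA,
    ljp: float = LJP_DEFAULT,
) -> float:
    """g_max (nS) giving a quasi-steady peak of ``target_peak_pa`` on the IV grid."""
    iv = default_protocols()[0]
    v = np.array(iv.step_voltages()) + ljp
    drive = (v - v_rev) / (1.0 + np.exp(-(v - v_half) / slope))
    return target_peak_pa / float(np.max(np.abs(drive)))


def channel_params_from_row(
    row: GatingRow,
    *,
    g_max: float | None = None,
    tau_act: float = 0.5,
    tau_fast: float = 80.0,
    tau_slow: float = 1000.0,
    frac_fast: float = 0.55,
    passive: PassiveParams | None = None,
) -> ChannelParams:
    """Mean ChannelParams for a table row.

    The printed tables constrain the steady-state gating; the kinetic time
    constants are simulator conventions (see docs/methods.md) unless a
    kinetics row is fitted separately.
    """
    if g_max is None:
        g_max = peak_scaled_g_max(row.v_half_act, row.slope_act, row.v_rev)
    act = ActivationParams(v_half=row.v_half_act, slope=row.slope_act, g_max=g_max,
                           v_rev=row.v_rev, tau_act=tau_act)
    inact = InactivationParams(v_half=row.v_half_inact, slope=row.slope_inact,
                               plateau=row.non_inactivating_pct / 100.0,
                               tau_fast=tau_fast, tau_slow=tau_slow, frac_fast=frac_fast)
    return ChannelParams(act=act, inact=inact, passive=passive or PassiveParams())


def cohort_spec_from_row(
    construct: str,
    row: GatingRow,
    *,
    n_cells: int | None = None,
    seed: int = 0,
    g_max_sigma: float = G_MAX_SIGMA_DEFAULT,
    qc_outlier_fraction: float = 0.0,
    **params_kwargs,
) -> CohortSpec:
    """CohortSpec emulating a printed table row (SD = SEM * sqrt(n) convention)."""
    if n_cells is None:
        n_cells = row.n_act
    variability = CellVariability(
        v_half_act_sd=row.v_half_act_sem * np.sqrt(row.n_act),
        slope_act_sd=row.slope_act_sem * np.sqrt(row.n_act),
        v_rev_sd=row.v_rev_sem * np.sqrt(row.n_act),
        v_half_inact_sd=row.v_half_inact_sem * np.sqrt(row.n_inact),
        slope_inact_sd=row.slope_inact_sem * np.sqrt(row.n_inact),
        plateau_sd=row.non_inactivating_pct_sem * np.sqrt(row.n_inact) / 100.0,
        g_max_sigma=g_max_sigma,
    )
    return CohortSpec(
        construct=construct,
        n_cells=n_cells,
        mean_params=channel_params_from_row(row, **params_kwargs),
        variability=variability,
        seed=seed,
        qc_outlier_fraction=qc_outlier_fraction,
    )
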