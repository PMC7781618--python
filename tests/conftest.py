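"""Shared fixtures: reference parameter sets and idealised variants.

"Idealised" parameter sets make the simulator's peak table satisfy the
peak I-V equation to machine precision (quasi-instantaneous activation,
frozen or absent inactivation, no noise/leak, fast capacitive decay); they
are the analytic oracles for the fitting chain.
"""

from dataclasses import replace

import pytest

from cavgating import ChannelParams, PassiveParams
from cavgating import reference as ref


QUIET = dict(noise_sd=0.0, g_leak=0.0, tau_cap=0.01)


def quiet_passive(**kwargs) -> PassiveParams:
    return PassiveParams(**{**QUIET, **kwargs})


def idealize(params: ChannelParams, freeze_inactivation: bool = True) -> ChannelParams:
    """Quasi-instantaneous activation; optionally no inactivation at all
    (plateau = 1 makes availability identically 1, so the peak table obeys
    the peak I-V equation exactly)."""
    act = replace(params.act, tau_act=0.01)
    inact = params.inact
    if freeze_inactivation:
        inact = replace(inact, plateau=1.0)
    passive = replace(params.passive, **QUIET)
    return ChannelParams(act=act, inact=inact, passive=passive)


@pytest.fixture(scope="session")
def row_8b43s() -> ref.GatingRow:
    return ref.TABLE_GATING_8B8A["8b 43S"]


@pytest.fixture(scope="session")
def row_8b11_43s() -> ref.GatingRow:
    return ref.TABLE_GATING_8B8A["8b 11 43S"]


@pytest.fixture(scope="session")
def params_8b43s(row_8b43s) -> ChannelParams:
    return ref.channel_params_from_row(row_8b43s)


@pytest.fixture(scope="session")
def ideal_8b43s(params_8b43s) -> ChannelParams:
    return idealize(params_8b43s)
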