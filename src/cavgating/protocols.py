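"""Voltage-clamp protocol definitions.

Protocols are declared in *nominal* (amplifier command) voltages; the
recording pipeline applies the liquid-junction-potential correction once, at
preprocessing, so all reported voltages are on the corrected scale.  With the
default LJP of -9.3 mV the nominal -80 mV holding potential corresponds to
the -89 mV reported for these recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VoltageProtocol", "default_protocols", "LJP_DEFAULT"]

LJP_DEFAULT = -9.3  # mV, liquid junction potential correction

# sweep timing bookkeeping (ms)
IV_PRE_MS = 10.0
IV_POST_MS = 5.0
SSI_PULSE_MS = 20.0
SSI_GAP_MS = 500.0
INACT_PRE_MS = 10.0
INACT_POST_MS = 10.0
LEAK_REF_PRE_MS = 10.0
LEAK_REF_STEP_MS = 50.0
LEAK_REF_POST_MS = 10.0
LEAK_REF_FROM_MV = -80.0
LEAK_REF_TO_MV = -90.0


@dataclass(frozen=True)
class VoltageProtocol:
    """Declarative description of a sweep sequence (nominal voltages, mV).

    kind : 'IV' (peak current-voltage family), 'SSI' (steady-state
        inactivation with a long conditioning step) or 'INACT5S'
        (single long depolarisation for inactivation kinetics).
    holding_potential : nominal holding potential between/around steps.
    step_increment : spacing of test (IV) or conditioning (SSI) voltages.
    step_duration : duration of the test pulse (ms).
    voltage_range : (min, max) nominal test/conditioning voltages, inclusive.
    conditioning_duration : SSI conditioning-step length (ms); SSI only.
    intersweep_interval : seconds between sweeps (metadata only; no rundown
        is modelled).
    """

    kind: str
    holding_potential: float = -80.0
    step_increment: float = 5.0
    step_duration: float = 20.0
    voltage_range: tuple[float, float] = (-80.0, 80.0)
    conditioning_duration: float | None = None
    intersweep_interval: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("IV", "SSI", "INACT5S"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.step_increment <= 0:
            raise ValueError("step_increment must be > 0")
        lo, hi = self.voltage_range
        if not lo < hi:
            raise ValueError("voltage_range must satisfy min < max")
        if self.kind == "SSI" and not (self.conditioning_duration and self.conditioning_duration > 0):
            raise ValueError("SSI protocol requires conditioning_duration > 0")

    def step_voltages(self) -> list[float]:
        """Nominal test (IV) / conditioning (SSI) voltages of the sweep family."""
        lo, hi = self.voltage_range
        out = []
        v = lo
        k = 0
        while v <= hi + 1e-9:
            out.append(round(v, 6))
            k += 1
            v = lo + k * self.step_increment
        return out


def default_protocols(iv_step_ms: float = 20.0) -> tuple[VoltageProtocol, VoltageProtocol, VoltageProtocol]:
    """The three standard protocols (IV, SSI, INACT5S) in nominal voltages.

    After the -9.3 mV junction correction these correspond to: IV from a
    -89 mV holding potential, 5 mV increments spanning -89 to +71 mV,
    20 ms steps (50 ms selectable via ``iv_step_ms``); SSI with 5-s
    conditioning steps, -119 to +1 mV in 10 mV increments, flanked by 20-ms
    control/test pulses to V_max; INACT5S, a single 5-s depolarisation to
    V_max.
    """
    iv = VoltageProtocol(kind="IV", step_duration=iv_step_ms)
    ssi = VoltageProtocol(
        kind="SSI",
        step_increment=10.0,
        step_duration=SSI_PULSE_MS,
        voltage_range=(-110.0, 10.0),
        conditioning_duration=5000.0,
    )
    inact = VoltageProtocol(kind="INACT5S", step_duration=5000.0, voltage_range=(-80.0, 80.0))
    return iv, ssi, inact
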