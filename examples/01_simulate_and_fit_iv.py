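"""Simulate one virtual cell's I-V family and fit its activation gating.

Builds a cell from the published 8b-43S reference parameters, runs the
20-ms step protocol (holding -89 mV after junction correction, 5 mV
increments, 5 pA noise, 1 nS ohmic leak), leak-subtracts offline, extracts
peak currents and fits the peak I-V equation plus the G-V Boltzmann.
"""

from cavgating import AnalysisOptions, analyze_recordings, default_protocols, reference, simulate_cohort
from cavgating.cohort import CellVariability, CohortSpec

row = reference.TABLE_GATING_8B8A["8b 43S"]
params = reference.channel_params_from_row(row)
spec = CohortSpec("8b 43S", 1, params, CellVariability(c_m_sd=0.0), seed=42)

iv_protocol = default_protocols()[0]
recordings = simulate_cohort(spec, [iv_protocol])
result = analyze_recordings(recordings, AnalysisOptions()).iloc[0]

print(f"QC: {result.qc_status} (peak {result.peak_at_v_max_pa:.0f} pA at {result.v_max:.1f} mV)")
print(f"fitted V0.5,act = {result.v_half_act:6.2f} mV   (generating value {row.v_half_act})")
print(f"fitted slope k  = {result.slope_act:6.2f} mV   (generating value {row.slope_act})")
print(f"fitted V_rev    = {result.v_rev:6.2f} mV   (generating value {row.v_rev})")
print()
print("V0.5,act is the voltage of half-maximal conductance; k sets how many")
print("mV are needed for an e-fold change; V_rev is the extrapolated zero-")
print("current potential of the ohmic driving force. Differences from the")
print("generating values reflect the 5 pA recording noise only.")
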