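"""Pace a single human ventricular myocyte and read off its phenotype.

Runs the baseline epicardial cell at 1 Hz until it reaches steady
state, then extracts the standard action-potential and Ca2+-transient
features from the final beat.
"""

from cardioreg import baseline_parameters, ProtocolSpec, run_protocol
from cardioreg.features import action_potential_features, calcium_features

params = baseline_parameters("tnnp")
spec = ProtocolSpec(protocol_id="paced", bcl=1000.0, n_beats=40,
                    stim_amplitude=52.0)
trace = run_protocol("tnnp", params, spec)

ap = action_potential_features(trace, 39)
ca = calcium_features(trace, 39)

print(f"resting potential : {ap['V_rest']:8.1f} mV")
print(f"peak voltage      : {ap['V_peak']:8.1f} mV")
print(f"max upstroke      : {ap['dVdt_max']:8.0f} mV/ms")
print(f"APD90             : {ap['APD']:8.1f} ms")
print(f"notch / dome      : {ap['V_maxmin']:6.1f} / {ap['V_minmax']:.1f} mV")
print(f"Ca amplitude      : {ca['dCa'] * 1e3:8.2f} uM")
print(f"Ca decay constant : {ca['Ca_decay']:8.0f} ms")
print()
print("These are the per-trial outputs that, measured across a randomized")
print("population, let the regression stages constrain the conductances.")
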