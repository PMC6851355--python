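"""Quantify tonic inhibitory currents from holding-current shifts.

Simulates the sequential-antagonist experiment (control → strychnine →
strychnine+bicuculline at a 0 mV hold) and reads the glycine- and
GABA-mediated tonic currents from all-points-histogram holding-current
estimates of each drug epoch.
"""
from spinaltone import estimate_holding_current
from spinaltone.synth import gen_vc_sequence, get_preset

params = get_preset("study_vc_ipsc")
trace, truth, _ = gen_vc_sequence(
    params,
    [
        ("control", 60.0, []),
        ("strychnine", 60.0, ["strychnine"]),
        ("strychnine+bicuculline", 60.0, ["strychnine", "bicuculline"]),
    ],
    seed=11,
)

h = {
    name: estimate_holding_current(trace, (start + 2.0, end - 2.0))
    for name, start, end in [
        ("control", 0.0, 60.0),
        ("strychnine", 60.0, 120.0),
        ("both", 120.0, 180.0),
    ]
}
tonic_gly = h["control"] - h["strychnine"]
tonic_gaba = h["strychnine"] - h["both"]
print(f"holding current, control epoch:        {h['control']:7.2f} pA")
print(f"holding current, + strychnine:         {h['strychnine']:7.2f} pA")
print(f"holding current, + bicuculline:        {h['both']:7.2f} pA")
print(f"glycine-mediated tonic current:        {tonic_gly:7.2f} pA (planted 10.25)")
print(f"GABA-mediated tonic current:           {tonic_gaba:7.2f} pA (planted 22.50)")
print("each antagonist removes the standing outward chloride current its "
      "receptor class carries at the 0 mV hold")
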