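"""Excitability before and after blocking the tonic inhibitory conductance.

The LIF cell preset is derived in closed form from the reported group
means.  Removing its tonic conductance (what strychnine + bicuculline do)
lowers the rheobase by the tonic current at threshold voltage and raises
the input resistance ~3-fold.
"""
from spinaltone import find_rheobase, measure_input_resistance, measure_resting_potential
from spinaltone.synth import gen_cc_response, get_preset

cell = get_preset("study_cell")
blocked = cell.without_tonic()

for name, c in [("control", cell), ("antagonists", blocked)]:
    rheo = find_rheobase(c, sample_rate=5000.0)
    resp, _ = gen_cc_response(c, [(-5.0, 500.0, 0.0)], sample_rate=5000.0)
    rin = measure_input_resistance(resp)
    rest, _ = gen_cc_response(c, [(0.0, 500.0, 0.0)], sample_rate=5000.0)
    vrest = measure_resting_potential(rest, (0.1, rest.duration))
    print(f"{name:12s} rheobase {rheo:5.1f} pA | "
          f"R_in {rin:7.1f} MOhm | V_rest {vrest:7.2f} mV")

shift = cell.tonic_current_pa(cell.v_th_mv)
print(f"rheobase drop {find_rheobase(cell, sample_rate=5000.0) - find_rheobase(blocked, sample_rate=5000.0):.0f} pA "
      f"~= tonic current at threshold ({shift:.1f} pA): the tonic chloride "
      f"conductance is what holds the cell below threshold")
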