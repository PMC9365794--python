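"""Passive membrane properties and capacitance-normalized I–V curves.

Estimates whole-cell capacitance from a membrane-test transient (charge
integration, cross-checked by a mono-exponential fit), input conductance
from the −70/−50 mV steady-state currents, and Na / fast-K / slow-K
current densities from a −90…+80 mV step family.
"""

import synaptoprobe as sp

mem, _ = sp.gen_membrane_test(capacitance=25.0, resistance=600.0,
                              noise_sd=2.0, n_sweeps=5, seed=3)
passive = sp.estimate_capacitance(mem)
print(f"capacitance {passive.capacitance:.1f} pF by charge integration "
      f"({passive.capacitance_expfit:.1f} pF by tau/R fit, "
      f"discrepancy {100 * passive.fit_discrepancy:.1f}%)")

iv_rec, _ = sp.gen_voltage_clamp_iv(capacitance=25.0, noise_sd=5.0, seed=3)
g_in = sp.input_conductance_from_iv(iv_rec)
print(f"input conductance {g_in:.2f} nS from the -70/-50 mV steps")

iv = sp.extract_iv_curves(iv_rec, passive.capacitance)
for v in (-30.0, -20.0, -10.0):
    print(f"  {v:+5.0f} mV: Na {sp.density_at_voltage(iv, v, 'na'):7.1f}  "
          f"Kfast {sp.density_at_voltage(iv, v, 'kfast'):6.1f}  "
          f"Kslow {sp.density_at_voltage(iv, v, 'kslow'):6.1f}  pA/pF")
# Na peak = most negative early current; fast K = early outward maximum;
# slow K = late-window mean; all baseline-subtracted and divided by C.
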