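"""Strength-duration and frequency-threshold curves.

Computes detection thresholds for a standard electrode while varying pulse
width (at 50 Hz) and frequency (at 0.25 ms phases), reproducing the shape
of classic chronaxie-style threshold curves for cortical stimulation.
"""

import numpy as np

from cortisim import run_strength_duration

pws = [0.1, 0.2, 0.4, 0.8, 1.6]
fs = [16, 32, 64, 128, 256]
tab = run_strength_duration(s=0.43, pulse_widths=pws, frequencies=fs)

print("threshold vs pulse width (50 Hz, 0.5 s train):")
pw_tab = tab[tab.variable == "pulse_width"]
for r in pw_tab.itertuples():
    print(f"  pw {r.value:4.1f} ms : {r.threshold_uA:7.2f} uA   "
          f"charge/phase {1000 * r.charge_uC_per_phase:6.3f} uA*ms")
qmin = pw_tab.loc[pw_tab.charge_uC_per_phase.idxmin()]
print(f"  -> charge per phase is minimal near pw = {qmin.value} ms;")
print("     longer pulses lower the amplitude threshold but cost charge.")
print()
print("threshold vs frequency (0.25 ms phases, 0.5 s train):")
f_tab = tab[tab.variable == "frequency"]
th = f_tab.threshold_uA.to_numpy()
for r, sav in zip(f_tab.itertuples(),
                  np.concatenate([[np.nan], 1 - th[1:] / th[:-1]])):
    note = "" if np.isnan(sav) else f"  (saving {100 * sav:.0f}% vs half rate)"
    print(f"  {r.value:5.0f} Hz : {r.threshold_uA:7.2f} uA{note}")
print("  -> the relative saving per doubling shrinks with frequency:")
print("     little efficiency benefit above ~64 Hz.")
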