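"""From a pulse train to perceived brightness over time.

Builds the classic demonstration stimulus — a cathodic-first train with
2 ms phases at 75 Hz lasting 50 ms — and runs the four-stage temporal
cascade: fast leaky integration of current, spike-strength extraction with
refractory attenuation, slow gamma-kernel integration, and compressive
mapping onto a 0-10 brightness rating scale.
"""

import numpy as np

from cortisim import PulseTrain, TemporalParams, simulate_temporal

train = PulseTrain(amplitude=30.0, pulse_width=2.0, frequency=75.0,
                   train_duration=0.05)
params = TemporalParams()
res = simulate_temporal(train, params)

print(f"pulses delivered        : {train.n_pulses}")
print(f"charge per phase        : {train.charge_per_phase:.1f} uA*ms")
print(f"spike events            : {res.events.times.size}")
print(f"refractory-attenuated   : strengths "
      f"{np.round(res.events.strengths, 3)}")
ipk = int(np.argmax(res.brightness.value))
print(f"peak brightness         : {res.max_brightness:.2f} rating units "
      f"at t = {res.brightness.time[ipk]:.0f} ms")
print()
print("The brightness peak arrives well after the 50 ms train ends: the")
print("slow integration stage (tau2 = 150 ms, 3 cascades) smears the rapid")
print("spiking response into a percept that builds up and decays over")
print("hundreds of milliseconds. Later spikes are weaker than the first")
print("because the 75 Hz inter-spike interval attenuates them (refractory")
print("factor ~0.73 at 13.3 ms intervals).")
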