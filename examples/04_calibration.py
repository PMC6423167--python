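"""Automatic calibration: map a dimensionless model onto a living neuron.

The Rulkov map produces bursts of ~50 dimensionless points in a [-1.3, 1.3]
range. Calibration stretches one burst to 1 s at a 10 kHz acquisition rate
(here ~150 interpolated output samples per map point) and maps the voltage
affinely into the living cell's observed range.
"""

import numpy as np

from hybridclamp import calibrate_model, detect_bursts, from_preset
from hybridclamp.experiment_runner import _ModelStepper

fs, live_range, target = 10000.0, (-62.0, -30.0), 1.0
model = from_preset("rulkov_burster")
calib = calibrate_model(model, live_range, target, fs)

print(f"native range   ({calib.character.v_min:.2f}, {calib.character.v_max:.2f})")
print(f"native burst   {calib.character.burst_duration:.0f} map points "
      f"(period {calib.character.burst_period:.0f})")
print(f"amplitude map  gain {calib.amplitude.gain:.2f} mV/unit, "
      f"offset {calib.amplitude.offset:.2f} mV")
print(f"time scale     {calib.time_scale:.1f} output samples per map point")

stepper = _ModelStepper(model, calib)
v = np.array([stepper.step(0.0) for _ in range(int(10 * fs))])
bursts = detect_bursts(v, fs, min_gap=0.5 * target)
durs = [b.duration for b in bursts[:-1]]
print(f"calibrated free run: {len(bursts)} bursts, median duration "
      f"{np.median(durs):.3f} s (target {target:g} s), "
      f"range ({v.min():.2f}, {v.max():.2f}) mV")
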