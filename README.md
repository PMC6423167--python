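# hybridclamp

Desk-scale dynamic-clamp simulation of **hybrid neural circuits** — model
neurons and synapses coupled in closed loop to a living (here: emulated)
neuron — with the periodic-loop scheduling, latency accounting and
automatic calibration machinery of a real-time electrophysiology rig,
abstracted over a deterministic virtual clock.

In a dynamic-clamp experiment the rig samples a cell's membrane potential
every `1/fs` seconds (10–20 kHz), computes model and synapse equations,
and injects the resulting current back into the cell before the next
deadline. `hybridclamp` reproduces that machinery in plain Python so the
algorithms — not the RTOS — can be developed, tested and taught at a desk:

* **Neuron model library** — the Rulkov two-dimensional spiking–bursting
  map, the Izhikevich quadratic model with reset, the Hindmarsh–Rose
  burster, and two conductance-based models with exponential
  nonlinearities (a three-variable Morris–Lecar-type burster with a slow
  potassium current, and a sodium/potassium interneuron model with
  persistent sodium and slow adaptation). All stock presets burst out of
  the box; expensive nonlinearities can be tabulated.
* **Synapse library** — electrical (gap junction), spike-triggered
  chemical kinetics, and graded synapses (fast instantaneous and slow
  kinetic, `dm/dt = k1 (1−m) a(V_pre) − k2 m`), with thresholds and slopes
  expressed as percentages of the presynaptic amplitude range.
* **Integrators** — Euler, Heun, classic RK4 and an embedded 6(5)
  Runge–Kutta pair with PI step control, plus automatic sub-step selection
  per acquisition interval.
* **Automatic calibration** — hysteresis burst detection, two-point affine
  amplitude mapping, burst-duration time-scale matching (ODE sub-stepping
  or map-output interpolation with an exact phase accumulator), and
  baseline-drift compensation from windowed minima.
* **Real-time loop engine** — anchored-deadline scheduling
  (`deadline_k = t0 + k/fs`, never re-based), per-operation timing,
  latency/jitter statistics, overrun recovery by borrowing from the next
  interval, and a non-blocking writer channel. A scripted virtual clock
  makes all of it exactly testable; a wall clock gives best-effort soft
  real-time.
* **Virtual preparation** — a calibrated Hindmarsh–Rose "living" cell
  bursting at ~1 Hz in a physiological millivolt range with seeded noise
  and drift, plus DAQ scaling conventions (input ×100 to mV, output
  10 nA/V). Recorded two-column traces can be replayed in its place.
* **Experiment runner** — the control–coupled–control protocol with
  bidirectional graded inhibitory synapses, XML experiment configuration
  (schema included), CSV/log outputs, and a burst-onset circular-phase
  antiphase index.

## Worked example

`examples/05_hybrid_circuit.py` couples a Hindmarsh–Rose model to the
virtual preparation at 10 kHz (10 s pre-control, 30 s coupled, 5 s
post-control) through a slow inhibitory graded synapse (g = 0.1 µS,
k1 = 14, k2 = 4, threshold 15%/slope 1% of the presynaptic range) toward
the living cell and a fast inhibitory graded synapse (g = 1.0 µS,
50%/5%) back:

```
calibration: live range (-63.71, -28.85) mV, live burst duration 0.386 s (11 bursts), target 0.386 s
calibration: model range (-1.434, 1.813), native burst 53.680, time scale 0.0138941 (model-time/interval)
coupled phase: latency n=300000  min=0.000us  max=0.000us  ...  failures(>100us)=0
antiphase index: 0.415 (circular dispersion 0.012)
peak synaptic currents: model->live 3.97 nA, live->model 37.19 nA (exactly 0 in both control phases)
```

The calibration lines show the automatic adaptation: the model's
dimensionless burst (53.7 native time units, range −1.4…1.8) is stretched
and mapped so one burst spans the living cell's 0.386 s burst inside its
−63.7…−28.9 mV range. The antiphase index is the circular median phase of
model burst onsets within the live burst cycle: 0.5 is perfect
alternation, and 0.415 with dispersion 0.012 is a tight antiphase
half-center rhythm. On the virtual clock every one of the 450,000 loop
intervals meets its 100 µs deadline exactly.

The other examples free-run every stock model (`01`), run the 20 kHz
toggle latency benchmark on virtual and wall clocks (`02`), demonstrate
overrun recovery on the anchored schedule (`03`), and walk through
calibration of the Rulkov map (`04`).

A thin CLI wraps the same functions:

```
hybridclamp run examples/configs/rulkov_hybrid.xml --seed 1
hybridclamp benchmark --fs 20000 --duration 5 --clock wall
hybridclamp freerun izhikevich_burster
hybridclamp calibrate examples/configs/izhikevich_hybrid.xml
```

Exit codes distinguish configuration (2), calibration (3) and runtime (4)
failures.

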