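# Methods

This note documents the models, algorithms and design choices behind
`hybridclamp`: what is simulated, under which assumptions, and what the
passing tests do and do not show about a wet-lab rig.

## The closed loop

A dynamic-clamp rig is a periodic loop at sampling frequency `fs`
(10–20 kHz here): each interval it acquires the living cell's membrane
potential, computes synapse and neuron models, commands a current, hands a
record to a non-real-time writer, and sleeps until the next deadline.
Deadlines form the fixed arithmetic sequence `t0 + k/fs` and are *never
re-based*: if an iteration finishes late, the next one wakes immediately
with its sleep shortened (or skipped, across multi-period overruns, with
every iteration index still executed so data cadence is preserved) until
the loop catches back up. Latency is the wake time minus the scheduled
time; jitter is max − min latency; a latency above one period is a
real-time failure.

All of this is expressed against a `ClockSource`. The **virtual clock** is
a simulated time line: task durations are scripted (constants,
per-iteration overrides, or seeded exponential jitter), so scheduling
semantics — including the 140 µs-overrun-in-a-100 µs-schedule recovery
pattern — are testable exactly and reproducibly. The **wall clock** uses
`time.perf_counter` with a sleep-then-spin wait; on a general-purpose OS
this is soft real-time only, so wall-clock tests assert that statistics
are produced, never that a bound holds. Nothing here emulates an RTOS
scheduler; the virtual clock verifies the *logic* of the loop, not the
ability of any OS to honor it.

Per-interval records are stored columnar (numpy arrays), so multi-million
interval runs are cheap; `IntervalRecord` objects are materialized on
demand. The writer channel is a deque-backed FIFO with amortized-O(1)
non-blocking `put` — single-threaded here, standing for the real rig's
inter-process message queue; the contract (FIFO, lossless across orderly
shutdown) is what the tests pin down.

## Neuron models

The model zoo spans the computational cost spectrum. Equations for the map
and the two reduced ODE models are the canonical published forms; the two
conductance-based models are this package's own parameterizations (see
below). Every stock preset must free-run in a square-wave bursting regime
— that is a tested invariant, not an aspiration — and presets live in
`presets/neurons.yaml` so tests and experiments reference names, not magic
numbers.

* **Rulkov map** (dimensionless, one state update per map point):
  fast map `x' = α/(1−x) + y_eff` for `x ≤ 0`; `x' = α + y_eff` while
  `0 < x < α + y_eff` and the previous `x ≤ 0`; else `x' = −1`; slow map
  `y' = y − μ(x+1) + μσ`, with external drive entering `y_eff = y + I`.
  Stock regime α = 4.5, σ = 0.005, μ = 0.001: bursts of ~3 spikes spanning
  ~51 points with a ~170-point period (duty 0.30). μ = 0 is accepted (the
  slow variable freezes); negative μ is rejected.
* **Izhikevich**: `v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)`,
  reset `v ≥ 30 → v = c, u += d` with the boundary inclusive (deterministic
  tie-break). Stock chattering/bursting set a = 0.02, b = 0.2, c = −50,
  d = 2, I = 15 (duty 0.40). Time in ms.
* **Hindmarsh–Rose**: `x' = y + bx² − x³ − z + I`, `y' = 1 − 5x² − y`,
  `z' = r(s(x − x_rest) − z)`. Stock square-wave set b = 3, I = 2.7,
  r = 0.005, s = 4, x_rest = −1.6 (duty 0.38). Also the intrinsic model of
  the virtual preparation.
* **Conductance models** (mV/ms/µA/cm², Boltzmann steady states
  `1/(1+exp(−(v−half)/slope))`):
  * *ghigliazza_holmes* variant — a three-variable burster with
    instantaneous calcium activation, a fast potassium gate n
    (τ = 4 ms) and a slow potassium gate s (τ = 1.5 s). The fast (v, n)
    subsystem was placed by direct bifurcation probing in a regime with a
    stable rest state coexisting with a spiking limit cycle
    (bistability window I_eff ≈ 39–40 µA/cm² at the stock conductances);
    the slow current `g_KS·s·(v−E_K)` sweeps the effective drive across
    that window, yielding square-wave bursting (duty ≈ 0.3–0.4).
  * *wang* variant — sodium/potassium spiking with the classic
    exponential rate functions (m instantaneous, h and n with φ = 5) plus
    a persistent sodium current (instantaneous Boltzmann activation,
    half −51 mV) and a slow adaptation potassium current
    (τ = 250 ms). The persistent sodium supplies the fast-subsystem
    bistability that pure sodium/potassium interneuron dynamics lack
    (they are Type 1 / tonic); adaptation terminates the burst. This is a
    standard square-wave bursting mechanism and is this package's design.

  Both conductance presets ship with on-attractor initial states: their
  slow gates approach the attractor over seconds of model time, and a
  characterization window contaminated by that transient reports a wrong
  voltage range. Nonlinearities can be tabulated (uniform-grid linear
  interpolation, clamped outside the domain, node values exact); at 10⁴
  nodes over [−100, 60] mV tables match direct evaluation to better than
  1e−6 and full trajectories to sub-millivolt over a burst.

## Integrators

Euler, Heun and classic RK4 advance tuple states (plain floats — in a
per-interval hot loop tuple arithmetic beats array allocation). The
embedded 6(5) pair uses Verner's 8-stage tableau with a PI step-size
controller; the tableau is data (`EmbeddedTableau`), and the contract —
empirical orders 6/5, error estimate bounding the true one-step error,
adaptive tolerance satisfaction — is what the tests verify, so the
tableau is replaceable.

`select_step` picks the fewest sub-steps per acquisition interval whose
step passes a stability probe: one calibrated burst simulated without
non-finite values, |state| > 1e6, or gating leaving [0, 1] (discrete
resets are applied inside the probe). Candidates are scanned 1…8 then by
doubling; the search runs at setup only, and halving the budget never
yields a larger sub-step.

## Calibration

A dimensionless model and a living neuron differ in amplitude and time
scale; calibration owns both mappings.

* **Burst detection**: hysteresis thresholds at `min + 0.25·range`
  (onset, upward) and `min + 0.15·range` (offset, downward), events closer
  than `min_gap` merged. Thresholds are relative to the trace's own
  extremes unless a `range_hint` pins them — used in the coupled phase,
  where synaptic hyperpolarization would otherwise skew them. Native
  (characterization) `min_gap` is a per-preset hint; for traces calibrated
  to a target duration, free-run analysis merges at 0.5× the target
  (measured across the stock models, intra-burst spike intervals stay
  below ~0.45× the burst duration while interburst gaps exceed ~1×), and
  coupled-phase analysis at 0.75× (bursts lengthen under interaction).
* **Amplitude**: two-point affine map of the model's free-run range onto
  the living range, with exact inverse. The deployed stepper re-fits the
  map at its own (finer) integration resolution over three burst periods,
  padding the observed span by 1% so chaotic burst-to-burst extremes stay
  inside the live range.
* **Time scale**: one model burst is stretched to the target duration —
  ODE models advance `native_burst/(target·fs)` model-time per interval
  (split into probe-approved sub-steps); map models emit
  `r = target·fs/points_per_burst` interpolated samples per map point
  through a phase accumulator whose long-run emission rate is exactly `r`
  (over N points, floor(N·r) or ceil(N·r) samples).
* **Drift**: every `window` samples the window minimum (the burst-trough
  baseline) is recorded; the compensator maintains an EMA baseline and an
  online least-squares trend of those minima, and reports the trend's
  total excursion as the correction. The trend, not the EMA departure, is
  reported because an EMA lags a ramp by `window·(1/α − ½)` and
  systematically under-reports it; the trend is unbiased for linear drift
  and recovers 1 mV/min over 60 s within 10%. Disabled, the correction is
  exactly 0. Compensation acts on the recorded signal only.
* **Online refresh** (off by default): a per-burst tracker can re-match
  the model's burst duration to the live cell's coupled-phase bursts.
  Default off because the protocol's reference is the *uncoupled*
  activity, and closed-loop re-matching couples the two durations into a
  positive feedback loop (longer model bursts beget longer live rebound
  bursts).

## Synapses

Unit discipline is µS × mV → nA throughout, with the dynamic-clamp sign
convention: `I = g·gate·(V_post − E_syn)` is positive when withdrawn from
the postsynaptic cell, and the injected current is its negation.

Graded synapses activate sigmoidally,
`a = 1/(1+exp((V_th − V_pre)/s))`, with threshold and slope given as
percentages of the presynaptic amplitude range and resolved against the
calibrated range — one preset works for any neuron. The slow variant's
gate obeys `dm/dt = k1(1−m)a − k2·m` (k in 1/s), advanced by the exact
exponential update of this linear-in-m ODE so the gate cannot leave
[0, 1] at any step size; its fixed point `k1·a/(k1·a + k2)` anchors the
tests. The fast variant is the instantaneous limit (`gate = a`).

A deferred reversal (`E_syn: null` in a preset) resolves at calibration
time to **30 mV below the observed postsynaptic minimum** — below the
slow-wave trough, as for a potassium-mediated graded inhibitory synapse.
Placing the reversal *at* the observed minimum was tried first and proved
wrong: the driving force then vanishes at the trough, the synapse cannot
shape the postsynaptic interburst, and the half-center degenerates into
weak spike-pulsatile coupling whose 1:1 lock phase is dictated by the
period detuning of the two bursters rather than by mutual inhibition.
With the sub-trough reversal, all four validation wirings lock at
onset-phase 0.42–0.53 with circular dispersion ≤ 0.05 across seeds.

The spike-triggered chemical synapse follows transmitter-pulse kinetics:
a presynaptic spike (upward threshold crossing with refractory hold)
releases `T_max` mM for `pulse_duration` ms, and the open fraction obeys
`ds/dt = αT(1−s) − βs`, advanced exactly. Fast and slow graded synapses
share one kinetic scheme; fast is the instantaneous limit.

## Virtual preparation

The living neuron is emulated — a Hindmarsh–Rose preset calibrated to a
1 s burst *period* (the characteristic pyloric rate) in a configurable
live range (default −62…−30 mV), with additive Gaussian noise on the
output sample (default 0.5 mV), linear drift in mV/min, and injected
current mapped to model drive through the inverse amplitude gain. With
noise and drift at zero the output is the deterministic calibrated model
trace; identical seeds give identical traces sample for sample. DAQ
conventions are explicit and invertible: acquired volts × 100 → mV,
command volts × 10 → nA. A recorded (time, mV) text trace can be replayed
instead (open loop by construction).

What the preparation does *not* emulate: electrode and amplifier
artifacts, seal/access resistance, channel noise (noise is additive on
the sample, not on the state), synaptic depression, and the
duration-regulating homeostasis of real pyloric neurons — its
Hindmarsh–Rose bursts lengthen under post-inhibitory rebound more than a
biological cell's would. Passing the hybrid tests therefore demonstrates
the correctness of the loop, calibration and synapse machinery under
realistic signal conditions, not biological fidelity of the stand-in.

## The hybrid experiment and its validation metric

`run_experiment` executes pre-control (uncoupled; this window *is* the
calibration observation), coupled (both synapses active inside the loop's
fixed operation order: acquisition, drift compensation, synapses, neuron
model, enqueue), and post-control. Control phases carry exactly zero
synaptic current. Both synapses operate in physiological units — the
model voltage is mapped to mV first — and the current injected into the
model is converted to model drive through the inverse amplitude gain.
The model column of the pre-control trace is the calibrated uncoupled
free run (the protocol's "uncoupled dynamics" reference panel). Desk-scale
default durations (10 s controls, 60 s coupled) scale down the canonical
1 + 5 + 1 minute protocol, which remains available by configuration.

Antiphase is quantified on burst onsets: for each live cycle
(onset→next onset) every model onset inside it contributes a phase in
[0, 1); the index is the circular median (0.5 = perfect alternation) with
the circular standard deviation as dispersion. The first 20% of the
coupled phase is discarded as a settling transient. With the stock
presets and the validation synapse parameters, all four wirings (Rulkov,
Izhikevich, Hindmarsh–Rose, and the Morris–Lecar-type burster) lock in
[0.42, 0.53].

## Configuration, outputs, CLI

Experiments round-trip losslessly through a versioned XML dialect
(`schema/experiment.xsd`; nested parameter overrides use dotted names).
Outputs are a per-sample hybrid trace CSV, a per-interval latency CSV,
and a plain-text experiment log recording model/synapse identities,
calibration results and the latency summary. The CLI (`run`, `benchmark`,
`freerun`, `calibrate`) is a thin wrapper over the library with exit
codes 2/3/4 for configuration/calibration/runtime failures.

## Problem sizes

The shipped tests and the acceptance script use desk-scale sizes chosen
to exercise every regime: 10 kHz loops with 60 s coupled phases (600,000
intervals per run) for the hybrid property, a full 3-million-interval
5-minute virtual-clock run for the scheduling arithmetic, 10⁵-step map
oracle comparisons, 10⁶-step gate-boundedness sweeps, and 12 s calibrated
free runs per model. Functional (non-headline) tests run at 2 kHz to keep
the suite fast.

## Known limitations

Hard real-time claims are out of scope by design: the wall clock is
best-effort. The burst detector is amplitude-hysteretic and will label
relative wobble in a suppressed trace as events (suppression tests
therefore compare against free-run thresholds). The Rulkov map's
late-burst spike intervals approach its interburst gap, so its burst
segmentation is sensitive to `min_gap` near that boundary; the stock
regime keeps a ≥20% margin. The drift compensator's trend estimate
assumes drift is slow and monotone on the run's time scale; oscillatory
baselines alias into it.
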