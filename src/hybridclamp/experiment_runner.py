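"""Full hybrid-circuit experiments: control-coupled-control protocol.

An experiment couples a model neuron to the (virtual or replayed) living
neuron through two synapses — conventionally a slow inhibitory graded
synapse from the model onto the living cell and a fast inhibitory graded
synapse in the return direction — and runs three phases on the periodic
loop engine:

1. *pre-control*: both cells free-run uncoupled; the live recording of
   this window drives the automatic calibration (live voltage range, burst
   duration, and — if requested — drift baseline);
2. *coupled*: both synapses active; every loop interval performs, in
   order, the acquisition exchange, drift compensation, synapse models,
   neuron model, and the enqueue to the writer channel;
3. *post-control*: synapses silenced again.

Control phases carry exactly zero synaptic current. The target of the
validation wiring is rhythmic antiphase bursting, quantified by
:func:`antiphase_index` — the circular median of model burst onsets within
the live burst cycle (0.5 = perfect antiphase).

Currents follow the dynamic-clamp sign convention: the synaptic current
``I = g·gate·(V_post - E_syn)`` is an outward membrane current when
positive, so the current *injected* into the postsynaptic cell is ``-I``.
Both synapses operate in physiological units (the model voltage is mapped
to mV first); the current injected into the model is converted to model
drive through the inverse amplitude gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationError,
    DriftCompensator,
    MapInterpolator,
    calibrate_model,
    detect_bursts,
)
from .integrators import IntegratorSpec, integrate_step, select_step
from .neuron_models import ConductanceModel, from_preset
from .rt_engine import (
    DurationModel,
    LoopLog,
    LoopSchedule,
    VirtualClock,
    WriterChannel,
    latency_stats,
    run_loop,
)
from .synapse_models import (
    ChemicalSynapse,
    ElectricalSynapseParams,
    GradedSynapse,
    GradedSynapseParams,
    electrical_current,
    synapse_from_preset,
)
from .virtual_preparation import AcquisitionScaling, ReplayPreparation, VirtualPreparation

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "antiphase_index",
    "ConfigError",
    "VALIDATION_PRESETS",
]


class ConfigError(ValueError):
    """Invalid experiment configuration."""


# The four validation wirings: (neuron preset, model->live synapse preset,
# live->model synapse preset).
VALIDATION_PRESETS = {
    "rulkov": ("rulkov_burster", "slow_inhibitory_graded",
               "fast_inhibitory_graded_rulkov"),
    "izhikevich": ("izhikevich_burster", "slow_inhibitory_graded",
                   "fast_inhibitory_graded"),
    "hindmarsh_rose": ("hindmarsh_rose_burster", "slow_inhibitory_graded_hr",
                       "fast_inhibitory_graded_hr"),
    "ghigliazza_holmes": ("ghigliazza_holmes_burster", "slow_inhibitory_graded",
                          "fast_inhibitory_graded"),
}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one hybrid-circuit run.

    Durations in seconds; the desk-scale defaults (10 s controls, 60 s
    coupled) scale down the canonical 1 min + 5 min + 1 min protocol,
    which remains available by configuration.
    """

    fs: float = 10000.0
    pre_s: float = 10.0
    coupled_s: float = 60.0
    post_s: float = 10.0
    neuron_preset: str = "hindmarsh_rose_burster"
    neuron_overrides: dict = field(default_factory=dict)
    syn_model_to_live: str = "slow_inhibitory_graded"
    syn_model_to_live_overrides: dict = field(default_factory=dict)
    syn_live_to_model: str = "fast_inhibitory_graded"
    syn_live_to_model_overrides: dict = field(default_factory=dict)
    integrator: str = "rk4"
    # calibration
    target_burst: str | float = "auto"   # 'auto' = match the live burst duration
    online_refresh: bool = False         # re-match duration each live burst
    frac_on: float = 0.25
    frac_off: float = 0.15
    min_gap_s: float = 0.1
    drift_compensation: bool = False
    drift_window_s: float = 0.2
    drift_alpha: float = 0.2
    # acquisition scaling
    input_factor: float = 100.0
    nA_per_V: float = 10.0
    # virtual preparation
    prep_preset: str = "hindmarsh_rose_burster"
    prep_period_s: float = 1.0
    prep_range: tuple = (-62.0, -30.0)
    prep_noise_sd: float = 0.5
    prep_drift: float = 0.0
    replay_path: str | None = None
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        for name in ("pre_s", "coupled_s", "post_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.pre_s * self.fs < 2:
            raise ConfigError("pre-control window too short to calibrate")
        if isinstance(self.target_burst, str) and self.target_burst != "auto":
            raise ConfigError("target_burst must be 'auto' or a duration in s")


@dataclass
class ExperimentResult:
    trace: pd.DataFrame              # the HybridTrace
    loop_logs: dict                  # phase -> LoopLog
    log_text: str                    # the plain-text experiment log
    calibration: object              # CalibrationMap of the model
    live_range: tuple
    live_burst_duration: float


# --------------------------------------------------------------------------
# Model stepper: one neuron model advanced per acquisition interval
# --------------------------------------------------------------------------


class _ModelStepper:
    """Advance a calibrated model one acquisition interval at a time.

    ODE models advance ``time_scale`` model-time per interval in the
    sub-steps chosen by the step-selection rule; map models emit
    interpolated samples at ratio r, iterating the map as needed. Output
    is the model voltage mapped to mV; input is the current (nA) injected
    into the model, converted to model drive through the inverse gain.
    """

    def __init__(self, model, calib, method: str = "rk4",
                 observe_periods: float = 3.0):
        self.model = model
        self.calib = calib
        self.amp = calib.amplitude
        if model.kind == "ode":
            self.spec = IntegratorSpec(method=method, dt=model.hints.dt)
            is_stable = (model.gating_in_bounds
                         if isinstance(model, ConductanceModel) else None)
            events = None
            if hasattr(model, "discrete_events"):
                events = lambda y: model.discrete_events(y)[0]  # noqa: E731
            self.n_sub, self.dt_sub = select_step(
                self.spec, lambda t, y: model.derivs(t, y),
                model.initial_state(), calib.time_scale,
                probe_time=calib.character.burst_duration,
                is_stable=is_stable, events=events)
            self._events = events
        else:
            self.interp = MapInterpolator(calib.time_scale)
            self._pending: list[float] = []
        self.state = model.initial_state()
        self.t = 0.0
        self._settle()
        if observe_periods > 0:
            self._refit_amplitude(observe_periods)

    def _refit_amplitude(self, n_periods: float) -> None:
        """Re-fit the amplitude map at deployment resolution.

        The characterization free run uses the model's native step; the
        deployed stepper integrates at the (usually finer) selected
        sub-step, which shifts spike extremes slightly. Observing a few
        burst periods at the deployed resolution and re-fitting the
        two-point map keeps the free-running mapped trace inside the live
        range.
        """
        from .calibration import fit_amplitude_map

        m = self.model
        horizon = n_periods * self.calib.character.burst_period
        lo = hi = self.state[m.v_index]
        if m.kind == "map":
            state = self.state
            for _ in range(int(horizon)):
                state = m.map_step(state)
                v = state[m.v_index]
                if v < lo:
                    lo = v
                elif v > hi:
                    hi = v
            self.state = state
        else:
            for _ in range(int(horizon / self.dt_sub)):
                self._ode_substep(0.0)
                v = self.state[m.v_index]
                if v < lo:
                    lo = v
                elif v > hi:
                    hi = v
        if hi > lo:
            # pad by 1% of the observed span: burst-to-burst (chaotic)
            # variation of spike extremes must not push the mapped trace
            # outside the live range
            pad = 0.01 * (hi - lo)
            self.amp = fit_amplitude_map((lo - pad, hi + pad),
                                         self.calib.live_range)

    def _settle(self) -> None:
        """Run past the native transient so output bursts immediately."""
        m = self.model
        if m.kind == "map":
            n = int(m.hints.transient)
            for _ in range(n):
                self.state = m.map_step(self.state)
        else:
            n = int(m.hints.transient / self.dt_sub)
            for _ in range(n):
                self._ode_substep(0.0)

    def _ode_substep(self, drive: float) -> None:
        self.state, _ = integrate_step(
            self.spec, lambda t, y: self.model.derivs(t, y, drive),
            self.state, self.t, self.dt_sub)
        if self._events is not None:
            self.state = self._events(self.state)
        self.t += self.dt_sub

    def set_target_duration(self, target_s: float, fs: float) -> None:
        """Online time-scale refresh: re-match the model burst duration.

        Living bursts lengthen or shorten during the interaction (e.g. by
        post-inhibitory rebound), so the automatic calibration can re-match
        the model's burst duration each time a live burst completes. Only
        the time scale changes; the selected sub-step count and the
        amplitude map stay fixed (for ODE models the sub-step shrinks or
        grows proportionally, which cannot destabilize the probe-approved
        step when durations lengthen).
        """
        if not target_s > 0:
            raise ValueError("target duration must be positive")
        native = self.calib.character.burst_duration
        if self.model.kind == "ode":
            self.dt_sub = native / (target_s * fs) / self.n_sub
        else:
            self.interp.r = target_s * fs / native

    def step(self, injected_nA: float = 0.0) -> float:
        """One acquisition interval; returns the mapped voltage in mV."""
        drive = injected_nA / self.amp.gain
        if self.model.kind == "ode":
            for _ in range(self.n_sub):
                self._ode_substep(drive)
            return self.amp.to_live(self.state[self.model.v_index])
        while not self._pending:
            self.state = self.model.map_step(self.state, drive)
            self._pending = self.interp.feed(self.state[self.model.v_index])
        return self.amp.to_live(self._pending.pop(0))


class _OnlineDurationTracker:
    """Per-burst live-duration estimate for the online calibration refresh.

    A small hysteresis state machine (thresholds anchored to the
    calibration-window range) completes one measurement per live burst;
    measurements enter an EMA so single odd bursts cannot jerk the model's
    time scale. Bursts shorter than a quarter of the initial estimate are
    ignored as noise blips.
    """

    def __init__(self, live_range: tuple, frac_on: float, frac_off: float,
                 fs: float, init_dur: float, alpha: float = 0.3):
        span = live_range[1] - live_range[0]
        self.th_on = live_range[0] + frac_on * span
        self.th_off = live_range[0] + frac_off * span
        self.fs = fs
        self.ema = init_dur
        self.alpha = alpha
        self.min_dur = 0.25 * init_dur
        self._above = False
        self._onset = 0

    def push(self, k: int, v: float) -> float | None:
        """Feed one sample; returns the refreshed EMA at burst completion."""
        if not self._above:
            if v >= self.th_on:
                self._above = True
                self._onset = k
            return None
        if v < self.th_off:
            self._above = False
            dur = (k - self._onset) / self.fs
            if dur >= self.min_dur:
                self.ema += self.alpha * (dur - self.ema)
                return self.ema
        return None


# --------------------------------------------------------------------------
# Synapse construction
# --------------------------------------------------------------------------


def _build_synapse(preset: str, overrides: dict, pre_range: tuple,
                   post_min: float):
    params = synapse_from_preset(preset, overrides or None)
    if isinstance(params, GradedSynapseParams):
        return GradedSynapse(params, pre_range=pre_range, post_min=post_min)
    if isinstance(params, ElectricalSynapseParams):
        return params  # stateless
    return ChemicalSynapse(params)


def _synapse_current(syn, v_pre: float, v_post: float, t_s: float,
                     dt_s: float) -> float:
    if isinstance(syn, GradedSynapse):
        return syn.step(v_pre, v_post, dt_s)
    if isinstance(syn, ElectricalSynapseParams):
        return -electrical_current(syn, v_pre, v_post)  # as withdrawn-from-post
    # chemical synapse kinetics run in ms
    return syn.step(v_pre, v_post, t_s * 1e3, dt_s * 1e3)


# --------------------------------------------------------------------------
# The experiment
# --------------------------------------------------------------------------


def run_experiment(config: ExperimentConfig, clock=None,
                   duration_model: DurationModel | None = None) -> ExperimentResult:
    """Run the three-phase hybrid-circuit protocol.

    On the default virtual clock the run is exactly reproducible from the
    config and seed. Returns the per-sample hybrid trace, the per-phase
    loop logs and the experiment log text.
    """
    config.validate()
    fs = config.fs
    dt_s = 1.0 / fs
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    log(f"hybrid-circuit experiment  fs={fs:g} Hz  "
        f"phases pre/coupled/post = {config.pre_s:g}/{config.coupled_s:g}/"
        f"{config.post_s:g} s  seed={config.seed}")

    # --- living side -----------------------------------------------------
    scaling = AcquisitionScaling(config.input_factor, config.nA_per_V)
    if config.replay_path:
        prep = ReplayPreparation.from_file(fs, config.replay_path)
        log(f"living neuron: replayed recording {config.replay_path}")
    else:
        prep = VirtualPreparation(
            fs, preset=config.prep_preset, target_period=config.prep_period_s,
            live_range=config.prep_range, noise_sd=config.prep_noise_sd,
            drift_rate=config.prep_drift, seed=config.seed)
        log(f"living neuron: virtual preparation ({config.prep_preset}, "
            f"period {config.prep_period_s:g} s, noise {config.prep_noise_sd:g} mV, "
            f"drift {config.prep_drift:g} mV/min)")

    model = from_preset(config.neuron_preset, config.neuron_overrides or None)
    log(f"model neuron: {config.neuron_preset} ({model.kind})"
        + (f" overrides {config.neuron_overrides}" if config.neuron_overrides else ""))

    drift = DriftCompensator(window=max(1, int(config.drift_window_s * fs)),
                             alpha=config.drift_alpha,
                             enabled=config.drift_compensation)

    n_pre = int(round(config.pre_s * fs))
    n_coupled = int(round(config.coupled_s * fs))
    n_post = int(round(config.post_s * fs))

    # shared experiment state mutated by the loop tasks
    st = {
        "live_raw": 0.0,       # as acquired, mV
        "live": 0.0,           # drift-corrected, mV
        "model_mV": math.nan,
        "i_inject_live": 0.0,  # nA commanded to the DAQ this interval
        "i_ml": 0.0,           # synaptic current model->live (withdrawn from live)
        "i_lm": 0.0,           # synaptic current live->model (withdrawn from model)
        "k_global": 0,
        "coupled": False,
    }

    live_col = np.empty(n_pre + n_coupled + n_post)
    model_col = np.full(n_pre + n_coupled + n_post, np.nan)
    iml_col = np.zeros(n_pre + n_coupled + n_post)
    ilm_col = np.zeros(n_pre + n_coupled + n_post)

    def daq_task(k: int) -> None:
        # write previous command, read the new sample (one exchange)
        command_V = scaling.inverse_nA(st["i_inject_live"])
        v_mV = prep.step(scaling.to_nA(command_V), dt_s)
        raw_V = scaling.inverse_mV(v_mV)
        st["live_raw"] = scaling.to_mV(raw_V)

    def drift_task(k: int) -> None:
        corr = drift.update(st["live_raw"])
        st["live"] = st["live_raw"] - corr

    stepper_holder: dict = {}

    def synapse_task(k: int) -> None:
        if not st["coupled"]:
            st["i_ml"] = 0.0
            st["i_lm"] = 0.0
            st["i_inject_live"] = 0.0
            return
        t_s = st["k_global"] * dt_s
        syn_ml = stepper_holder["syn_ml"]
        syn_lm = stepper_holder["syn_lm"]
        st["i_ml"] = _synapse_current(syn_ml, st["model_mV"], st["live"], t_s, dt_s)
        st["i_lm"] = _synapse_current(syn_lm, st["live"], st["model_mV"], t_s, dt_s)
        st["i_inject_live"] = -st["i_ml"]

    def model_task(k: int) -> None:
        stepper = stepper_holder.get("stepper")
        if stepper is not None:
            if st["coupled"]:
                tracker = stepper_holder.get("tracker")
                if tracker is not None:
                    refreshed = tracker.push(st["k_global"], st["live"])
                    if refreshed is not None:
                        stepper.set_target_duration(refreshed, fs)
            st["model_mV"] = stepper.step(-st["i_lm"])
        g = st["k_global"]
        live_col[g] = st["live"]
        model_col[g] = st["model_mV"]
        iml_col[g] = st["i_ml"]
        ilm_col[g] = st["i_lm"]
        st["k_global"] = g + 1

    tasks = [
        ("daq_exchange", daq_task),
        ("drift_compensation", drift_task),
        ("synapse_models", synapse_task),
        ("neuron_model", model_task),
    ]

    clock = clock if clock is not None else VirtualClock()
    writer = WriterChannel()
    logs: dict[str, LoopLog] = {}

    def run_phase(name: str, n: int, t0: float) -> None:
        if n == 0:
            return
        schedule = LoopSchedule(fs=fs, t0=t0)
        logs[name] = run_loop(schedule, tasks, clock, n,
                              duration_model=duration_model, writer=writer)
        if logs[name].error is not None:
            raise RuntimeError(f"loop error in {name} phase") from logs[name].error

    # --- phase 1: pre-control, then calibrate ----------------------------
    run_phase("pre", n_pre, 0.0)
    pre_live = live_col[:n_pre]
    bursts = detect_bursts(pre_live, fs, config.frac_on, config.frac_off,
                           config.min_gap_s)
    if len(bursts) < 2:
        raise CalibrationError(
            f"only {len(bursts)} burst(s) in the pre-control window; "
            "cannot calibrate")
    live_range = (float(pre_live.min()), float(pre_live.max()))
    live_dur = float(np.median([b.duration for b in bursts[:-1]])) \
        if len(bursts) > 2 else bursts[0].duration
    target = live_dur if config.target_burst == "auto" else float(config.target_burst)
    calib = calibrate_model(model, live_range, target, fs, drift=drift)
    log(f"calibration: live range ({live_range[0]:.2f}, {live_range[1]:.2f}) mV, "
        f"live burst duration {live_dur:.3f} s ({len(bursts)} bursts), "
        f"target {target:.3f} s")
    log(f"calibration: model range ({calib.character.v_min:.3f}, "
        f"{calib.character.v_max:.3f}), native burst "
        f"{calib.character.burst_duration:.3f}, time scale {calib.time_scale:.6g} "
        f"({'model-time/interval' if model.kind == 'ode' else 'samples/map point'})")

    stepper = _ModelStepper(model, calib, method=config.integrator)
    stepper_holder["stepper"] = stepper
    if config.online_refresh:
        stepper_holder["tracker"] = _OnlineDurationTracker(
            live_range, config.frac_on, config.frac_off, fs, init_dur=target)
        log("calibration: online per-burst duration refresh enabled")
    if model.kind == "ode":
        log(f"step selection: {stepper.n_sub} sub-step(s), dt_sub={stepper.dt_sub:.6g}")

    # backfill the pre-control model column with the calibrated uncoupled
    # free run (the 'uncoupled dynamics' panel of the protocol)
    for g in range(n_pre):
        model_col[g] = stepper.step(0.0)
    st["model_mV"] = float(model_col[n_pre - 1])

    # --- phase 2: coupled -------------------------------------------------
    syn_ml = _build_synapse(config.syn_model_to_live,
                            config.syn_model_to_live_overrides,
                            pre_range=(calib.amplitude.to_live(calib.character.v_min),
                                       calib.amplitude.to_live(calib.character.v_max)),
                            post_min=live_range[0])
    syn_lm = _build_synapse(config.syn_live_to_model,
                            config.syn_live_to_model_overrides,
                            pre_range=live_range,
                            post_min=calib.amplitude.to_live(calib.character.v_min))
    stepper_holder["syn_ml"] = syn_ml
    stepper_holder["syn_lm"] = syn_lm
    for tag, syn, preset in (("model->live", syn_ml, config.syn_model_to_live),
                             ("live->model", syn_lm, config.syn_live_to_model)):
        p = syn.params if hasattr(syn, "params") else syn
        log(f"synapse {tag}: {preset} {p}")

    st["coupled"] = True
    run_phase("coupled", n_coupled, config.pre_s)

    # --- phase 3: post-control -------------------------------------------
    st["coupled"] = False
    run_phase("post", n_post, config.pre_s + config.coupled_s)

    n_total = n_pre + n_coupled + n_post
    phase = np.empty(n_total, dtype=object)
    phase[:n_pre] = "pre"
    phase[n_pre:n_pre + n_coupled] = "coupled"
    phase[n_pre + n_coupled:] = "post"
    trace = pd.DataFrame({
        "time_s": np.arange(n_total) / fs,
        "live_mV": live_col,
        "model_mV": model_col,
        "i_model_to_live_nA": iml_col,
        "i_live_to_model_nA": ilm_col,
        "phase": phase,
    })

    for name, loop_log in logs.items():
        summary = latency_stats(loop_log, fail_threshold=1.0 / fs)
        log(f"{name} phase: {summary}")

    result = ExperimentResult(
        trace=trace, loop_logs=logs, log_text="\n".join(log_lines) + "\n",
        calibration=calib, live_range=live_range, live_burst_duration=live_dur)

    if config.out_dir:
        _write_outputs(config, result)
    return result


def _write_outputs(config: ExperimentConfig, result: ExperimentResult) -> None:
    import os

    os.makedirs(config.out_dir, exist_ok=True)
    result.trace.to_csv(os.path.join(config.out_dir, "hybrid_trace.csv"),
                        index=False)
    frames = [log.to_frame().assign(phase=name)
              for name, log in result.loop_logs.items()]
    pd.concat(frames).to_csv(os.path.join(config.out_dir, "latency.csv"),
                             index=False)
    with open(os.path.join(config.out_dir, "experiment.log"), "w") as fh:
        fh.write(result.log_text)


# --------------------------------------------------------------------------
# Antiphase metric
# --------------------------------------------------------------------------


def antiphase_index(live_onsets, model_onsets) -> tuple[float, float]:
    """Circular median and dispersion of model burst phase in the live cycle.

    For each live cycle (onset to next onset), every model onset inside it
    contributes a phase in [0, 1). Returns ``(median, dispersion)`` where
    the median is circular (phase 0.98 and 0.02 average to 0.0, not 0.5)
    and the dispersion is the circular standard deviation
    ``sqrt(-2 ln R)/(2 pi)``, both in cycle units.

    Antiphase bursting gives a median near 0.5; in-phase near 0 (or 1).
    """
    live = np.sort(np.asarray(live_onsets, dtype=float))
    mod = np.sort(np.asarray(model_onsets, dtype=float))
    if live.size < 3 or mod.size < 3:
        raise ValueError("need at least 3 burst onsets on each side")
    phases = []
    for a, b in zip(live[:-1], live[1:]):
        for m in mod[(mod >= a) & (mod < b)]:
            phases.append((m - a) / (b - a))
    if not phases:
        raise ValueError("no model onsets fall inside any live cycle")
    ph = np.asarray(phases)
    ang = 2.0 * math.pi * ph
    # circular median: the sample minimizing summed circular distance
    best, best_cost = None, math.inf
    for cand in ang:
        d = np.angle(np.exp(1j * (ang - cand)))
        cost = float(np.sum(np.abs(d)))
        if cost < best_cost:
            best, best_cost = cand, cost
    median = (best / (2.0 * math.pi)) % 1.0
    R = float(np.abs(np.mean(np.exp(1j * ang))))
    R = min(max(R, 1e-12), 1.0)
    dispersion = math.sqrt(max(0.0, -2.0 * math.log(R))) / (2.0 * math.pi)
    return median, dispersion


def coupled_antiphase(result: ExperimentResult, config: ExperimentConfig,
                      discard_frac: float = 0.2) -> tuple[float, float]:
    """Antiphase index of the coupled phase, after a settling transient.

    The first ``discard_frac`` of the coupled phase is discarded before
    burst detection on both the live and the mapped model trace.
    """
    tr = result.trace
    coupled = tr[tr.phase == "coupled"]
    n_skip = int(discard_frac * len(coupled))
    seg = coupled.iloc[n_skip:]
    fs = config.fs
    # thresholds anchored to the uncoupled (calibration-window) range:
    # synaptic hyperpolarization must not skew the hysteresis levels.
    # Both traces live in the same mV range after calibration. Intra-burst
    # spike intervals scale with the matched burst duration, so events are
    # merged at half of it.
    # (bursts may lengthen under coupling, so the merge gap uses a wider
    # multiple of the pre-control duration than the free-run convention)
    hint = result.live_range
    gap = max(config.min_gap_s, 0.75 * result.live_burst_duration)
    b_live = detect_bursts(seg.live_mV.to_numpy(), fs, config.frac_on,
                           config.frac_off, gap, range_hint=hint)
    b_model = detect_bursts(seg.model_mV.to_numpy(), fs, config.frac_on,
                            config.frac_off, gap, range_hint=hint)
    return antiphase_index([b.onset for b in b_live],
                           [b.onset for b in b_model])
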