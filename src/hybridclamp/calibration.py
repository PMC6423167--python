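"""Automatic adaptation between model and living neuron.

A dimensionless (or natively-millivolt) model and a biological cell differ
in amplitude and time scale. This module owns all of that mapping:

* burst detection with a hysteresis threshold on the slow wave;
* a two-point affine amplitude map between the model's voltage range and
  the living neuron's observed range (with exact inverse);
* time-scale matching — how much model time an ODE model must advance per
  acquisition interval, or how many interpolated output samples a map model
  must emit per map point — so one model burst spans the target duration;
* linear interpolation of map-model output with a phase accumulator whose
  long-run emission rate is exactly the configured ratio;
* drift compensation: an exponential moving average of per-window minima,
  whose departure from its initial value is subtracted from the live signal
  before any threshold or range computation.

Calibration results are echoed into the experiment log by the runner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BurstEvent",
    "AmplitudeMap",
    "CalibrationMap",
    "DriftCompensator",
    "MapInterpolator",
    "detect_bursts",
    "fit_amplitude_map",
    "fit_time_scale",
    "interpolate_map_output",
    "characterize_model",
    "calibrate_model",
    "ModelCharacter",
]


class CalibrationError(RuntimeError):
    """Calibration could not be completed (e.g. no bursts found)."""


@dataclass(frozen=True)
class BurstEvent:
    """One detected burst: [onset, offset) in seconds (or model time)."""

    onset: float
    offset: float
    v_min: float
    v_max: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def detect_bursts(
    trace,
    fs: float,
    frac_on: float = 0.25,
    frac_off: float = 0.15,
    min_gap: float = 0.1,
    range_hint: tuple | None = None,
) -> list[BurstEvent]:
    """Hysteresis burst detector.

    The on threshold sits at ``min + frac_on*(max-min)`` of the trace, the
    off threshold at ``frac_off`` of the range (``frac_off <= frac_on``).
    A burst onset is an upward crossing of the on threshold, the offset the
    next downward crossing of the off threshold. Events separated by less
    than ``min_gap`` (seconds at sampling rate ``fs``) are merged. A flat
    trace yields no bursts.

    ``range_hint`` fixes the (min, max) the thresholds are computed from —
    used when the trace's own extremes are biased, e.g. by synaptic
    hyperpolarization during a coupled phase.
    """
    v = np.asarray(trace, dtype=float)
    if v.size < 2:
        return []
    if not (0.0 < frac_on < 1.0 and 0.0 < frac_off <= frac_on):
        raise ValueError("require 0 < frac_off <= frac_on < 1")
    if range_hint is not None:
        vmin, vmax = float(range_hint[0]), float(range_hint[1])
    else:
        vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return []
    th_on = vmin + frac_on * (vmax - vmin)
    th_off = vmin + frac_off * (vmax - vmin)

    above_on = v >= th_on
    below_off = v < th_off
    onsets = np.flatnonzero(above_on[1:] & ~above_on[:-1]) + 1
    offsets = np.flatnonzero(below_off[1:] & ~below_off[:-1]) + 1
    if above_on[0]:
        onsets = np.concatenate(([0], onsets))

    events: list[tuple[int, int]] = []
    j = 0
    for i in onsets:
        if events and i < events[-1][1]:
            continue  # still inside the previous event
        j_arr = offsets[np.searchsorted(offsets, i, side="right"):]
        end = int(j_arr[0]) if j_arr.size else v.size
        events.append((int(i), end))

    # merge events closer than min_gap
    gap_samples = min_gap * fs
    merged: list[tuple[int, int]] = []
    for i, end in events:
        if merged and i - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((i, end))

    out = []
    for i, end in merged:
        seg = v[i:end] if end > i else v[i:i + 1]
        out.append(BurstEvent(onset=i / fs, offset=end / fs,
                              v_min=float(seg.min()), v_max=float(seg.max())))
    return out


# --------------------------------------------------------------------------
# Amplitude mapping
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AmplitudeMap:
    """Affine model-units -> mV map with exact inverse."""

    gain: float
    offset: float

    def to_live(self, x: float) -> float:
        return self.gain * x + self.offset

    def to_model(self, v: float) -> float:
        return (v - self.offset) / self.gain


def fit_amplitude_map(model_range: tuple, live_range: tuple) -> AmplitudeMap:
    """Two-point affine fit: model min/max onto live min/max (mV)."""
    m0, m1 = model_range
    l0, l1 = live_range
    if m1 == m0 or l1 == l0:
        raise ValueError("degenerate range")
    gain = (l1 - l0) / (m1 - m0)
    return AmplitudeMap(gain=gain, offset=l0 - gain * m0)


def fit_time_scale(model_burst: float, target_burst: float, fs: float,
                   kind: str = "ode") -> float:
    """Time-scale factor matching one model burst to ``target_burst`` s.

    For ODE models: model time advanced per acquisition interval,
    ``model_burst / (target_burst * fs)``. For map models: interpolation
    ratio r = output samples per map point,
    ``target_burst * fs / model_burst`` (model_burst in map points).
    """
    if not (model_burst > 0 and target_burst > 0 and fs > 0):
        raise ValueError("all time-scale inputs must be positive")
    if kind == "map":
        return target_burst * fs / model_burst
    return model_burst / (target_burst * fs)


# --------------------------------------------------------------------------
# Map-output interpolation
# --------------------------------------------------------------------------


def interpolate_map_output(x_prev: float, x_next: float, r: float,
                           phase: float = 0.0) -> tuple[list, float]:
    """Emit linearly-interpolated samples between two consecutive map points.

    The phase accumulator tracks the fractional position (in map-point
    units) of the next output sample; samples are emitted at spacing 1/r
    while the phase is inside [0, 1), and the residual carries over so the
    long-run rate is exactly r samples per map point. The raw map value
    ``x_prev`` itself is reproduced whenever the phase hits 0.
    """
    if not r > 0:
        raise ValueError("interpolation ratio must be positive")
    out = []
    step = 1.0 / r
    p = phase
    while p < 1.0 - 1e-12:
        out.append(x_prev + p * (x_next - x_prev))
        p += step
    return out, p - 1.0


class MapInterpolator:
    """Stateful wrapper around :func:`interpolate_map_output`."""

    def __init__(self, r: float):
        if not r > 0:
            raise ValueError("interpolation ratio must be positive")
        self.r = r
        self.phase = 0.0
        self._prev: float | None = None

    def feed(self, x: float) -> list:
        """Feed the next map point; return the output samples due."""
        if self._prev is None:
            self._prev = x
            return []
        out, self.phase = interpolate_map_output(self._prev, x, self.r, self.phase)
        self._prev = x
        return out


# --------------------------------------------------------------------------
# Drift compensation
# --------------------------------------------------------------------------


class DriftCompensator:
    """Baseline-drift tracker built on windowed minima.

    Every ``window`` samples, the window's minimum (the burst-trough
    baseline) is recorded. Two statistics are maintained over those
    minima: an exponential moving average with smoothing ``alpha`` (the
    smoothed ``baseline``) and an online least-squares linear trend. The
    reported ``correction`` — meant to be subtracted from the live signal
    before any threshold or range computation — is the fitted trend's
    total excursion since the start, which is unbiased for a linear ramp
    (a pure EMA departure systematically under-reports a ramp by its own
    lag). Disabled, the correction is exactly 0.
    """

    def __init__(self, window: int = 2000, alpha: float = 0.2,
                 enabled: bool = True):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self.alpha = alpha
        self.enabled = enabled
        self.baseline: float | None = None
        self.initial_baseline: float | None = None
        self.correction = 0.0
        self._buf_n = 0
        self._buf_min = math.inf
        # accumulators of the (window index, window min) regression
        self._n = 0
        self._si = 0.0
        self._sii = 0.0
        self._sm = 0.0
        self._sim = 0.0

    def _ingest(self, wmin: float) -> float:
        if self.baseline is None:
            self.baseline = wmin
            self.initial_baseline = wmin
        else:
            self.baseline += self.alpha * (wmin - self.baseline)
        i = float(self._n)
        self._n += 1
        self._si += i
        self._sii += i * i
        self._sm += wmin
        self._sim += i * wmin
        n = self._n
        det = n * self._sii - self._si * self._si
        if det > 0:
            slope = (n * self._sim - self._si * self._sm) / det
            self.correction = slope * (n - 1)
        return self.correction

    def update(self, sample: float) -> float:
        """Push one sample; returns the current correction (mV)."""
        if not self.enabled:
            return 0.0
        if sample < self._buf_min:
            self._buf_min = sample
        self._buf_n += 1
        if self._buf_n >= self.window:
            wmin = self._buf_min
            self._buf_n = 0
            self._buf_min = math.inf
            self._ingest(wmin)
        return self.correction

    def update_window(self, window_samples) -> float:
        """Process a whole window at once (offline use)."""
        arr = np.asarray(window_samples, dtype=float)
        if arr.size == 0:
            raise ValueError("window must be non-empty")
        if not self.enabled:
            return 0.0
        return self._ingest(float(arr.min()))


# --------------------------------------------------------------------------
# Whole-model characterization and calibration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelCharacter:
    """Free-run statistics of a model in its native units."""

    v_min: float
    v_max: float
    burst_duration: float  # median, model time units (map: points)
    burst_period: float    # median onset-to-onset, model time units
    n_bursts: int


@dataclass
class CalibrationMap:
    """Everything needed to run a model against a living neuron."""

    amplitude: AmplitudeMap
    time_scale: float       # ODE: model time per interval; map: ratio r
    kind: str               # 'ode' | 'map'
    character: ModelCharacter
    live_range: tuple
    drift: DriftCompensator = field(default_factory=lambda: DriftCompensator(enabled=False))


def free_run(model, duration: float | None = None, dt: float | None = None,
             integrator=None):
    """Native free run of a model; returns (voltage array, dt used)."""
    from .integrators import IntegratorSpec, integrate_step

    hints = model.hints
    duration = duration if duration is not None else hints.free_run_time
    if model.kind == "map":
        n = int(round(duration))
        state = model.initial_state()
        out = np.empty(n)
        for i in range(n):
            state = model.map_step(state)
            out[i] = state[model.v_index]
        return out, 1.0
    dt = dt if dt is not None else hints.dt
    spec = integrator or IntegratorSpec(method="rk4", dt=dt)
    n = int(round(duration / dt))
    state = model.initial_state()
    out = np.empty(n)
    t = 0.0
    for i in range(n):
        state, _ = integrate_step(spec, lambda tt, y: model.derivs(tt, y), state, t, dt)
        state, _ = _events(model, state)
        out[i] = state[model.v_index]
        t += dt
    return out, dt


def _events(model, state):
    if hasattr(model, "discrete_events"):
        return model.discrete_events(state)
    return state, False


def characterize_model(model, duration: float | None = None) -> ModelCharacter:
    """Free-run a model and measure its range and burst timing."""
    v, dt = free_run(model, duration)
    hints = model.hints
    n_skip = int(round(hints.transient / dt))
    v = v[n_skip:]
    fs_model = 1.0 / dt
    bursts = detect_bursts(v, fs_model, min_gap=hints.min_gap)
    if len(bursts) < 2:
        raise CalibrationError(
            f"model produced {len(bursts)} burst(s) in a free run; cannot calibrate"
        )
    durations = np.array([b.duration for b in bursts[:-1]])
    onsets = np.array([b.onset for b in bursts])
    periods = np.diff(onsets)
    return ModelCharacter(
        v_min=float(v.min()), v_max=float(v.max()),
        burst_duration=float(np.median(durations)),
        burst_period=float(np.median(periods)),
        n_bursts=len(bursts),
    )


def calibrate_model(model, live_range: tuple, target_burst: float, fs: float,
                    character: ModelCharacter | None = None,
                    match: str = "duration",
                    drift: DriftCompensator | None = None) -> CalibrationMap:
    """Build the full calibration of ``model`` against a living neuron.

    ``live_range`` is the observed (min, max) of the living cell in mV and
    ``target_burst`` the burst duration (seconds) the model should match
    (``match='period'`` matches onset-to-onset period instead, used by the
    virtual preparation).
    """
    ch = character or characterize_model(model)
    amp = fit_amplitude_map((ch.v_min, ch.v_max), live_range)
    native = ch.burst_duration if match == "duration" else ch.burst_period
    scale = fit_time_scale(native, target_burst, fs, kind=model.kind)
    return CalibrationMap(
        amplitude=amp, time_scale=scale, kind=model.kind, character=ch,
        live_range=tuple(live_range),
        drift=drift or DriftCompensator(enabled=False),
    )
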