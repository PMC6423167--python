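"""Synthetic stand-in for the DAQ + living neuron.

Hybrid-circuit experiments couple a model cell to a biological neuron of
the pyloric central pattern generator — a cell bursting at roughly one
burst per second. No hardware or recordings are required here: the
"living" side is emulated by a calibrated Hindmarsh-Rose burster rendered
into a physiological millivolt range, with optional additive Gaussian
noise and linear baseline drift, both seeded and reproducible sample for
sample. A recorded two-column (time, mV) trace can be replayed in its
place.

The acquisition scaling conventions are explicit: the raw analog input is
multiplied by the *input voltage scaling factor* (default 100) to recover
millivolts, and the command output voltage is converted to injected
current at the *output conversion factor* (default 10 nA/V).
"""

from __future__ import annotations

import math

import numpy as np

from .calibration import calibrate_model, characterize_model, CalibrationMap
from .integrators import IntegratorSpec, integrate_step
from .neuron_models import from_preset

__all__ = [
    "AcquisitionScaling",
    "VirtualPreparation",
    "ReplayPreparation",
    "daq_exchange",
    "load_trace",
]


class AcquisitionScaling:
    """Linear, invertible DAQ scaling conventions."""

    def __init__(self, input_factor: float = 100.0, nA_per_V: float = 10.0):
        if input_factor == 0 or nA_per_V == 0:
            raise ValueError("scaling factors must be non-zero")
        self.input_factor = input_factor
        self.nA_per_V = nA_per_V

    def to_mV(self, raw_in: float) -> float:
        return self.input_factor * raw_in

    def to_nA(self, command_out: float) -> float:
        return self.nA_per_V * command_out

    def inverse_mV(self, v_mV: float) -> float:
        return v_mV / self.input_factor

    def inverse_nA(self, i_nA: float) -> float:
        return i_nA / self.nA_per_V


def daq_exchange(scaling: AcquisitionScaling, raw_in: float,
                 command_out: float) -> tuple[float, float]:
    """One acquisition exchange: raw volts in -> mV; command volts -> nA."""
    if not (math.isfinite(raw_in) and math.isfinite(command_out)):
        raise ValueError("non-finite DAQ values")
    return scaling.to_mV(raw_in), scaling.to_nA(command_out)


class VirtualPreparation:
    """A calibrated bursting cell standing in for the biological neuron.

    The intrinsic model (a Hindmarsh-Rose preset by default) is
    time-scaled so its burst *period* matches ``target_period`` seconds at
    sampling rate ``fs``, and amplitude-mapped into ``live_range`` mV.
    Injected current (nA) is mapped into model drive through the inverse
    of the amplitude gain; a positive injected current depolarizes.
    Output samples get seeded Gaussian noise (``noise_sd`` mV) and linear
    drift (``drift_rate`` mV/min).
    """

    def __init__(self, fs: float, preset: str = "hindmarsh_rose_burster",
                 target_period: float = 1.0,
                 live_range: tuple = (-62.0, -30.0),
                 noise_sd: float = 0.5, drift_rate: float = 0.0,
                 seed: int | None = 0):
        self.fs = fs
        self.model = from_preset(preset)
        self.calibration: CalibrationMap = calibrate_model(
            self.model, live_range, target_period, fs, match="period")
        self.target_period = target_period
        self.live_range = tuple(live_range)
        self.noise_sd = noise_sd
        self.drift_rate = drift_rate
        self._rng = np.random.default_rng(seed)
        self._state = self.model.initial_state()
        self._spec = IntegratorSpec(method="rk4", dt=self.calibration.time_scale)
        self._t_model = 0.0
        self._n = 0
        # settle past the model transient so output bursts immediately
        self._settle()

    def _settle(self):
        dt = self.model.hints.dt
        n = int(self.model.hints.transient / dt)
        st = self._state
        for _ in range(n):
            st, _ = integrate_step(self._spec, self.model.derivs, st,
                                   self._t_model, dt)
        self._state = st

    def step(self, injected_current: float = 0.0, dt: float | None = None) -> float:
        """Advance one acquisition interval; returns membrane mV."""
        if not math.isfinite(injected_current):
            raise ValueError("non-finite injected current")
        dt = dt if dt is not None else 1.0 / self.fs
        if not dt > 0:
            raise ValueError("dt must be positive")
        # nA -> model drive through the inverse amplitude gain
        drive = injected_current / self.calibration.amplitude.gain
        h = self.calibration.time_scale * (dt * self.fs)
        self._state, _ = integrate_step(
            self._spec, lambda t, y: self.model.derivs(t, y, drive),
            self._state, self._t_model, h)
        self._t_model += h
        self._n += 1
        v = self.calibration.amplitude.to_live(self._state[self.model.v_index])
        t_s = self._n / self.fs
        if self.drift_rate:
            v += self.drift_rate * t_s / 60.0
        if self.noise_sd:
            v += self.noise_sd * self._rng.standard_normal()
        return v

    def run(self, duration: float, current_fn=None) -> np.ndarray:
        """Free-run (or drive) the preparation for ``duration`` seconds."""
        n = int(round(duration * self.fs))
        out = np.empty(n)
        for k in range(n):
            i = current_fn(k) if current_fn is not None else 0.0
            out[k] = self.step(i)
        return out


def load_trace(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time s, voltage mV) plain-text/CSV recording."""
    arr = np.loadtxt(path, delimiter=None if str(path).endswith(".txt") else ",")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("expected two columns: time, voltage")
    return arr[:, 0], arr[:, 1]


class ReplayPreparation:
    """Replay a recorded membrane-potential trace as the living neuron.

    The recording is resampled to the loop rate by linear interpolation;
    injected current is accepted (for interface parity) but cannot
    influence a recording — replay is open-loop by construction.
    """

    def __init__(self, fs: float, time_s, voltage_mV):
        t = np.asarray(time_s, dtype=float)
        v = np.asarray(voltage_mV, dtype=float)
        if t.size != v.size or t.size < 2:
            raise ValueError("need matching time/voltage columns, >= 2 samples")
        n = int(math.floor((t[-1] - t[0]) * fs)) + 1
        grid = t[0] + np.arange(n) / fs
        self.samples = np.interp(grid, t, v)
        self.fs = fs
        self.live_range = (float(v.min()), float(v.max()))
        self._k = 0

    @classmethod
    def from_file(cls, fs: float, path) -> "ReplayPreparation":
        t, v = load_trace(path)
        return cls(fs, t, v)

    def step(self, injected_current: float = 0.0, dt: float | None = None) -> float:
        v = float(self.samples[min(self._k, self.samples.size - 1)])
        self._k += 1
        return v
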