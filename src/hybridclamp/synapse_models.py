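"""Synapse model library: electrical, graded (fast/slow), and spike-triggered
chemical coupling currents.

Unit discipline throughout: conductances in µS, voltages in mV, currents in
nA (µS × mV = nA). The sign convention for chemical/graded currents is that
a positive current is *withdrawn* from the postsynaptic cell, so a synapse
with reversal below the postsynaptic voltage is inhibitory.

Graded synapses release transmitter continuously as a sigmoidal function of
presynaptic voltage — the dominant mode of transmission between pyloric
CPG neurons. Their threshold and slope are expressed as *percentages of the
presynaptic amplitude range* and resolved against the observed min/max of
the presynaptic signal (supplied by the calibration module), so one preset
works for any neuron once calibrated. The slow variant adds first-order
gate kinetics with forward rate ``k1`` (1/s, scaled by activation) and
backward rate ``k2`` (1/s); its fixed point under constant activation a is
``k1*a / (k1*a + k2)``. The fast variant is the instantaneous limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "ElectricalSynapseParams",
    "GradedSynapseParams",
    "ChemicalSynapseParams",
    "GradedSynapse",
    "ChemicalSynapse",
    "electrical_current",
    "graded_activation",
    "graded_slow_step",
    "graded_current",
    "chemical_step",
    "synapse_from_preset",
]


# --------------------------------------------------------------------------
# Electrical (gap junction)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectricalSynapseParams:
    """Ohmic gap junction; ``g`` in µS."""

    g: float = 0.1

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("conductance must be non-negative")


def electrical_current(params: ElectricalSynapseParams, v_pre: float,
                       v_post: float) -> float:
    """I = g (v_pre - v_post), in nA; antisymmetric under exchange."""
    if not (math.isfinite(v_pre) and math.isfinite(v_post)):
        raise ValueError("non-finite voltage")
    return params.g * (v_pre - v_post)


# --------------------------------------------------------------------------
# Graded synapses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GradedSynapseParams:
    """Graded chemical synapse.

    ``v_threshold_pct`` and ``slope_pct`` are fractions (0.15 == 15%) of
    the presynaptic amplitude range; ``E_syn`` in mV; ``k1``/``k2`` in 1/s
    (slow mode only). ``E_syn=None`` defers the reversal until calibration:
    it is placed 30 mV below the observed postsynaptic minimum, i.e. well
    below the slow-wave trough, as for a potassium-mediated graded
    inhibitory synapse — guaranteeing an inhibitory driving force
    throughout the postsynaptic cycle.
    """

    g: float = 0.2
    v_threshold_pct: float = 0.15
    slope_pct: float = 0.01
    E_syn: float | None = None
    k1: float = 14.0
    k2: float = 4.0
    mode: str = "fast"

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("conductance must be non-negative")
        if self.mode not in ("fast", "slow"):
            raise ValueError(f"unknown graded mode {self.mode!r}")


def graded_activation(params: GradedSynapseParams, v_pre: float,
                      pre_range: tuple) -> float:
    """Sigmoidal transmitter activation in [0, 1].

    The absolute threshold and slope are ``pct * (max - min)`` of the
    presynaptic range, the threshold offset from the range minimum.
    Activation is exactly 0.5 at the absolute threshold and monotone
    non-decreasing in ``v_pre``.
    """
    lo, hi = pre_range
    if not hi > lo:
        raise ValueError("degenerate presynaptic range")
    span = hi - lo
    v_th = lo + params.v_threshold_pct * span
    s = params.slope_pct * span
    x = (v_th - v_pre) / s
    if x > 500.0:
        return 0.0
    if x < -500.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


def graded_slow_step(params: GradedSynapseParams, m_gate: float, v_pre: float,
                     pre_range: tuple, dt: float) -> float:
    """Advance the slow gate one step of dm/dt = k1 (1-m) a(v_pre) - k2 m.

    Integrated with the exact exponential update for this linear-in-m ODE,
    so the gate cannot leave [0, 1] for any dt > 0. ``dt`` in seconds.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if not 0.0 <= m_gate <= 1.0:
        raise ValueError("m_gate outside [0,1]")
    a = graded_activation(params, v_pre, pre_range)
    rate = params.k1 * a + params.k2
    if rate <= 0.0:
        return m_gate
    m_inf = params.k1 * a / rate
    return m_inf + (m_gate - m_inf) * math.exp(-rate * dt)


def graded_current(params: GradedSynapseParams, gate: float,
                   v_post: float) -> float:
    """I = g * gate * (v_post - E_syn), nA; positive = withdrawn from post."""
    if not 0.0 <= gate <= 1.0:
        raise ValueError("gate outside [0,1]")
    if params.E_syn is None:
        raise ValueError("E_syn unresolved; resolve against the live range first")
    return params.g * gate * (v_post - params.E_syn)


DEFERRED_E_SYN_OFFSET = 30.0  # mV below the observed postsynaptic minimum


class GradedSynapse:
    """Stateful graded synapse bound to a presynaptic range.

    ``pre_range`` and (if deferred) ``E_syn`` are resolved at calibration
    time; ``step`` then maps (v_pre, v_post, dt) -> current in nA.
    """

    def __init__(self, params: GradedSynapseParams, pre_range: tuple,
                 post_min: float | None = None):
        if params.E_syn is None:
            if post_min is None:
                raise ValueError("need post_min to resolve the deferred E_syn")
            params = GradedSynapseParams(
                g=params.g, v_threshold_pct=params.v_threshold_pct,
                slope_pct=params.slope_pct,
                E_syn=post_min - DEFERRED_E_SYN_OFFSET,
                k1=params.k1, k2=params.k2, mode=params.mode)
        self.params = params
        self.pre_range = tuple(pre_range)
        self.m_gate = 0.0

    def step(self, v_pre: float, v_post: float, dt: float) -> float:
        p = self.params
        if p.mode == "slow":
            self.m_gate = graded_slow_step(p, self.m_gate, v_pre,
                                           self.pre_range, dt)
            gate = self.m_gate
        else:
            gate = graded_activation(p, v_pre, self.pre_range)
        return graded_current(p, gate, v_post)


# --------------------------------------------------------------------------
# Spike-triggered chemical synapse
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemicalSynapseParams:
    """First-order transmitter-pulse kinetics keyed on presynaptic spikes.

    A presynaptic spike releases a transmitter pulse of amplitude ``T_max``
    (mM) lasting ``pulse_duration`` (ms); the open fraction follows
    ds/dt = alpha T (1-s) - beta s with ``alpha`` in 1/(ms mM) and ``beta``
    in 1/ms.
    """

    g: float = 0.5
    E_syn: float = -80.0
    alpha: float = 0.94
    beta: float = 0.18
    T_max: float = 1.0
    pulse_duration: float = 1.0


@dataclass
class ChemicalSynapseState:
    s_open: float = 0.0
    last_spike: float = -math.inf


def chemical_step(params: ChemicalSynapseParams, state: ChemicalSynapseState,
                  spike_times, t_now: float, v_post: float,
                  dt: float) -> tuple[ChemicalSynapseState, float]:
    """Advance the open fraction over [t_now, t_now+dt]; return new state
    and postsynaptic current in nA.

    Transmitter is ``T_max`` within ``pulse_duration`` ms of the most
    recent spike at or before the step, else 0; the linear gate ODE is
    advanced with its exact exponential solution. ``spike_times`` must be
    sorted ascending (ms).
    """
    for a, b in zip(spike_times, list(spike_times)[1:]):
        if b < a:
            raise ValueError("spike_times must be sorted ascending")
    last = state.last_spike
    for ts in spike_times:
        if ts <= t_now + dt and ts > last:
            last = ts
    T = params.T_max if (t_now - last) < params.pulse_duration else 0.0
    rate = params.alpha * T + params.beta
    s_inf = params.alpha * T / rate if rate > 0 else 0.0
    s_new = s_inf + (state.s_open - s_inf) * math.exp(-rate * dt)
    current = params.g * s_new * (v_post - params.E_syn)
    return ChemicalSynapseState(s_open=s_new, last_spike=last), current


class ChemicalSynapse:
    """Stateful wrapper with built-in presynaptic spike detection.

    A spike is an upward crossing of ``spike_threshold`` (mV) with a
    refractory hold, so one spike is detected once.
    """

    def __init__(self, params: ChemicalSynapseParams,
                 spike_threshold: float = 0.0, refractory: float = 2.0):
        self.params = params
        self.spike_threshold = spike_threshold
        self.refractory = refractory
        self.state = ChemicalSynapseState()
        self._prev_v = -math.inf

    def step(self, v_pre: float, v_post: float, t_now: float,
             dt: float) -> float:
        spikes = []
        if (v_pre >= self.spike_threshold > self._prev_v
                and t_now - self.state.last_spike >= self.refractory):
            spikes = [t_now]
        self._prev_v = v_pre
        self.state, current = chemical_step(self.params, self.state, spikes,
                                            t_now, v_post, dt)
        return current


# --------------------------------------------------------------------------
# Preset registry
# --------------------------------------------------------------------------


def synapse_from_preset(name: str, overrides: dict | None = None):
    """Instantiate synapse *parameters* from a named stock preset.

    Graded presets stay unbound (range/reversal resolved at calibration).
    """
    from .neuron_models import load_presets

    presets = load_presets("synapses")
    if name not in presets:
        raise KeyError(f"unknown synapse preset {name!r}; have {sorted(presets)}")
    entry = dict(presets[name])
    kind = entry.pop("kind")
    params = dict(entry.get("params", {}))
    if overrides:
        params.update(overrides)
    cls = {
        "electrical": ElectricalSynapseParams,
        "graded": GradedSynapseParams,
        "chemical": ChemicalSynapseParams,
    }[kind]
    return cls(**params)
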