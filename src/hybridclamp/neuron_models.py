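"""Neuron model library: discrete maps and ODE models with bursting dynamics.

Four families are provided, spanning the cost spectrum used in hybrid-circuit
work:

* ``RulkovMap`` — a two-dimensional spiking-bursting iterated map; no ODE
  integration, one map point per "event sample", output interpolated up to
  the acquisition rate by the calibration module.
* ``Izhikevich`` — quadratic integrate-and-fire with recovery variable and a
  discrete reset rule (the only model here with discrete events).
* ``HindmarshRose`` — the classic three-variable square-wave burster.
* ``ConductanceModel`` — Hodgkin-Huxley-style models with exponential
  nonlinearities, in two variants: a three-variable Morris-Lecar-type
  burster with a slow potassium current (``ghigliazza_holmes``) and a
  four-variable sodium/potassium interneuron model with a slow adaptation
  current (``wang``). Their rate/steady-state functions can be tabulated.

States are tuples of floats. The designated "voltage" is state component
``v_index`` (the fast variable for dimensionless models); all mapping to
physiological millivolts is owned by the calibration module.

Stock parameter sets live in ``presets/neurons.yaml``; every stock preset is
required (and tested) to free-run in a bursting regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable

import yaml

__all__ = [
    "RulkovParams",
    "IzhikevichParams",
    "HindmarshRoseParams",
    "ConductanceParams",
    "RulkovMap",
    "Izhikevich",
    "HindmarshRose",
    "ConductanceModel",
    "LookupTable",
    "tabulate",
    "CalibrationHints",
    "load_presets",
    "from_preset",
    "MODEL_CLASSES",
]


class ModelError(ValueError):
    """Invalid state or parameters handed to a model."""


@dataclass(frozen=True)
class CalibrationHints:
    """Model-time bookkeeping the calibration module needs.

    All values are in the model's own time units (map points for maps).
    ``free_run_time`` must cover several bursts; ``transient`` is discarded
    before burst statistics; ``min_gap`` merges burst events closer than
    this.
    """

    dt: float
    free_run_time: float
    transient: float
    min_gap: float


# --------------------------------------------------------------------------
# Rulkov map
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RulkovParams:
    """Two-dimensional spiking-bursting map parameters (dimensionless).

    ``mu`` is the slow-variable rate and must be small and positive;
    ``sigma`` biases the slow nullcline (x* = sigma - 1)."""

    alpha: float = 4.5
    sigma: float = 0.005
    mu: float = 0.001

    def __post_init__(self):
        # mu = 0 is tolerated (frozen slow variable); negative rates are not
        if self.mu < 0:
            raise ModelError("mu must be non-negative")


def rulkov_step(params: RulkovParams, state: tuple, input_current: float = 0.0) -> tuple:
    """One iteration of the piecewise fast map and the linear slow map.

    ``state`` is ``(x, x_prev, y)``. The external drive enters the fast map
    additively with the slow variable; the slow variable relaxes toward
    ``sigma - 1`` in x.
    """
    x, x_prev, y = state
    if not (math.isfinite(x) and math.isfinite(x_prev) and math.isfinite(y)):
        raise ModelError(f"non-finite state {state}")
    y_eff = y + input_current
    if x <= 0.0:
        if x == 1.0:  # pragma: no cover - unreachable on this branch, kept for safety
            raise ModelError("singular fast map at x == 1")
        x_new = params.alpha / (1.0 - x) + y_eff
    elif x < params.alpha + y_eff and x_prev <= 0.0:
        x_new = params.alpha + y_eff
    else:
        x_new = -1.0
    y_new = y - params.mu * (x + 1.0) + params.mu * params.sigma
    return (x_new, x, y_new)


class RulkovMap:
    """Map-model wrapper around :func:`rulkov_step`."""

    kind = "map"
    v_index = 0

    def __init__(self, params: RulkovParams | None = None,
                 hints: CalibrationHints | None = None):
        self.params = params or RulkovParams()
        self.hints = hints or CalibrationHints(
            dt=1.0, free_run_time=60000, transient=10000, min_gap=100
        )

    def initial_state(self) -> tuple:
        return (-1.0, -1.0, self.params.sigma - 3.5)

    def map_step(self, state: tuple, input_current: float = 0.0) -> tuple:
        return rulkov_step(self.params, state, input_current)


# --------------------------------------------------------------------------
# Izhikevich
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IzhikevichParams:
    """Quadratic model with recovery variable ``u``; time in ms, v in mV.

    Defaults are a chattering/bursting cell: fast reset to ``c = -50`` with
    small recovery increment ``d``."""

    a: float = 0.02
    b: float = 0.2
    c: float = -50.0
    d: float = 2.0
    I: float = 15.0
    peak: float = 30.0


class Izhikevich:
    kind = "ode"
    v_index = 0

    def __init__(self, params: IzhikevichParams | None = None,
                 hints: CalibrationHints | None = None):
        self.params = params or IzhikevichParams()
        # time unit: ms
        self.hints = hints or CalibrationHints(
            dt=0.05, free_run_time=2000.0, transient=400.0, min_gap=20.0
        )

    def initial_state(self) -> tuple:
        p = self.params
        return (p.c, p.b * p.c)

    def derivs(self, t: float, state: tuple, input_current: float = 0.0) -> tuple:
        if len(state) != 2:
            raise ModelError(f"expected 2 state variables, got {len(state)}")
        v, u = state
        p = self.params
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + p.I + input_current
        du = p.a * (p.b * v - u)
        return (dv, du)

    def discrete_events(self, state: tuple) -> tuple[tuple, bool]:
        """Spike-cut reset: at or above ``peak``, v -> c and u -> u + d."""
        v, u = state
        p = self.params
        if v >= p.peak:
            return (p.c, u + p.d), True
        return state, False


def apply_discrete_events(model, state: tuple) -> tuple[tuple, bool]:
    """Apply a model's reset rule, if it has one; boundary is inclusive."""
    if hasattr(model, "discrete_events"):
        return model.discrete_events(state)
    return state, False


# --------------------------------------------------------------------------
# Hindmarsh-Rose
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HindmarshRoseParams:
    """Three-variable square-wave burster (dimensionless)."""

    b: float = 3.0
    I: float = 2.7
    r: float = 0.005
    s: float = 4.0
    x_rest: float = -1.6

    def __post_init__(self):
        if not self.r > 0:
            raise ModelError("r must be positive")


class HindmarshRose:
    kind = "ode"
    v_index = 0

    def __init__(self, params: HindmarshRoseParams | None = None,
                 hints: CalibrationHints | None = None):
        self.params = params or HindmarshRoseParams()
        # time unit: dimensionless; one burst ~ a few hundred units at r~2e-3
        self.hints = hints or CalibrationHints(
            dt=0.02, free_run_time=6000.0, transient=1500.0, min_gap=80.0
        )

    def initial_state(self) -> tuple:
        return (-1.5, -10.0, 2.0)

    def derivs(self, t: float, state: tuple, input_current: float = 0.0) -> tuple:
        if len(state) != 3:
            raise ModelError(f"expected 3 state variables, got {len(state)}")
        x, y, z = state
        p = self.params
        dx = y + p.b * x * x - x * x * x - z + p.I + input_current
        dy = 1.0 - 5.0 * x * x - y
        dz = p.r * (p.s * (x - p.x_rest) - z)
        return (dx, dy, dz)


# --------------------------------------------------------------------------
# Conductance-based models
# --------------------------------------------------------------------------


def boltzmann(v: float, half: float, slope: float) -> float:
    """Sigmoidal steady state 1/(1+exp(-(v-half)/slope)); slope > 0 rises."""
    return 1.0 / (1.0 + math.exp(-(v - half) / slope))


@dataclass(frozen=True)
class ConductanceParams:
    """Hodgkin-Huxley-type parameters; mV, ms, µF/cm², mS/cm², µA/cm².

    ``variant='ghigliazza_holmes'``: state (v, n, s) — instantaneous calcium
    activation, fast potassium gate n, slow potassium gate s.
    ``variant='wang'``: state (v, h, n, z) — instantaneous m, sodium
    inactivation h, delayed-rectifier n (exponential rate functions), slow
    adaptation gate z.
    """

    variant: str = "ghigliazza_holmes"
    C: float = 1.0
    I: float = 0.0
    g: dict = field(default_factory=dict)  # maximal conductances by current name
    E: dict = field(default_factory=dict)  # reversal potentials by ion
    gates: dict = field(default_factory=dict)  # per-gate half/slope/tau

    def __post_init__(self):
        if self.variant not in ("ghigliazza_holmes", "wang"):
            raise ModelError(f"unknown conductance variant {self.variant!r}")


GH_DEFAULTS = ConductanceParams(
    variant="ghigliazza_holmes",
    C=20.0,
    I=46.0,
    g={"Ca": 4.0, "K": 8.0, "KS": 0.4, "L": 2.0},
    E={"Ca": 120.0, "K": -84.0, "L": -60.0},
    gates={
        "m": {"half": -1.2, "slope": 9.0},          # instantaneous Ca activation
        "n": {"half": 12.0, "slope": 8.7, "tau": 4.0},
        "s": {"half": -20.0, "slope": 5.0, "tau": 1500.0},
    },
)

WANG_DEFAULTS = ConductanceParams(
    variant="wang",
    C=1.0,
    I=0.0,
    g={"Na": 35.0, "NaP": 0.8, "K": 9.0, "Z": 1.5, "L": 0.1},
    E={"Na": 55.0, "K": -90.0, "L": -65.0},
    gates={
        "h": {"phi": 5.0},
        "n": {"phi": 5.0},
        "p": {"half": -51.0, "slope": 4.0},
        "z": {"half": -50.0, "slope": 4.0, "tau": 250.0},
    },
)


# Wang-type exponential rate functions (ms^-1); the 0/0 removable
# singularities are patched with the analytic limit.
def _alpha_m(v):
    d = v + 35.0
    if abs(d) < 1e-7:
        return 1.0
    return 0.1 * d / (1.0 - math.exp(-d / 10.0))


def _beta_m(v):
    return 4.0 * math.exp(-(v + 60.0) / 18.0)


def _alpha_h(v):
    return 0.07 * math.exp(-(v + 58.0) / 20.0)


def _beta_h(v):
    return 1.0 / (1.0 + math.exp(-(v + 28.0) / 10.0))


def _alpha_n(v):
    d = v + 34.0
    if abs(d) < 1e-7:
        return 0.1
    return 0.01 * d / (1.0 - math.exp(-d / 10.0))


def _beta_n(v):
    return 0.125 * math.exp(-(v + 44.0) / 80.0)


WANG_RATE_FNS = {
    "alpha_m": _alpha_m, "beta_m": _beta_m,
    "alpha_h": _alpha_h, "beta_h": _beta_h,
    "alpha_n": _alpha_n, "beta_n": _beta_n,
}


class ConductanceModel:
    """Conductance-based model; nonlinearities optionally table-driven."""

    kind = "ode"
    v_index = 0

    def __init__(self, params: ConductanceParams | None = None,
                 hints: CalibrationHints | None = None,
                 tables: dict | None = None):
        self.params = params or GH_DEFAULTS
        if hints is None:
            if self.params.variant == "ghigliazza_holmes":
                hints = CalibrationHints(dt=0.05, free_run_time=15000.0,
                                         transient=3000.0, min_gap=250.0)
            else:
                hints = CalibrationHints(dt=0.01, free_run_time=8000.0,
                                         transient=1000.0, min_gap=100.0)
        self.hints = hints
        self._tables = tables  # name -> LookupTable, replaces the direct fns

    # -- nonlinearity access (direct or tabulated) -------------------------

    def _fn(self, name: str, direct: Callable[[float], float], v: float) -> float:
        if self._tables is not None and name in self._tables:
            return self._tables[name](v)
        return direct(v)

    def nonlinearities(self) -> dict:
        """The scalar functions of v eligible for tabulation."""
        p = self.params
        if p.variant == "wang":
            return dict(WANG_RATE_FNS)
        g = p.gates
        return {
            "minf": lambda v: boltzmann(v, g["m"]["half"], g["m"]["slope"]),
            "ninf": lambda v: boltzmann(v, g["n"]["half"], g["n"]["slope"]),
            "sinf": lambda v: boltzmann(v, g["s"]["half"], g["s"]["slope"]),
        }

    def tabulated(self, lo: float = -100.0, hi: float = 60.0,
                  n_nodes: int = 10001) -> "ConductanceModel":
        """Copy of this model with every nonlinearity replaced by a table."""
        tables = {name: tabulate(fn, lo, hi, n_nodes)
                  for name, fn in self.nonlinearities().items()}
        return ConductanceModel(self.params, self.hints, tables)

    # -- dynamics ----------------------------------------------------------

    # on-attractor states of the stock bursting presets: starting here keeps
    # the slow gates (tau up to 1.5 s of model time) from biasing the
    # characterization window with a long approach transient
    _STOCK_INIT = {
        "ghigliazza_holmes": (-17.509340437733826, 0.09606159991598691,
                              0.26957639750482687),
        "wang": (-84.77518692990151, 0.9874111054528154,
                 0.015056971327590402, 0.2532754740679507),
    }

    def initial_state(self) -> tuple:
        if self.params == {"ghigliazza_holmes": GH_DEFAULTS,
                           "wang": WANG_DEFAULTS}[self.params.variant]:
            return self._STOCK_INIT[self.params.variant]
        if self.params.variant == "wang":
            v0 = -64.0
            return (v0,
                    _alpha_h(v0) / (_alpha_h(v0) + _beta_h(v0)),
                    _alpha_n(v0) / (_alpha_n(v0) + _beta_n(v0)),
                    0.0)
        v0 = -40.0
        g = self.params.gates
        return (v0,
                boltzmann(v0, g["n"]["half"], g["n"]["slope"]),
                boltzmann(v0, g["s"]["half"], g["s"]["slope"]))

    def derivs(self, t: float, state: tuple, input_current: float = 0.0) -> tuple:
        p = self.params
        if p.variant == "wang":
            if len(state) != 4:
                raise ModelError(f"expected 4 state variables, got {len(state)}")
            v, h, n, z = state
            nl = WANG_RATE_FNS
            am = self._fn("alpha_m", nl["alpha_m"], v)
            bm = self._fn("beta_m", nl["beta_m"], v)
            minf = am / (am + bm)
            i_na = p.g["Na"] * minf ** 3 * h * (v - p.E["Na"])
            i_nap = 0.0
            if "NaP" in p.g:
                gp = p.gates["p"]
                pinf = boltzmann(v, gp["half"], gp["slope"])
                i_nap = p.g["NaP"] * pinf * (v - p.E["Na"])
            i_k = p.g["K"] * n ** 4 * (v - p.E["K"])
            i_z = p.g["Z"] * z * (v - p.E["K"])
            i_l = p.g["L"] * (v - p.E["L"])
            dv = (p.I + input_current - i_na - i_nap - i_k - i_z - i_l) / p.C
            ph, pn = p.gates["h"]["phi"], p.gates["n"]["phi"]
            ah = self._fn("alpha_h", nl["alpha_h"], v)
            bh = self._fn("beta_h", nl["beta_h"], v)
            an = self._fn("alpha_n", nl["alpha_n"], v)
            bn = self._fn("beta_n", nl["beta_n"], v)
            dh = ph * (ah * (1.0 - h) - bh * h)
            dn = pn * (an * (1.0 - n) - bn * n)
            gz = p.gates["z"]
            dz = (boltzmann(v, gz["half"], gz["slope"]) - z) / gz["tau"]
            return (dv, dh, dn, dz)
        # ghigliazza_holmes variant
        if len(state) != 3:
            raise ModelError(f"expected 3 state variables, got {len(state)}")
        v, n, s = state
        g = p.gates
        minf = self._fn("minf",
                        lambda vv: boltzmann(vv, g["m"]["half"], g["m"]["slope"]), v)
        i_ca = p.g["Ca"] * minf * (v - p.E["Ca"])
        i_k = p.g["K"] * n * (v - p.E["K"])
        i_ks = p.g["KS"] * s * (v - p.E["K"])
        i_l = p.g["L"] * (v - p.E["L"])
        dv = (p.I + input_current - i_ca - i_k - i_ks - i_l) / p.C
        ninf = self._fn("ninf",
                        lambda vv: boltzmann(vv, g["n"]["half"], g["n"]["slope"]), v)
        sinf = self._fn("sinf",
                        lambda vv: boltzmann(vv, g["s"]["half"], g["s"]["slope"]), v)
        dn = (ninf - n) / g["n"]["tau"]
        ds = (sinf - s) / g["s"]["tau"]
        return (dv, dn, ds)

    def gating_in_bounds(self, state: tuple, slack: float = 1e-9) -> bool:
        return all(-slack <= x <= 1.0 + slack for x in state[1:])


# --------------------------------------------------------------------------
# Lookup tables
# --------------------------------------------------------------------------


class LookupTable:
    """Uniform-grid linear-interpolation table with boundary clamping.

    Evaluation at a node reproduces the tabulated function exactly; queries
    outside [lo, hi] clamp to the boundary values.
    """

    __slots__ = ("lo", "hi", "n_nodes", "values", "_inv_dx")

    def __init__(self, lo: float, hi: float, values):
        if not lo < hi:
            raise ValueError("require lo < hi")
        if len(values) < 2:
            raise ValueError("need at least 2 nodes")
        self.lo = float(lo)
        self.hi = float(hi)
        self.values = tuple(float(v) for v in values)
        self.n_nodes = len(self.values)
        self._inv_dx = (self.n_nodes - 1) / (self.hi - self.lo)

    def __call__(self, x: float) -> float:
        if x <= self.lo:
            return self.values[0]
        if x >= self.hi:
            return self.values[-1]
        u = (x - self.lo) * self._inv_dx
        nearest = round(u)
        if abs(u - nearest) < 1e-9:  # node queries reproduce fn exactly
            return self.values[int(nearest)]
        i = int(u)
        if i >= self.n_nodes - 1:
            return self.values[-1]
        frac = u - i
        return self.values[i] * (1.0 - frac) + self.values[i + 1] * frac

    @property
    def nodes(self) -> tuple:
        dx = (self.hi - self.lo) / (self.n_nodes - 1)
        return tuple(self.lo + i * dx for i in range(self.n_nodes))


def tabulate(fn: Callable[[float], float], lo: float, hi: float,
             n_nodes: int) -> LookupTable:
    """Sample ``fn`` on a uniform grid into a clamping linear table."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    dx = (hi - lo) / (n_nodes - 1)
    values = []
    for i in range(n_nodes):
        x = lo + i * dx
        v = fn(x)
        if not math.isfinite(v):
            raise ValueError(f"non-finite function value {v} at node x={x}")
        values.append(v)
    return LookupTable(lo, hi, values)


# --------------------------------------------------------------------------
# Preset registry
# --------------------------------------------------------------------------

MODEL_CLASSES = {
    "rulkov": RulkovMap,
    "izhikevich": Izhikevich,
    "hindmarsh_rose": HindmarshRose,
    "conductance": ConductanceModel,
}

_PARAM_CLASSES = {
    "rulkov": RulkovParams,
    "izhikevich": IzhikevichParams,
    "hindmarsh_rose": HindmarshRoseParams,
    "conductance": ConductanceParams,
}


def load_presets(kind: str = "neurons") -> dict:
    """Load the stock preset registry (``neurons`` or ``synapses``)."""
    text = resources.files("hybridclamp").joinpath(f"presets/{kind}.yaml").read_text()
    return yaml.safe_load(text)


def from_preset(name: str, overrides: dict | None = None):
    """Instantiate a neuron model from a named stock preset."""
    presets = load_presets("neurons")
    if name not in presets:
        raise KeyError(f"unknown neuron preset {name!r}; have {sorted(presets)}")
    entry = presets[name]
    model_kind = entry["model"]
    params = dict(entry.get("params", {}))
    if overrides:
        params.update(overrides)
    pcls = _PARAM_CLASSES[model_kind]
    p = pcls(**params)
    hints = entry.get("hints")
    h = CalibrationHints(**hints) if hints else None
    model = MODEL_CLASSES[model_kind](p, h)
    if entry.get("tabulate") and isinstance(model, ConductanceModel):
        tb = entry["tabulate"]
        model = model.tabulated(tb.get("lo", -100.0), tb.get("hi", 60.0),
                                tb.get("n_nodes", 10001))
    return model
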