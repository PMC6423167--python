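"""Fixed-step and embedded-pair integration of the ODE neuron models.

States are plain tuples of floats: the per-interval loop advances one small
state at a time, where tuple arithmetic beats array allocation by a wide
margin. Derivative callables have signature ``f(t, y) -> tuple`` and must be
pure.

Four schemes are exposed: forward Euler, Heun (explicit trapezoid), the
classic 4th-order Runge-Kutta, and an embedded 6(5) Runge-Kutta pair
(Verner's 8-stage tableau, as distributed in DVERK) with a PI step-size
controller. The embedded pair additionally returns a per-step local error
estimate; fixed-step schemes return ``None`` in that slot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "IntegratorSpec",
    "integrate_step",
    "integrate_adaptive",
    "select_step",
    "METHODS",
    "VERNER65",
]

DerivFn = Callable[[float, tuple], tuple]


class IntegrationError(ValueError):
    """Raised for non-finite derivatives or an unsatisfiable step search."""


@dataclass(frozen=True)
class IntegratorSpec:
    """Which scheme to run and at what step.

    ``dt`` is in model-time units (whatever the model's equations use).
    ``atol``/``rtol`` and the step bounds apply to the embedded pair only.
    """

    method: str = "rk4"
    dt: float = 1e-3
    atol: float = 1e-8
    rtol: float = 1e-6
    dt_min: float = 1e-12
    dt_max: float = math.inf

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {sorted(METHODS)}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


def _check_finite(dy: Sequence[float], t: float, y: tuple) -> None:
    for v in dy:
        if not math.isfinite(v):
            raise IntegrationError(f"non-finite derivative {dy} at t={t}, state={y}")


def _euler(f: DerivFn, t: float, y: tuple, dt: float) -> tuple:
    k1 = f(t, y)
    _check_finite(k1, t, y)
    return tuple(yi + dt * ki for yi, ki in zip(y, k1))


def _heun(f: DerivFn, t: float, y: tuple, dt: float) -> tuple:
    k1 = f(t, y)
    _check_finite(k1, t, y)
    yp = tuple(yi + dt * ki for yi, ki in zip(y, k1))
    k2 = f(t + dt, yp)
    _check_finite(k2, t + dt, yp)
    return tuple(yi + 0.5 * dt * (a + b) for yi, a, b in zip(y, k1, k2))


def _rk4(f: DerivFn, t: float, y: tuple, dt: float) -> tuple:
    h2 = 0.5 * dt
    k1 = f(t, y)
    _check_finite(k1, t, y)
    k2 = f(t + h2, tuple(yi + h2 * ki for yi, ki in zip(y, k1)))
    k3 = f(t + h2, tuple(yi + h2 * ki for yi, ki in zip(y, k2)))
    k4 = f(t + dt, tuple(yi + dt * ki for yi, ki in zip(y, k3)))
    sixth = dt / 6.0
    return tuple(
        yi + sixth * (a + 2.0 * b + 2.0 * c + d)
        for yi, a, b, c, d in zip(y, k1, k2, k3, k4)
    )


@dataclass(frozen=True)
class EmbeddedTableau:
    """Butcher tableau of an embedded explicit Runge-Kutta pair."""

    c: tuple
    a: tuple  # rows of strictly-lower-triangular coefficients
    b_high: tuple  # higher-order weights (used to advance)
    b_low: tuple  # lower-order weights (error estimate only)
    order_high: int
    order_low: int


# Verner's 6(5) pair (8 stages) — the tableau used by DVERK.
VERNER65 = EmbeddedTableau(
    c=(0.0, 1 / 6, 4 / 15, 2 / 3, 5 / 6, 1.0, 1 / 15, 1.0),
    a=(
        (),
        (1 / 6,),
        (4 / 75, 16 / 75),
        (5 / 6, -8 / 3, 5 / 2),
        (-165 / 64, 55 / 6, -425 / 64, 85 / 96),
        (12 / 5, -8.0, 4015 / 612, -11 / 36, 88 / 255),
        (-8263 / 15000, 124 / 75, -643 / 680, -81 / 250, 2484 / 10625, 0.0),
        (3501 / 1720, -300 / 43, 297275 / 52632, -319 / 2322, 24068 / 84065, 0.0, 3850 / 26703),
    ),
    b_high=(3 / 40, 0.0, 875 / 2244, 23 / 72, 264 / 1955, 0.0, 125 / 11592, 43 / 616),
    b_low=(13 / 160, 0.0, 2375 / 5984, 5 / 16, 12 / 85, 3 / 44, 0.0, 0.0),
    order_high=6,
    order_low=5,
)


def _embedded_step(
    f: DerivFn, t: float, y: tuple, dt: float, tab: EmbeddedTableau = VERNER65
) -> tuple[tuple, float]:
    """One embedded-pair step: returns (y_high, max-norm error estimate)."""
    n = len(tab.c)
    ks: list[tuple] = []
    for i in range(n):
        if i == 0:
            yi = y
        else:
            row = tab.a[i]
            yi = tuple(
                yj + dt * sum(row[m] * ks[m][j] for m in range(i))
                for j, yj in enumerate(y)
            )
        ki = f(t + tab.c[i] * dt, yi)
        _check_finite(ki, t + tab.c[i] * dt, yi)
        ks.append(ki)
    y_high = tuple(
        yj + dt * sum(tab.b_high[m] * ks[m][j] for m in range(n))
        for j, yj in enumerate(y)
    )
    err = max(
        abs(dt * sum((tab.b_high[m] - tab.b_low[m]) * ks[m][j] for m in range(n)))
        for j in range(len(y))
    )
    return y_high, err


METHODS = {
    "euler": _euler,
    "heun": _heun,
    "rk4": _rk4,
    "rk65": None,  # handled specially: returns an error estimate
}


def integrate_step(
    spec: IntegratorSpec, derivs: DerivFn, state: tuple, t: float, dt: float | None = None
) -> tuple[tuple, float | None]:
    """Advance one step of the scheme named in ``spec``.

    Returns ``(new_state, error_estimate)``; the estimate is ``None`` for
    fixed-step methods. Exact on constant-derivative systems for every
    method. ``dt`` overrides ``spec.dt`` when given.
    """
    h = spec.dt if dt is None else dt
    if not h > 0:
        raise ValueError("dt must be positive")
    if spec.method == "rk65":
        y, err = _embedded_step(derivs, t, state, h)
        return y, err
    return METHODS[spec.method](derivs, t, state, h), None


def integrate_adaptive(
    spec: IntegratorSpec,
    derivs: DerivFn,
    state: tuple,
    t0: float,
    t1: float,
    dt0: float | None = None,
) -> tuple[tuple, int]:
    """Adaptive embedded-pair integration from ``t0`` to ``t1``.

    PI step control: accepted steps satisfy ``err <= atol + rtol*|y|``;
    the new step is ``h * min(5, max(0.2, 0.9*(tol/err)^(1/6)))`` damped by
    the previous ratio. Returns the final state and the accepted-step count.
    """
    if spec.method != "rk65":
        raise ValueError("adaptive driver requires method 'rk65'")
    t, y = t0, state
    h = min(dt0 or spec.dt, t1 - t0)
    n_accepted = 0
    prev_ratio = 1.0
    while t < t1 - 1e-15 * max(1.0, abs(t1)):
        h = min(h, t1 - t)
        h = max(h, spec.dt_min)
        y_new, err = _embedded_step(derivs, t, y, h)
        tol = spec.atol + spec.rtol * max(abs(v) for v in y)
        if err <= tol or h <= spec.dt_min * (1 + 1e-9):
            t += h
            y = y_new
            n_accepted += 1
            ratio = (tol / err) ** (1 / 6) if err > 0 else 5.0
            # PI controller: damp with the previous ratio's history
            fac = 0.9 * ratio * prev_ratio**0.08
            prev_ratio = min(ratio, 5.0)
            h = min(h * min(5.0, max(0.2, fac)), spec.dt_max)
        else:
            h = max(h * max(0.2, 0.9 * (tol / err) ** (1 / 6)), spec.dt_min)
    return y, n_accepted


def select_step(
    spec: IntegratorSpec,
    derivs: DerivFn,
    state: tuple,
    interval_budget: float,
    probe_time: float,
    is_stable: Callable[[tuple], bool] | None = None,
    events: Callable[[tuple], tuple] | None = None,
    n_cap: int = 64,
) -> tuple[int, float]:
    """Pick the fewest sub-steps per loop interval that integrate stably.

    ``interval_budget`` is the model time that must be advanced per
    real-time interval; the probe simulates ``probe_time`` of model time
    (one calibrated burst, typically) at ``dt_sub = budget/n`` and rejects a
    candidate on any non-finite value, blow-up (|state| > 1e6) or failure of
    the optional model-specific ``is_stable`` predicate (used to keep gating
    variables inside [0, 1]). Candidates are scanned 1..8 then by doubling
    up to ``n_cap``; the search is deterministic.
    """
    if not interval_budget > 0:
        raise ValueError("interval_budget must be positive")
    candidates = list(range(1, 9)) + [16, 32, 64, 128, 256]
    for n in candidates:
        if n > n_cap:
            break
        dt_sub = interval_budget / n
        if _probe(spec, derivs, state, dt_sub, probe_time, is_stable, events):
            return n, dt_sub
    raise IntegrationError(
        f"no sub-step count <= {n_cap} integrates {probe_time} model-time units "
        f"stably with budget {interval_budget}"
    )


def _probe(spec, derivs, state, dt_sub, probe_time, is_stable, events=None) -> bool:
    method = spec.method if spec.method != "rk65" else "rk4"
    step = METHODS[method]
    y = state
    t = 0.0
    n_steps = max(1, int(math.ceil(probe_time / dt_sub)))
    try:
        for _ in range(n_steps):
            y = step(derivs, t, y, dt_sub)
            if events is not None:
                y = events(y)
            t += dt_sub
            for v in y:
                if not math.isfinite(v) or abs(v) > 1e6:
                    return False
            if is_stable is not None and not is_stable(y):
                return False
    except IntegrationError:
        return False
    return True
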