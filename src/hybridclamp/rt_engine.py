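"""Periodic-loop engine: absolute-schedule iteration, latency accounting,
overrun recovery, and the non-blocking writer channel.

The real-time contract is expressed against a ``ClockSource``. The
*virtual* clock makes the scheduling semantics exactly testable: task
durations are scripted (constant, per-iteration overrides, or seeded
distributions) and time advances deterministically, so latency, sleep and
overrun behaviour are reproducible to the bit. The *wall* clock is
best-effort soft real-time on a general-purpose OS: statistics are
produced, but no hard bound is asserted.

Scheduling semantics:

* deadlines form the fixed arithmetic sequence ``t0 + k/fs`` and are never
  re-based — after an overrun the following iterations wake immediately
  (sleep shrunk or skipped) until the loop catches back up to the anchored
  schedule, preserving data cadence;
* each iteration performs its tasks in the configured order (acquisition
  exchange, drift compensation, synapse models, neuron model, enqueue for
  the writer) and then sleeps until the next deadline;
* every iteration yields one interval record (columnar storage, so
  multi-million-interval runs stay cheap).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LoopSchedule",
    "IntervalRecord",
    "LoopLog",
    "VirtualClock",
    "WallClock",
    "DurationModel",
    "WriterChannel",
    "run_loop",
    "latency_stats",
    "LatencySummary",
    "benchmark_toggle",
]


@dataclass(frozen=True)
class LoopSchedule:
    """Fixed-period schedule: deadline of iteration k is ``t0 + k/fs``."""

    fs: float
    t0: float = 0.0

    def __post_init__(self):
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def period(self) -> float:
        return 1.0 / self.fs

    def deadline(self, k: int) -> float:
        return self.t0 + k * self.period

    def n_intervals(self, duration: float) -> int:
        """Number of loop iterations in ``duration`` seconds."""
        return int(round(duration * self.fs))


@dataclass(frozen=True)
class IntervalRecord:
    """One loop iteration, reconstructed from the columnar log."""

    index: int
    scheduled: float
    wake: float
    durations: dict
    sleep: float
    overrun: bool

    @property
    def latency(self) -> float:
        return self.wake - self.scheduled


class LoopLog:
    """Columnar per-interval log of a loop run."""

    def __init__(self, op_names: Sequence[str], n: int):
        self.op_names = list(op_names)
        self.scheduled = np.empty(n)
        self.wake = np.empty(n)
        self.op_durations = np.empty((n, len(self.op_names)))
        self.sleep = np.empty(n)
        self.overrun = np.zeros(n, dtype=bool)
        self.count = 0
        self.error: Exception | None = None

    @property
    def latency(self) -> np.ndarray:
        return self.wake[: self.count] - self.scheduled[: self.count]

    def record(self, k: int) -> IntervalRecord:
        if k >= self.count:
            raise IndexError(k)
        return IntervalRecord(
            index=k,
            scheduled=float(self.scheduled[k]),
            wake=float(self.wake[k]),
            durations={name: float(self.op_durations[k, i])
                       for i, name in enumerate(self.op_names)},
            sleep=float(self.sleep[k]),
            overrun=bool(self.overrun[k]),
        )

    def records(self) -> list[IntervalRecord]:
        return [self.record(k) for k in range(self.count)]

    def to_frame(self, every: int = 1):
        """Latency log as a DataFrame, one row per interval.

        ``every`` thins the log (keep every n-th interval) for long runs.
        """
        import pandas as pd

        sel = np.arange(0, self.count, max(1, every))
        data = {
            "index": sel,
            "scheduled": self.scheduled[sel],
            "wake": self.wake[sel],
            "latency": self.wake[sel] - self.scheduled[sel],
        }
        for i, name in enumerate(self.op_names):
            data[f"dur_{name}"] = self.op_durations[sel, i]
        data["sleep"] = self.sleep[sel]
        data["overrun"] = self.overrun[sel]
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# Clocks
# --------------------------------------------------------------------------


class VirtualClock:
    """Deterministic simulated clock.

    ``advance`` models computation taking time; ``sleep_until`` never
    wakes early and wakes *late* only if time has already passed the
    target — exactly the anchored-deadline overrun semantics.
    """

    kind = "virtual"

    def __init__(self, t0: float = 0.0):
        self.t = t0

    def now(self) -> float:
        return self.t

    def advance(self, dt: float) -> None:
        if dt < 0:
            raise ValueError("cannot advance backwards")
        self.t += dt

    def sleep_until(self, target: float) -> float:
        if target > self.t:
            self.t = target
        return self.t


class WallClock:
    """Best-effort OS timing (soft real-time only)."""

    kind = "wall"

    def __init__(self):
        self._origin = time.perf_counter()

    def now(self) -> float:
        return time.perf_counter() - self._origin

    def sleep_until(self, target: float) -> float:
        # coarse sleep, then a short spin for precision
        while True:
            remaining = target - self.now()
            if remaining <= 0:
                return self.now()
            if remaining > 2e-4:
                time.sleep(remaining - 1e-4)
            else:
                pass  # spin


class DurationModel:
    """Scripted per-operation durations for the virtual clock.

    ``base`` gives each operation's nominal duration (seconds; missing
    names default to 0). ``overrides`` maps ``(op_name, iteration)`` to a
    duration, for injecting one-off overruns. ``jitter`` maps op names to
    an exponential-jitter scale added on top, drawn from ``seed``.
    """

    def __init__(self, base: dict | None = None,
                 overrides: dict | None = None,
                 jitter: dict | None = None, seed: int | None = None):
        self.base = dict(base or {})
        self.overrides = dict(overrides or {})
        self.jitter = dict(jitter or {})
        self._rng = np.random.default_rng(seed)

    def __call__(self, name: str, k: int) -> float:
        if (name, k) in self.overrides:
            return float(self.overrides[(name, k)])
        d = float(self.base.get(name, 0.0))
        if name in self.jitter:
            d += float(self._rng.exponential(self.jitter[name]))
        return d


# --------------------------------------------------------------------------
# Writer channel
# --------------------------------------------------------------------------


class WriterChannel:
    """Bounded-cost FIFO between the loop and the (non-RT) writer.

    ``put`` is amortized O(1) and never blocks the loop; ``drain`` yields
    everything enqueued so far in FIFO order. After ``close``, puts are
    rejected and drains return empty.
    """

    def __init__(self):
        from collections import deque

        self._q = deque()
        self.closed = False

    def put(self, item) -> None:
        if self.closed:
            raise RuntimeError("channel closed")
        self._q.append(item)

    def drain(self) -> list:
        out = list(self._q)
        self._q.clear()
        return out

    def close(self) -> None:
        self.closed = True
        self._q.clear()

    def __len__(self) -> int:
        return len(self._q)


# --------------------------------------------------------------------------
# The loop
# --------------------------------------------------------------------------


ENQUEUE_OP = "enqueue"


def run_loop(
    schedule: LoopSchedule,
    tasks: Sequence[tuple[str, Callable[[int], object] | None]],
    clock,
    n_iterations: int,
    duration_model: DurationModel | None = None,
    writer: WriterChannel | None = None,
    payload: Callable[[int], object] | None = None,
) -> LoopLog:
    """Run the periodic loop for ``n_iterations`` anchored intervals.

    ``tasks`` is the ordered list of (name, callable) pairs executed every
    iteration; callables receive the iteration index (``None`` is allowed
    for pure-timing runs). On the virtual clock each task additionally
    advances time by ``duration_model(name, k)``. After the tasks, the
    payload (if any) is enqueued on ``writer`` — timed as the 'enqueue'
    operation — and the loop sleeps until the next anchored deadline; if
    that deadline has already passed the next iteration wakes immediately.

    A task raising stops the loop cleanly: the partial log is returned
    with the exception recorded in ``log.error``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    op_names = ["wake_latency"] + [name for name, _ in tasks] + [ENQUEUE_OP]
    log = LoopLog(op_names, n_iterations)
    virtual = getattr(clock, "kind", "wall") == "virtual"
    period = schedule.period
    for k in range(n_iterations):
        deadline = schedule.deadline(k)
        wake = clock.sleep_until(deadline)
        log.scheduled[k] = deadline
        log.wake[k] = wake
        log.op_durations[k, 0] = wake - deadline  # wake latency
        col = 1
        try:
            for name, fn in tasks:
                t_start = clock.now()
                if fn is not None:
                    fn(k)
                if virtual and duration_model is not None:
                    clock.advance(duration_model(name, k))
                log.op_durations[k, col] = clock.now() - t_start
                col += 1
            t_start = clock.now()
            if writer is not None:
                writer.put(payload(k) if payload is not None else k)
            if virtual and duration_model is not None:
                clock.advance(duration_model(ENQUEUE_OP, k))
            log.op_durations[k, col] = clock.now() - t_start
        except Exception as exc:  # noqa: BLE001 - loop contract: stop cleanly
            log.op_durations[k, col:] = 0.0
            log.sleep[k] = 0.0
            log.error = exc
            log.count = k
            return log
        finish = clock.now()
        next_deadline = deadline + period
        log.sleep[k] = max(0.0, next_deadline - finish)
        log.overrun[k] = finish > next_deadline
        log.count = k + 1
    return log


# --------------------------------------------------------------------------
# Latency statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LatencySummary:
    n: int
    min: float
    max: float
    mean: float
    std: float
    jitter: float  # max - min
    failures: int  # latencies above the threshold (one period, typically)
    fail_threshold: float
    hist_counts: tuple
    hist_edges: tuple

    def __str__(self) -> str:  # appended to the experiment log
        us = 1e6
        return (
            f"latency n={self.n}  min={self.min*us:.3f}us  max={self.max*us:.3f}us  "
            f"mean={self.mean*us:.3f}+/-{self.std*us:.3f}us  "
            f"jitter={self.jitter*us:.3f}us  "
            f"failures(>{self.fail_threshold*us:.0f}us)={self.failures}"
        )


def latency_stats(latencies, fail_threshold: float,
                  n_bins: int = 50) -> LatencySummary:
    """Summarize latencies (seconds): min/max/mean±std, jitter, failures.

    ``fail_threshold`` is the real-time constraint — one loop period
    (e.g. 50 µs at 20 kHz); latencies above it count as failures.
    Histogram counts are intended for log-scaled count axes.
    """
    if hasattr(latencies, "latency"):  # accept a LoopLog directly
        latencies = latencies.latency
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        raise ValueError("no latencies to summarize")
    counts, edges = np.histogram(lat, bins=n_bins)
    return LatencySummary(
        n=int(lat.size),
        min=float(lat.min()),
        max=float(lat.max()),
        mean=float(lat.mean()),
        std=float(lat.std()),
        jitter=float(lat.max() - lat.min()),
        failures=int(np.count_nonzero(lat > fail_threshold)),
        fail_threshold=float(fail_threshold),
        hist_counts=tuple(int(c) for c in counts),
        hist_edges=tuple(float(e) for e in edges),
    )


# --------------------------------------------------------------------------
# Benchmark loop
# --------------------------------------------------------------------------


def benchmark_toggle(fs: float, duration: float, clock=None,
                     duration_model: DurationModel | None = None
                     ) -> tuple[LoopLog, np.ndarray]:
    """The classic latency benchmark: toggle a binary output every interval.

    At frequency ``fs`` the toggled output is a square wave of period
    ``2/fs`` (two samples per cycle). Returns the loop log and the emitted
    0/1 samples.
    """
    schedule = LoopSchedule(fs=fs)
    n = schedule.n_intervals(duration)
    out = np.empty(n, dtype=np.int8)

    def toggle(k: int) -> None:
        out[k] = k & 1

    clock = clock if clock is not None else VirtualClock()
    log = run_loop(schedule, [("toggle_output", toggle)], clock, n,
                   duration_model=duration_model)
    return log, out
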