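"""The classic real-time latency benchmark: toggle a digital output.

Runs the 20 kHz toggle loop (a 100 µs square wave, two samples per cycle)
on the deterministic virtual clock with scripted exponential jitter, and
on the wall clock of this machine (soft real-time: statistics only, no
hard guarantee). Latencies above one period (50 µs at 20 kHz) count as
real-time failures.
"""

from hybridclamp import DurationModel, VirtualClock, WallClock, benchmark_toggle, latency_stats

fs, duration = 20000.0, 2.0

log, out = benchmark_toggle(fs, duration, clock=VirtualClock(),
                            duration_model=DurationModel(
                                jitter={"toggle_output": 15e-6}, seed=0))
print(f"virtual clock: {log.count} intervals, square-wave period "
      f"{2.0 / fs * 1e6:.0f} us")
print(" ", latency_stats(log, fail_threshold=1.0 / fs))

log, out = benchmark_toggle(fs, 0.25, clock=WallClock())
print(f"wall clock:    {log.count} intervals (soft real-time, this machine)")
print(" ", latency_stats(log, fail_threshold=1.0 / fs))
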