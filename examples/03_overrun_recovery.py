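"""Overrun recovery on the anchored schedule.

One iteration's neuron-model computation is scripted to take 140 µs inside
a 100 µs (10 kHz) schedule. The loop borrows time from the next iteration
— which wakes 40 µs late with its sleep shortened — and is back on the
fixed deadline grid one interval later. Deadlines are never re-based.
"""

from hybridclamp import DurationModel, LoopSchedule, VirtualClock, run_loop

N = 5
schedule = LoopSchedule(fs=10000.0)
dm = DurationModel(overrides={("neuron_model", N): 140e-6})
log = run_loop(schedule, [("neuron_model", None)], VirtualClock(), 10,
               duration_model=dm)

print("iter  scheduled(us)  wake(us)  latency(us)  sleep(us)  overrun")
for k in range(10):
    r = log.record(k)
    print(f"{k:4d} {r.scheduled * 1e6:12.0f} {r.wake * 1e6:10.0f}"
          f" {r.latency * 1e6:11.1f} {r.sleep * 1e6:10.1f}   {r.overrun}")
print()
print(f"iteration {N} overruns by 40 us; iteration {N + 1} wakes 40 us late")
print(f"and sleeps less; iteration {N + 2} is back on schedule.")
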