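# Stock neuron presets. Every preset must free-run in a bursting regime
# (property-tested); parameter values are the package's own bursting
# defaults, configurable per experiment. Hints are in model time units.

rulkov_burster:
  model: rulkov
  params: {alpha: 4.5, sigma: 0.005, mu: 0.001}
  hints: {dt: 1.0, free_run_time: 60000, transient: 10000, min_gap: 100}

izhikevich_burster:
  model: izhikevich
  params: {a: 0.02, b: 0.2, c: -50.0, d: 2.0, I: 15.0, peak: 30.0}
  hints: {dt: 0.05, free_run_time: 2000.0, transient: 400.0, min_gap: 20.0}

hindmarsh_rose_burster:
  model: hindmarsh_rose
  params: {b: 3.0, I: 2.7, r: 0.005, s: 4.0, x_rest: -1.6}
  hints: {dt: 0.02, free_run_time: 6000.0, transient: 1500.0, min_gap: 80.0}

ghigliazza_holmes_burster:
  model: conductance
  params:
    variant: ghigliazza_holmes
    C: 20.0
    I: 46.0
    g: {Ca: 4.0, K: 8.0, KS: 0.4, L: 2.0}
    E: {Ca: 120.0, K: -84.0, L: -60.0}
    gates:
      m: {half: -1.2, slope: 9.0}
      n: {half: 12.0, slope: 8.7, tau: 4.0}
      s: {half: -20.0, slope: 5.0, tau: 1500.0}
  hints: {dt: 0.05, free_run_time: 15000.0, transient: 3000.0, min_gap: 250.0}

wang_burster:
  model: conductance
  params:
    variant: wang
    C: 1.0
    I: 0.0
    g: {Na: 35.0, NaP: 0.8, K: 9.0, Z: 1.5, L: 0.1}
    E: {Na: 55.0, K: -90.0, L: -65.0}
    gates:
      h: {phi: 5.0}
      n: {phi: 5.0}
      p: {half: -51.0, slope: 4.0}
      z: {half: -50.0, slope: 4.0, tau: 250.0}
  hints: {dt: 0.01, free_run_time: 8000.0, transient: 1000.0, min_gap: 100.0}

# Tabulated twin of the expensive model (high-resolution nonlinearity tables)
wang_burster_tabulated:
  model: conductance
  params:
    variant: wang
    C: 1.0
    I: 0.0
    g: {Na: 35.0, NaP: 0.8, K: 9.0, Z: 1.5, L: 0.1}
    E: {Na: 55.0, K: -90.0, L: -65.0}
    gates:
      h: {phi: 5.0}
      n: {phi: 5.0}
      p: {half: -51.0, slope: 4.0}
      z: {half: -50.0, slope: 4.0, tau: 250.0}
  hints: {dt: 0.01, free_run_time: 8000.0, transient: 1000.0, min_gap: 100.0}
  tabulate: {lo: -100.0, hi: 60.0, n_nodes: 10001}
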