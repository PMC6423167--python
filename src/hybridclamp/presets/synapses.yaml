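# Stock synapse presets. Graded thresholds/slopes are fractions of the
# presynaptic amplitude range, resolved at calibration time; a null E_syn
# defers the reversal to the observed postsynaptic minimum (guaranteed
# inhibitory). The four validation configurations pair a slow inhibitory
# graded synapse (model -> living) with a fast inhibitory graded synapse
# (living -> model); fast-synapse conductance depends on the model.

slow_inhibitory_graded:
  kind: graded
  params: {g: 0.2, v_threshold_pct: 0.15, slope_pct: 0.01, E_syn: null,
           k1: 14.0, k2: 4.0, mode: slow}

slow_inhibitory_graded_hr:
  kind: graded
  params: {g: 0.1, v_threshold_pct: 0.15, slope_pct: 0.01, E_syn: null,
           k1: 14.0, k2: 4.0, mode: slow}

fast_inhibitory_graded:
  kind: graded
  params: {g: 0.8, v_threshold_pct: 0.5, slope_pct: 0.05, E_syn: null,
           mode: fast}

fast_inhibitory_graded_hr:
  kind: graded
  params: {g: 1.0, v_threshold_pct: 0.5, slope_pct: 0.05, E_syn: null,
           mode: fast}

fast_inhibitory_graded_rulkov:
  kind: graded
  params: {g: 0.2, v_threshold_pct: 0.5, slope_pct: 0.05, E_syn: null,
           mode: fast}

gap_junction:
  kind: electrical
  params: {g: 0.1}

chemical_fast_inhibitory:
  kind: chemical
  params: {g: 0.5, E_syn: -80.0, alpha: 0.94, beta: 0.18, T_max: 1.0,
           pulse_duration: 1.0}
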