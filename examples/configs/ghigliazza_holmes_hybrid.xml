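<?xml version='1.0' encoding='UTF-8'?>
<hybrid_experiment version="1">
  <timing fs="10000.0" pre_s="10.0" coupled_s="60.0" post_s="10.0"/>
  <neuron preset="ghigliazza_holmes_burster"/>
  <synapse direction="model_to_live" preset="slow_inhibitory_graded"/>
  <synapse direction="live_to_model" preset="fast_inhibitory_graded"/>
  <integrator method="rk4"/>
  <calibration target_burst="auto" online_refresh="false" frac_on="0.25" frac_off="0.15" min_gap_s="0.1" drift_compensation="false" drift_window_s="0.2" drift_alpha="0.2"/>
  <scaling input_factor="100.0" nA_per_V="10.0"/>
  <preparation preset="hindmarsh_rose_burster" period_s="1.0" range_min="-62.0" range_max="-30.0" noise_sd="0.5" drift="0.0"/>
  <seeds master="1"/>
</hybrid_experiment>
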