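"""A full hybrid-circuit experiment against the virtual preparation.

Control-coupled-control protocol at 10 kHz: 10 s of uncoupled pre-control
(the calibration window), 30 s with bidirectional inhibitory graded
synapses (slow model->live, fast live->model), 5 s post-control. The
target behaviour is a rhythmic antiphase alternation between the model
and the "living" cell: a burst-onset phase index near 0.5.

Loading the same configuration from XML (examples/configs/) and the CLI
`hybridclamp run` are equivalent entry points.
"""

from hybridclamp.experiment_runner import (
    ExperimentConfig,
    VALIDATION_PRESETS,
    coupled_antiphase,
    run_experiment,
)

neuron, syn_ml, syn_lm = VALIDATION_PRESETS["hindmarsh_rose"]
config = ExperimentConfig(fs=10000.0, pre_s=10.0, coupled_s=30.0, post_s=5.0,
                          neuron_preset=neuron, syn_model_to_live=syn_ml,
                          syn_live_to_model=syn_lm, seed=1)
result = run_experiment(config)

print(result.log_text)
median, dispersion = coupled_antiphase(result, config)
print(f"antiphase index: {median:.3f} (circular dispersion {dispersion:.3f})")
print("0.5 = model bursts exactly half a cycle after the living neuron;")
print("values in ~[0.35, 0.65] with low dispersion indicate a robust")
print("antiphase half-center rhythm.")

coupled = result.trace[result.trace.phase == "coupled"]
print(f"\npeak synaptic currents: model->live "
      f"{coupled.i_model_to_live_nA.abs().max():.2f} nA, live->model "
      f"{coupled.i_live_to_model_nA.abs().max():.2f} nA "
      f"(exactly 0 in both control phases)")
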