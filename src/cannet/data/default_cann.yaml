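cans_per_stream_layer: 2
init_weight_scale: 0.1
input_gain: 1.25
lateral_rule: neighboring-streams-same-layer
n_layers: 3
n_lcf_inputs: 4
n_outputs: 1
n_rf_inputs: 4
n_streams: 2
n_ucf_units: 8
output_r_sink: 1.0
seed: 0
stability_margin: 0.8
ucf_rule: broadcast-to-all-cans
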