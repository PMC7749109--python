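# Stress feed-forward experiment at the study scale.
experiment = stress_ff
n_models = 124
n_test = 20
component = ff
epochs = 300
seed = 0
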