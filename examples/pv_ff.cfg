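# Pressure/volume feed-forward experiment at the study scale.
experiment = pv_ff
n_models = 80
n_test = 6
target = volume
seed = 0
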