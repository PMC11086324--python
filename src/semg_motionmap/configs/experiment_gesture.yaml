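experiment: gesture
n_per_class: 200
overlap: 0.3
seed: 11
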