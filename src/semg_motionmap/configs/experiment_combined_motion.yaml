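experiment: combined_motion
seed: 11
epochs: 600
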