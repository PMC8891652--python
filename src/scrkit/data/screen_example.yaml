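# Generator config for a 12-replicate efficiency screen with ground truth
# matching a mid-range reassigning system.
seed: 42
true_efficiency: 0.569
n_replicates: 12
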