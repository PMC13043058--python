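experiment: fig5_generalization
study:
  name: generalization
  params:
    n_seeds: 20
seeds: {n_seeds: 20, master_seed: 0}
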