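experiment: fig11_doors
study:
  name: doors
  params:
    n_seeds: 30
    pre_trials: 50
    learn_trials: 50
seeds: {n_seeds: 30, master_seed: 0}
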