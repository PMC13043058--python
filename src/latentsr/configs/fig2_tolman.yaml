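experiment: fig2_tolman
study:
  name: designs
  params:
    environment: tolman-onehot-72
    designs: [targeted, direct]
seeds: {n_seeds: 30, master_seed: 0}
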