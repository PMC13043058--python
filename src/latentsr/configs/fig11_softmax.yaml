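experiment: fig11_softmax
study:
  name: designs
  params:
    designs: [direct, targeted, continuous, mistargeted]
    policy: {kind: softmax, beta: 1.0}
seeds: {n_seeds: 30, master_seed: 0}
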