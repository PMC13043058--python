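experiment: fig7_designs_dsr_image
study:
  name: designs
  params:
    feature_kind: image-like
    D: 256
    designs: [direct, targeted, continuous, mistargeted]
seeds: {n_seeds: 30, master_seed: 0}
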