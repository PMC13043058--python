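experiment: gridworld_targeted
environment: {kind: gridworld, width: 10, height: 10}
features: {kind: onehot}
agent: {kind: dsr}
design: {name: targeted, pre_trials: 50, learn_trials: 50}
policy: {kind: epsilon-greedy, epsilon: 0.3}
doors: {pre: false, learn: false}
seeds: {n_seeds: 30, master_seed: 0}
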