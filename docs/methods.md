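# Methods

This note documents the models, the synthetic environments and
features, the parameter choices, and the numerical decisions behind
`latentsr`. It is the place to look when a default seems arbitrary or a
simulation result needs interpreting.

## The model

### Successor representation

An agent in a discrete maze chooses among the four compass moves
(masked so wall- or door-violating moves are never available) and seeks
to maximize discounted reward, `Q(s,a) = E[Σ_t γ^t R(s_t)]`. The
successor representation factors this value into a reward-independent
transition summary and a reward estimate. The tabular form stores
`M(s, s', a)`, the expected discounted number of future visits to `s'`
after taking `a` in `s` under the running policy. `M` obeys a Bellman
recursion and is learned by the temporal-difference rule

    M(s, ·, a) ← M(s, ·, a) + α [ e_s + γ M(s', ·, a*) − M(s, ·, a) ].

Given `M`, values follow as `Q(s,a) = Σ_s' M(s, s', a) R(s')`. Because
`M` is policy-dependent, the *statistics of exploration* are imprinted
on the map — the property the whole study turns on: pre-exposure
designs that shape behavior differently leave different maps, and those
maps produce different reward-learning speed once reward appears.

### Deep successor features

The feature-based form replaces states by feature vectors `φ(s)` (rows
of a matrix `Φ`, one per state). One map per action sends `φ(s)` to a
successor-feature vector `m(s, a)` — the expected discounted future sum
of features — and a separate linear head with weights `w` (no bias)
predicts the reward of a state from its features, so
`Q(s, a) ≈ m(s, a) · w`. The SF maps default to a single linear layer
per action (no bias): this is the smallest architecture that expresses
the factorization, makes the model *exactly* the tabular SR when
features are one-hot (which the test-suite exploits for oracle
equivalence), and keeps the occupancy read-out well posed. A
one-hidden-layer ReLU variant is available (`hidden=` parameter) but is
not part of any packaged study.

The per-state occupancy structure is recovered from a trained model by
least squares: stacking the SF vectors of all states into `M_Φ^a` and
solving `M_Φ^a = C^a Φ` via the state-feature Gram matrix `Φ Φᵀ`. Row
`i` of `C^a` estimates the expected visitation frequencies from state
`i`; for one-hot features the extraction is exact. The Gram matrix must
be invertible, i.e. the state features must be linearly independent —
the feature generator enforces this.

### Learning by replay, and the goal cage

Every experienced tuple `(s, a, s', r)` is appended to a buffer that
never evicts; one uniformly sampled batch (32 tuples) is replayed after
every environment step, updating both the SF maps (TD targets
`φ(s) + γ m(s', a*)`, with `a*` the greedy bootstrap action over
allowed moves; an on-policy bootstrap is a config switch) and the
reward head (squared error of `φ(s')·w` against `r`).

Whenever a trial ends at its terminal landmark (the goal; the
mistargeted landmark during mistargeted pre-exposure), one
self-transition per action `(g, a, g, r_phase)` is appended and
immediately replayed — emulating the animal's confinement in the goal
cage after a trial. This anchors the landmark's own successor feature
at its fixed point `φ(g)/(1−γ)` and, with one-hot codes, amplifies the
goal entry of every state's occupancy row as learning propagates it.
Ablation flags reproduce the failure modes: `zero_vector_goal`
regresses the goal SF to the zero vector, and `goal_replay=False`
disables the injection; both markedly slow or abolish task mastery.
The injected batch is replayed `n_goal_replays` times (default 1).

### Dyna-DQN baseline

The control agent shares environments, policies, buffer, step caps and
seeding but learns `Q` directly: a linear map from `φ(s)` to per-action
values, trained by Q-learning with (i) a direct update on each real
transition, (ii) one planning batch per step drawn uniformly from the
remembered transitions, and (iii) bootstrap values from a target-weight
copy synced every 200 updates, with zero bootstrap at the trial's
terminal state. The direct-RL step and target network matter: without
them, replay-composition differences between pre-exposure designs leak
into early reward learning and the baseline spuriously mimics the SR's
design sensitivity. With them the baseline learns the tasks but shows
no significant targeted-vs-continuous difference — the contrast the
design comparison needs. The baseline is run with image-like features
in the packaged design-comparison study.

## Environments

Two maze families are generated in code; there are no external data.

* **Gridworld** — an open `10×10` arena (300-step trial cap). Start is
  in the bottom-left region `(1,8)`, goal top-right `(8,1)`, the
  mistargeted landmark in the far bottom-right `(8,8)`, and four
  intermediate start cells are spread over the arena; all positions are
  configurable. An `8×6` variant hosts the generalization probe.
* **Tolman-style T-maze** — a 14-choice-unit serpentine maze shipped as
  a plain-text layout: a 72-state variant (three-cell blind alleys,
  1500-step cap, one-hot features) and a coarse 30-state variant
  (one-cell alleys, 150-step cap, image-like features). One-way door
  cells along the goal-ward corridor remove, when doors are enabled,
  exactly the reverse direction of their passage edges. The historical
  apparatus's exact corridor geometry is not published; the packaged
  layout reproduces the features the results depend on — choice points,
  dead ends, a single goal path, door direction — and is swappable via
  the maze-file loader.

Trials end on arrival at the active design's terminal state or at the
step cap; timeouts record latency equal to the cap and no success.
Reward (5.0) is paid only on goal arrival during the learning phase.

## State features

One-hot codes are the `N×N` identity. The image-like generator stands
in for a pretrained convolutional embedding of rendered views and
reproduces the two properties the pipeline uses: nearby states have
similar features, and all features are linearly independent. Each of
`D` dimensions is a draw from a Gaussian process over the maze
coordinates (squared-exponential kernel, length scale 2 grid units) and
rows are normalized to unit length, so cosine similarity between states
falls off smoothly with distance (Spearman correlation with negative
path distance > 0.5 on the 10×10 arena). `D` defaults to 2048,
mirroring a flattened 1×4×512 conv-net output; studies that train on
image-like features use `D = 128–256`, far above the rank requirement
(`D ≥ N`) while keeping the linear SF maps small. An externally
computed `N×D` matrix can be substituted directly via `FeatureMap`.

## Task designs

Pre-exposure (50 trials, unrewarded) precedes learning (50 trials,
rewarded), with trial indices `−50…−1` and `0…49`:

* **direct** — no pre-exposure;
* **targeted** — pre-exposure trials start at `s` and end at the
  (unrewarded) future goal;
* **continuous** — pre-exposure trials start uniformly over the
  intermediate cells, `s` and `g`, and always last the full step cap;
* **mistargeted** — trials end at the non-goal landmark `m`
  (gridworld only).

The learning phase is identical across designs. Parameter snapshots
are taken at trials −50, 0 and 50, matching the analysis points.

## Parameters

| parameter | default | notes |
| --- | --- | --- |
| discount `γ` | 0.9 | maze diameters ≈ 15–30 steps; results are not sensitive to the exact value |
| SF learning rate | 0.05 | calibrated so every design masters the gridworld within the 50 learning trials |
| reward-head learning rate | 0.2 | fast reward acquisition; at slower rates the pre-exposed agents' sparse reward tuples are drowned out by their large unrewarded buffers and the continuous design loses its advantage over direct learning |
| batch size / cadence | 32, one batch per step | uniform over the whole buffer |
| goal-replay passes | 1 | per goal-terminated trial |
| ε (ε-greedy) | 0.3 | exploration policy of the main studies |
| β (softmax) | 1.0 | used in the door experiment |
| initialization | Glorot uniform | both SF maps and reward head; `zeros` option for oracle-equivalence work |

## Numerical choices

* **Step-size clipping.** Batch gradients are summed, so `k` samples
  hitting the same table row advance it by `lr·k` times the mean error
  — a divergent iteration once `lr·k > 2` (tiny buffers at trial
  starts; door-pocket dwelling makes it sustained). One-hot updates
  clip each row's effective step at 1; dense-feature updates clip by
  the batch Gram matrix's largest eigenvalue, the exact stability
  quantity for correlated rows. Non-pathological updates are
  bit-identical to the raw rule.
* **Ties.** Greedy action ties are broken uniformly at random with the
  policy RNG during action selection and by lowest index in recorded
  greedy-policy tables.
* **Seeding.** A master seed plus a CRC of the condition label plus the
  replicate index feed a `SeedSequence`, so a condition's stream is
  identical no matter which batch it runs in, and conditions are
  mutually independent.
* **Oracle convergence.** The closed-form SR solves
  `(I − γP)V = I`; the TD route to the same fixed point uses expected
  synchronous sweeps (error contracts by γ per sweep), since sampled
  constant-step TD has a noise floor far above the comparison
  tolerance.

## Study scales

The full study conditions are 30 simulations and 50 + 50 trials. The
packaged reduced scales, used where full scale is disproportionate:
Tolman optimality, 6 seeds × 15 pre-exposure trials (continuous trials
cost 1500 steps each); door experiment, 10 seeds × 20 pre-exposure +
50 learning trials at the 500-step cap (the door-transfer effect
unfolds late in learning); ablation, 10 seeds; generalization probe,
20 seeds with `D = 128`. The CLI's `--scale smoke` shrinks any
experiment to 5 seeds × 15 trials for quick end-to-end checks.

## What the synthetic data does and does not show

The generators emulate the *structure* of the modelled experiments —
maze topology, door constraints, unrewarded exploration statistics,
distance-graded perceptual similarity — not real sensory input or
animal behavior. Passing tests establish that the successor-based
mechanism produces the claimed behavioral and representational
patterns under these idealized conditions; they say nothing about
parameter values fitted to animals, and the image-like features omit
every property of real visual embeddings except their distance-decaying
similarity.

## Known limitations

* The continuous design's latent advantage over direct learning
  expresses late: in the first few rewarded trials the continuous
  agent is *slower* than a naive one, because its coherent
  occupancy-based Q surface combined with a near-zero, noisy reward
  head forms local attractors that trap ε-greedy behavior until reward
  information spreads; it overtakes direct learning from roughly the
  eighth rewarded trial. The targeted design's advantage is present
  from trial 0.
* With one-hot features and a linear SF map the latent agent's map is
  learned essentially exactly, so pre-exposure is more powerful than a
  network-based agent would show. In the time-constrained door task
  this makes the no-doors latent agent master a task that a noisier
  learner fails; the qualitative ordering between conditions is
  unaffected.
* The ordering statistics use rank-based two-sample tests without
  multiplicity correction across the three design pairs; pairs are
  reported individually.
* The Tolman layouts are topological stand-ins, not reconstructions of
  the historical apparatus, and the 30-state variant's choice units
  have single-cell alleys by cell-count necessity.
* The `generalization_bias_score` is this package's own quantification
  of the qualitative "trajectory toward the goal" pattern (mass-weighted
  decrease in goal distance of a row's top-k states, relative to a
  uniform row); it is labelled as such in outputs.
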