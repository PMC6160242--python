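# Methods

`mbnav` simulates a model-based reinforcement-learning agent in a
three-chamber Y-maze and the cue/context conditioning protocol used to
characterize goal-directed navigation in the hippocampus–ventral
striatum circuit. This note records the model as implemented, the
numerical choices behind it, and where and why the implementation had
to depart from a literal transcription of the published equations.

## Arena and kinematics

The walkable region is the union of three 6×6-unit square chambers,
centers 5 units from the origin at bearings 90°/210°/330°, each rotated
to face the center, and an equilateral triangular passage whose edges
coincide with the chamber entrance walls (apothem 2). The bounding
diameter is ≈ 16.9 units; construction fails loudly if the pieces do
not connect or the diameter leaves 16 ± 1. Nine goal sites sit at the
midpoints of the non-entrance chamber walls, inset 0.5 units. Polygon
predicates (point and segment containment) use shapely with coordinates
snapped to a 10⁻⁶ precision grid so collinear chamber/passage walls
merge exactly.

Actions are forward / turn-left-step / turn-right-step: heading changes
by 0 or ±90° plus Gaussian noise (σ = 0.1 rad), then the position
advances 1.5 + N(0, 0.1) units. A move whose segment would cross a wall
leaves the position unchanged (the turn still applies) — this keeps the
dynamics Markov in the pose. Goal detection is a closed ball of radius
1.0 around a site, nearest site first, lowest id on ties.

## Sensors

Each of 11 grid cells is a hexagonal grating
G(x,y) = 2/3 (1/3 Σᵢ cos(kᵢ·(r − r₀)) + 1/2), three plane waves 60°
apart, spatial frequencies 2–7 cycles per 16-unit maze in steps of 0.5,
orientation and phase drawn once per agent and frozen. Cells are
binarized on a unit-step sampling grid and the 11 bits packed into an
integer code; combined with the 4-sector head-direction signal this
yields ~570 distinct tokens over the maze (the few-hundred-level
discrete input regime of the original study).

Two sensor choices deserve notice. First, the binarization threshold
defaults to the grating's spatial mean (1/3), not the midpoint of the
activation range: the grating distribution is skewed, and a 0.5 cutoff
leaves only ~27 % of bits active, which makes ~40 % of codes alias
across positions several units apart and destroys the latent state
space downstream. At the mean threshold the residual aliasing is
confined to adjacent sampling cells. Second, a finer (half-unit)
sampling grid is configurable but defaults off: it quadruples the token
count, so each token's transition statistics accumulate four times
slower, and the agent stays near chance within the protocol's trial
budget.

## Latent state space (CRP + congruence)

The categorization table P_c(s|x) holds one probability column per
experienced token. A novel token's column is its Chinese-restaurant
prior: existing states in proportion to popularity Σⱼ P_c(s|xⱼ), one
brand-new state with mass α/A, A = α + total popularity, α = 20.
Inference is the column argmax (lowest id on ties). Every step, the
previous token's column is multiplied by the transition likelihood
P_M(s_t|s_i, a_{t−1}) and renormalized — exactly a Bayes posterior over
the source category. A degenerate all-zero product leaves the column
unchanged. Popularity is maintained incrementally and equals a
recomputation from the current table to float precision.

Because every novel token instantiates a candidate state row, the raw
row count equals the token count by construction; the meaningful
"number of latent states" is the number of *active* states (argmax of
at least one column), which stays well below the token count (~330 of
~570 after cue conditioning) — the rich-get-richer consolidation the
CRP is meant to provide.

Two implementation details are load-bearing, both discovered by
instrumenting the state-space dynamics (popularity concentration,
assignment churn, place-field spread):

* **Source re-inference.** The transition conjugate is updated *after*
  the congruence step, with the source state re-inferred from the
  reshaped column. Without this, assignments that fail to predict the
  observed transition can never migrate, and the state space collapses
  onto a few high-popularity hubs.
* **Belief-weighted counts.** The observed transition is credited to
  the source *belief* (the column truncated at mass 0.02 and
  renormalized) rather than only to its argmax. Newly founded
  categories thereby accumulate row evidence in proportion to their
  plausibility before they win the argmax; with hard counts their rows
  stay empty, the congruence likelihood punishes them on any unseen
  successor, and they die of sparsity.

The Dirichlet prior pseudo-count per successor is ε = 0.001. This value
matters: the congruence decision between "keep the specialist category"
and "absorb into a popular generalist" is a likelihood ratio between
observed successor evidence and the ε-floor. At ε = 0.01 the ratio is
too weak and the state space collapses (popularity_max ≈ 25 α, ~55
surviving states with ~4-unit place fields); at ε ≤ 10⁻⁶ it
over-fragments. ε = 0.001 keeps the CRP in its healthy regime
(popularity_max < α, ~1-unit place fields); it is a config knob.

## Value learning

φ_{g,s} starts at Beta(1, 1) (value 0.5). Each sensed step updates the
cued goal's entry for the current state:
φ ← φ + α_t(φ_Obs + φ̃ − φ), φ_Obs = [1 − r, r], components floored at
10⁻³, with α_t = α₀/log₁₀ t (α₀ = 1.5, clamped for t ≤ 10, t counting
value updates across the whole run). The update also runs at a trial's
step 0, so a trial that starts on the cued goal still learns from its
reward.

The future term φ̃ comes from a greedy forward sweep through the
transition model: s̃ᵢ = the most valuable state reachable within one
action (each action's transition argmax, best P_v among them), starting
from the current state, truncating at dead ends. Two magnitude
conventions are implemented:

* **Raw discounted counts** (φ̃ = Σᵢ γⁱ φ_{g,s̃ᵢ}) — the printed form.
  It is only stable when Σᵢ₌₁..ₗ γⁱ < 1, i.e. depth 1: the stationary
  count magnitude M solves M = 1 + γM = 10, and the induced backup is
  exactly v ← 0.1 r + 0.9 v′. At depth 9 the series factor is ≈ 5.5 and
  the counts grow geometrically until overflow; the literal form cannot
  have produced a full training run.
* **Lookahead bootstrap** (default for training) — the sweep returns
  the best discounted value it finds, v* = maxᵢ γ^{i−1} v(s̃ᵢ), as the
  vector [1 − v*, v*] scaled to the one-step stationary mass
  γ/(1 − γ) = 9. At depth 1 this is identical in effect to the raw
  form's stationary behavior (so the depth-1 learner *is* the baseline
  learner), and at depth 9 it propagates distant reward expectancy up
  to nine transitions per update. The obvious alternative — summing the
  nine states' value *distributions* — provably flattens the value
  gradient (the greedy sweep climbs toward the goal from everywhere, so
  every state's target is pulled toward goal value) and leaves the
  agent at chance.

## Control

The shallow controller is the printed one-step maximization with ties
in action order (forward < left < right); untrained rows resolve to
their argmax under the uniform prior (state 0 by the lowest-id rule).
The sweep controller deepens three rollouts in lockstep (the first
transition forced to each action, then unrestricted greedy steps,
merging chains allowed, dead rollouts freezing their evidence), stops
when the certainty d = log₂ e₁ − log₂ e₂ over the two best cumulative
evidences exceeds 0.15 bits or at depth 9, and samples the action by a
softmax with exponent β = 80 over the **raw** accumulated evidence.
Raw, not normalized: merged rollouts share their continuation terms,
which cancel in softmax differences, so choice sharpness is independent
of depth; normalizing the evidence to probabilities first makes the
differences shrink ~1/depth and the choice near-uniform. Zero total
evidence yields a uniform draw. In the cue-free CX probe every value
lookup is replaced by the goal-pooled value Σ_g P_v(r=1|g,s) (a max
pooling is available by config).

## Protocol and replication

Trials: random start pose (uniform over the walkable region, uniform
heading; the first 360 cue trials start within 4 units of the center),
uniformly cued goal, at most 32 steps; a reward draw (Bernoulli with
the phase's per-room probability) happens on every step that ends
within 1 unit of the *cued* site, and a success ends the trial. Cue
phase: 2,000 trials at probability 1. Context phase: 700 trials at
0.75 in one fixed chamber / 0.25 elsewhere, binary reward (the value
model has no magnitude slot). CX probes: 2,000 steps from the central
3×3 area, learning and rewards off (novel tokens during the probe are
categorized read-only to the most popular state). Each learner draws
five independent RNG substreams (sensor bank, motor noise, reward,
softmax, starts) from its seed; a fixed seed reproduces runs
bit-identically, and checkpoints archive all five learned structures
plus RNG states.

The simulation *is* the data generator: there is no external data. It
emulates the structure of the animal protocol (phases, trial counts,
reward contingencies, probe design) but not, e.g., continuous-time
kinematics, nose-poke dynamics, inter-trial intervals, or any
electrophysiology; passing tests show the computational claims
reproduce under the stated conditions, not that the model fits any
particular animal's data.

## Analyses

States decode to space by enumerating the finite token grid: a state's
location is the centroid of the sample points of all tokens that
argmax-categorize to it (undecodable states are flagged, not dropped
silently; decoding is expectedly imperfect). Value maps take the
per-place maximum of P_v across head directions at 1 cell per unit;
transition maps the per-place maximum of P_M to places within one
action's reach (1.8 units = step + 3σ). Conditioning-change
distributions compare checkpoints of the same learner: value entries
with pre-phase value > 0.5 (grouped by the decoded state's room,
nearest chamber for passage states) and transition entries with
pre-phase probability > 0.05. Room-preference statistics count
goal-site hits per room in the CX probe with paired t-tests across
learners.

## Problem sizes

The package's own reduced replication — used by the acceptance script
and the acceptance-level tests — runs 3 independent learners per
variant at the full phase lengths (2,000 + 700 trials, 2,000-step
probes); one learner of the full-sweep variant takes ~25 s on one core.
The published study averaged 10 learners; `run_experiment` defaults to
10 when replication fidelity matters more than turnaround.

## Known quantitative deviations

With the stabilized learner the implementation reproduces the
qualitative results: the variant ordering
swControl+Reward > swControl > swReward ≥ Baseline, the decline of
sweep depth (≈ 8 → 5) and rise of decision certainty over cue
conditioning, the post-context free-run preference for the high-reward
room (absent after cue conditioning alone), the near-invariance of the
transition model across contextual conditioning (|mean change| ~ 10⁻³)
versus the marked drop of value entries, larger in the low-reward
rooms.

Quantitatively, cue accuracy lands at ~54/55/43/41 % for the four
variants against the published 69/62/39/36 %, and the value-change
means at about −0.13 (low rooms) and −0.04 (high room) against −0.29
and −0.17. Both gaps trace to the same place: the printed value-update
and evidence-normalization rules are not runnable as written (divergent
counts at depth 9; depth-dependent softmax collapse), so those pieces
were re-derived under stability constraints, and the stabilized value
scale saturates near 0.8 rather than 1.0 — which both caps policy
sharpness and leaves suprathreshold value entries less room to fall.
The gap between the two sweep-controller variants (~1 point here vs 7
printed) is within replicate noise at n = 3. None of these numbers were
adjusted toward the published values; the acceptance script reports
what the implementation computes.

## Limitations

Directional place fields only (head direction is part of the token);
no habit formation, backward replay, eligibility traces, hierarchical
state spaces or successor representations; reward is binary; the
decoding inverse is exact only up to grid-code aliasing. The CRP/
congruence dynamics have two self-sustaining regimes (specialized vs
collapsed); the defaults keep the system in the specialized regime for
the default maze and sensors, but aggressive changes to α, ε, or the
sensor resolution can tip it.
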