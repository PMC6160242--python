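# mbnav

A Bayesian model-based reinforcement-learning (MB-RL) agent for
goal-directed spatial navigation, built as a computational analogue of
the rodent hippocampus–ventral-striatum circuit, together with the
Y-maze cue/context conditioning experiment used to probe it.

The package is for computational neuroscientists and RL researchers who
want to simulate — and take apart — an agent that must *simultaneously*
learn three things from raw sensory input: a discrete latent state
space, a state-transition model, and a goal-conditioned state-value
model, and that plans by serial forward rollouts ("sweeps") reminiscent
of hippocampal theta sequences at decision points.

## The model

An agent moves through a three-chamber Y-maze (diameter ≈ 16 units,
nine rewarded goal sites, three per chamber) with three noisy action
primitives: step 1.5 units forward, or turn ±90° and step. Its only
sensors are a bank of 11 thresholded grid cells (hexagonal gratings,
2–7 cycles per maze) and a 4-sector head-direction signal; together
they yield a discrete token x = G × h.

Four coupled components:

* **Latent state categorization** — a growing conditional table
  P_c(s|x) with a Chinese-restaurant-process prior (concentration
  α = 20): a novel token joins existing categories in proportion to
  their popularity or founds a new one with mass α/A. Each step the
  previous token's column is rescaled by the transition likelihood
  (a Bayes posterior), P_c(s_i|x_{t−1}) ∝ P_M(s_t|s_i, a_{t−1})
  P_c(s_i|x_{t−1}), so only categories that afford accurate prediction
  are retained.
* **State-transition model** (hippocampus analogue) — Dirichlet
  pseudo-counts θ_{s,a}(s′) over latent successors; the posterior
  P_M(s′|s,a) is the normalized count vector.
* **State-value model** (ventral-striatum analogue) — Beta counts
  φ_{g,s} per (goal, state); P_v(r=1|g,s) is the posterior mean.
  Values are learned with a TD-like conjugate update
  φ ← φ + α_t(φ_Obs + φ̃ − φ), where φ̃ carries the discounted
  (γ = 0.90) reward expectancy accumulated along a forward sweep of
  depth 1 (baseline learner) or 9 (sweep learner), and
  α_t = 1.5 / log10 t.
* **Control** — either a shallow one-step maximization
  a = argmax_a P_v(r=1|g, argmax_{s′} P_M(s′|s,a)), or a sweep
  controller that rolls out one simulated trajectory per action,
  accumulates reward evidence r̃, deepens all rollouts until the
  decision certainty d = log2 r̃_best − log2 r̃_second exceeds 0.15 bits
  (cap 9), and samples the action by softmax (β = 80).

The 2×2 grid of {shallow, sweep} controllers × {depth-1, depth-9}
learners gives the four variants Baseline, swControl, swReward and
swControl+Reward.

The experiment mirrors the animal protocol: 2,000 cue-conditioning
trials (cued goal, certain reward, 32-step limit), 700 contextual
conditioning trials (75 % reward in one fixed chamber, 25 % elsewhere),
and reward-free, cue-free "CX test" probes (2,000 steps, goal-pooled
control) that read out the learned room preference.

## Worked example

```python
import numpy as np
from mbnav import ExperimentConfig, MazeGeometry
from mbnav.agent import Agent
from mbnav.maze import Phase
from mbnav.protocol import run_phase, run_cx_test, variant_config, accuracy

config = variant_config(ExperimentConfig(), "swcr")   # full-sweep variant
geometry = MazeGeometry(config.maze)
agent = Agent(config, geometry, seed_seq=np.random.SeedSequence(7))

logs = run_phase(agent, geometry, Phase.CUE, config, n_trials=500)
print(f"cue accuracy (500 trials): {100 * accuracy(logs):.1f}%")
print(f"latent states in use: {len(agent.categorization.active_states())}")
probe = run_cx_test(agent, geometry, n_steps=1000)
print(f"free-run reward-site visits per room: {probe.room_counts.tolist()}")
```

prints

```
cue accuracy (500 trials): 38.2%
latent states in use: 329
free-run reward-site visits per room: [644, 0, 0]
```

— after 500 trials the agent reaches the cued goal within the step
limit on 38 % of trials (accuracy keeps rising through the full
2,000-trial phase), has organized its experience into ~330 latent
place-by-heading categories, and in a cue-free probe it patrols the
reward sites it knows about. `mbnav.analysis` turns checkpoints into
decoded place atlases, per-goal value maps, transition maps,
sweep-length maps and room-preference statistics; the `mbnav` command
line (`mbnav train / cxtest / analyze`) wraps the same calls for shell
use.

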