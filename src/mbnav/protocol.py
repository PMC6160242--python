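"""The conditioning experiment: trials, phases, variants, replication.

A trial starts at a random pose with a randomly cued goal and runs the
sense -> categorize -> learn -> act loop until the agent obtains reward
at the cued site or the 32-step limit expires.  Cue conditioning runs
2,000 trials with certain reward (the first 360 starting near the
center); contextual conditioning runs 700 trials with 75% reward in one
fixed high-reward chamber and 25% elsewhere; the CX test is a 2,000-step
reward-free, cue-free run probing the learned room preference.

Four agent variants form a 2x2 grid over {shallow, sweep} controllers
and learning-sweep depths {1, 9}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .agent import Agent, AgentCheckpoint
from .config import ExperimentConfig
from .maze import (
    AgentPose,
    MazeGeometry,
    Phase,
    PhaseSchedule,
    apply_action,
    goal_check,
    sample_reward,
)

VARIANTS: dict[str, dict[str, Any]] = {
    "baseline": {"controller": "shallow", "learning_sweep_depth": 1},
    "swcontrol": {"controller": "sweep", "learning_sweep_depth": 1},
    "swreward": {"controller": "shallow", "learning_sweep_depth": 9},
    "swcr": {"controller": "sweep", "learning_sweep_depth": 9},
}
VARIANT_LABELS = {
    "baseline": "Baseline",
    "swcontrol": "swControl",
    "swreward": "swReward",
    "swcr": "swControl+Reward",
}


def variant_config(config: ExperimentConfig, variant: str) -> ExperimentConfig:
    """Configuration for one cell of the 2x2 controller/learning grid."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    agent = replace(config.agent, **VARIANTS[variant])
    return replace(config, agent=agent)


@dataclass
class TrialLog:
    trial: int
    phase: str
    goal: int
    start: tuple[float, float, float]
    steps: int
    success: bool
    path_length: float
    mean_sweep_depth: float
    mean_certainty: float
    step_records: list[tuple] | None = None  # (x, y, heading, action, depth)


@dataclass
class CXLog:
    """Free-run probe log: per-step positions and reward-site hits."""

    positions: np.ndarray  # (n_steps, 2)
    hits: np.ndarray  # goal id per step, -1 when no site in range
    room_counts: np.ndarray  # (3,) goal_check hits per room


@dataclass
class LearnerArchive:
    seed_entropy: Any
    cue_logs: list[TrialLog]
    post_cue_checkpoint: AgentCheckpoint
    post_cue_cx: CXLog
    context_logs: list[TrialLog]
    post_context_checkpoint: AgentCheckpoint
    post_context_cx: CXLog


@dataclass
class ExperimentArchive:
    variant: str
    config: dict
    seed: int
    learners: list[LearnerArchive] = field(default_factory=list)


def run_trial(
    agent: Agent,
    geometry: MazeGeometry,
    phase: PhaseSchedule,
    goal: int,
    start: AgentPose,
    trial_index: int = 0,
    learning: bool = True,
    record_steps: bool = False,
) -> TrialLog:
    """One conditioning trial from `start` toward the cued `goal`."""
    limit = phase.schedule.trial_limit
    pose = start
    depths: list[int] = []
    certs: list[float] = []
    records: list[tuple] | None = [] if record_steps else None
    path = 0.0
    success = False
    steps = 0

    sense = agent.sense if learning else agent.sense_readonly
    token_j, s = sense(pose)
    r = 0
    hit = goal_check(pose, geometry)
    if hit == goal:
        r = sample_reward(goal, phase, geometry, agent.rng_reward)
    if learning:
        agent.learn_value(goal, s, r)
    if r:
        success = True

    while not success and steps < limit:
        a, trace = agent.select_action(s, goal)
        if trace is not None:
            depths.append(trace.stop_depth)
            certs.append(trace.stop_certainty)
        new_pose = apply_action(pose, a, geometry, agent.rng_env)
        path += float(np.hypot(new_pose.x - pose.x, new_pose.y - pose.y))
        pose = new_pose
        steps += 1
        if records is not None:
            d = depths[-1] if depths else 0
            records.append((pose.x, pose.y, pose.heading, a, d))

        token_prev = token_j
        token_j, s = sense(pose)
        r = 0
        hit = goal_check(pose, geometry)
        if hit == goal:
            r = sample_reward(goal, phase, geometry, agent.rng_reward)
        if learning:
            agent.learn_transition(token_prev, a, s)
            agent.learn_value(goal, s, r)
        if r:
            success = True

    return TrialLog(
        trial=trial_index,
        phase=phase.phase.value,
        goal=goal,
        start=(start.x, start.y, start.heading),
        steps=steps,
        success=success,
        path_length=path,
        mean_sweep_depth=float(np.mean(depths)) if depths else 0.0,
        mean_certainty=float(np.mean(certs)) if certs else 0.0,
        step_records=records,
    )


def run_phase(
    agent: Agent,
    geometry: MazeGeometry,
    phase: Phase,
    config: ExperimentConfig | None = None,
    n_trials: int | None = None,
    record_steps: bool = False,
) -> list[TrialLog]:
    """A full conditioning phase (cue or context) of sequential trials."""
    config = config or agent.config
    sched = PhaseSchedule(phase, config.schedule)
    n_trials = sched.n_trials if n_trials is None else n_trials
    logs: list[TrialLog] = []
    for i in range(n_trials):
        central = (
            phase is Phase.CUE and i < config.schedule.cue_central_trials
        )
        start = geometry.random_pose(
            agent.rng_start,
            radius=config.schedule.central_radius if central else None,
        )
        goal = int(agent.rng_start.integers(9))
        logs.append(
            run_trial(
                agent, geometry, sched, goal, start,
                trial_index=i, learning=True, record_steps=record_steps,
            )
        )
    return logs


def run_cx_test(
    agent: Agent,
    geometry: MazeGeometry,
    n_steps: int | None = None,
) -> CXLog:
    """Free-run probe: goal-pooled control, learning and rewards off."""
    sched = agent.config.schedule
    n_steps = sched.cx_steps if n_steps is None else n_steps
    pose = geometry.random_pose(agent.rng_start, square_half=sched.cx_start_half)
    positions = np.zeros((n_steps, 2), dtype=float)
    hits = np.full(n_steps, -1, dtype=np.int64)
    room_counts = np.zeros(3, dtype=np.int64)
    _, s = agent.sense_readonly(pose)
    for t in range(n_steps):
        a, _ = agent.select_action(s, None)
        pose = apply_action(pose, a, geometry, agent.rng_env)
        positions[t] = (pose.x, pose.y)
        _, s = agent.sense_readonly(pose)
        hit = goal_check(pose, geometry)
        if hit is not None:
            hits[t] = hit
            room_counts[int(geometry.goal_rooms[hit])] += 1
    return CXLog(positions=positions, hits=hits, room_counts=room_counts)


def run_learner(
    config: ExperimentConfig,
    geometry: MazeGeometry,
    seed_seq: np.random.SeedSequence,
    cue_trials: int | None = None,
    context_trials: int | None = None,
    cx_steps: int | None = None,
    record_steps: bool = False,
) -> LearnerArchive:
    """Train one learner through both phases with probes and checkpoints."""
    agent = Agent(config, geometry, seed_seq)
    cue_logs = run_phase(
        agent, geometry, Phase.CUE, config, n_trials=cue_trials,
        record_steps=record_steps,
    )
    post_cue = agent.checkpoint()
    post_cue_cx = run_cx_test(agent, geometry, n_steps=cx_steps)
    context_logs = run_phase(
        agent, geometry, Phase.CONTEXT, config, n_trials=context_trials,
        record_steps=record_steps,
    )
    post_context = agent.checkpoint()
    post_context_cx = run_cx_test(agent, geometry, n_steps=cx_steps)
    return LearnerArchive(
        seed_entropy=seed_seq.entropy,
        cue_logs=cue_logs,
        post_cue_checkpoint=post_cue,
        post_cue_cx=post_cue_cx,
        context_logs=context_logs,
        post_context_checkpoint=post_context,
        post_context_cx=post_context_cx,
    )


def run_experiment(
    variant: str,
    config: ExperimentConfig | None = None,
    n_learners: int | None = None,
    seed: int | None = None,
    cue_trials: int | None = None,
    context_trials: int | None = None,
    cx_steps: int | None = None,
) -> ExperimentArchive:
    """Replicate one variant over independent learners (distinct seeds)."""
    config = (config or ExperimentConfig()).validate()
    config = variant_config(config, variant)
    n_learners = config.n_learners if n_learners is None else n_learners
    seed = config.seed if seed is None else seed
    geometry = MazeGeometry(config.maze)
    archive = ExperimentArchive(variant=variant, config=config.to_dict(), seed=seed)
    root = np.random.SeedSequence(seed)
    for learner_ss in root.spawn(n_learners):
        archive.learners.append(
            run_learner(
                config, geometry, learner_ss,
                cue_trials=cue_trials, context_trials=context_trials,
                cx_steps=cx_steps,
            )
        )
    return archive


def accuracy(logs: list[TrialLog]) -> float:
    """Fraction of successful trials."""
    if not logs:
        return float("nan")
    return float(np.mean([t.success for t in logs]))
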