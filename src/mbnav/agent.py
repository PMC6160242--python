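"""The MB-RL agent: sensors, state space, world models and per-step logic.

One `Agent` owns a frozen grid-cell bank, the CRP categorization model,
the Dirichlet transition model and the Beta value model, plus the RNG
substreams for motor noise, reward draws and softmax choice.  The
per-step learning follows the joint scheme: observe the token, infer
the latent state, make the previous token's categorization congruent
with the observed transition, count the transition, and TD-update the
goal-conditioned value with sweep-accumulated future counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ExperimentConfig
from .control import SweepTrace, adaptive_sweep_select, shallow_select
from .maze import AgentPose, MazeGeometry
from .sensors import GridCellBank
from .state_space import CategorizationModel
from .world_model import (
    TransitionModel,
    ValueModel,
    accumulate_future_conjugate,
    learning_rate,
)


@dataclass
class AgentCheckpoint:
    """Frozen snapshot of every learned structure of one agent."""

    config: dict
    categorization: dict
    transition: dict
    value: dict
    bank: dict
    rng_state: dict
    learn_step: int
    version: int = 1


class Agent:
    """Model-based reinforcement-learning agent for the Y-maze."""

    def __init__(
        self,
        config: ExperimentConfig,
        geometry: MazeGeometry,
        seed_seq: np.random.SeedSequence | int = 0,
    ):
        self.config = config
        self.geometry = geometry
        if not isinstance(seed_seq, np.random.SeedSequence):
            seed_seq = np.random.SeedSequence(seed_seq)
        self._seed_seq = seed_seq
        bank_ss, env_ss, reward_ss, policy_ss, start_ss = seed_seq.spawn(5)
        self.rng_env = np.random.default_rng(env_ss)
        self.rng_reward = np.random.default_rng(reward_ss)
        self.rng_policy = np.random.default_rng(policy_ss)
        self.rng_start = np.random.default_rng(start_ss)

        acfg = config.agent
        self.bank = GridCellBank(config.sensors, np.random.default_rng(bank_ss))
        self.categorization = CategorizationModel(alpha=acfg.crp_alpha)
        self.transition = TransitionModel(eps=acfg.dirichlet_eps)
        self.value = ValueModel(
            gamma=acfg.gamma, alpha0=acfg.alpha0, floor=acfg.value_floor
        )
        self.learn_step = 0  # global learning-rate index (value updates)

    # -- sensing ---------------------------------------------------------
    def sense(self, pose: AgentPose) -> tuple[int, int]:
        """Observe the sensory token at a pose; returns (token_id, state)."""
        token = self.bank.sensory_token(pose)
        key = (token.grid_code, token.head_sector)
        j = self.categorization.observe_token(key)
        n = self.categorization.n_states
        self.transition.ensure_states(n)
        self.value.ensure_states(n)
        return j, self.categorization.infer_state(key)

    def sense_readonly(self, pose: AgentPose) -> tuple[int | None, int]:
        """Sense without learning (CX test): models are left untouched.

        A token never seen during training is categorized to the most
        popular existing state (the CRP assignment with state creation
        suppressed); with an empty model this is state 0.
        """
        token = self.bank.sensory_token(pose)
        key = (token.grid_code, token.head_sector)
        cat = self.categorization
        if cat.has_token(key):
            return cat.token_id(key), cat.infer_state(key)
        if cat.n_states == 0:
            return None, 0
        return None, int(np.argmax(cat.popularity))

    # -- learning --------------------------------------------------------
    def learn_transition(self, token_prev: int, a_prev: int, s_now: int) -> int:
        """Joint state-space / transition learning for one experienced step.

        The previous token's categorization is first made congruent with
        the observed transition; the source state is then re-inferred
        from the reshaped column before counting the transition, so that
        assignments that fail to predict s_now can migrate to a fresh
        state and found their own transition row.
        """
        self.categorization.congruence_update(
            token_prev, s_now, a_prev, self.transition
        )
        sources, weights = self.categorization.belief(token_prev)
        self.transition.update_soft(sources, weights, a_prev, s_now)
        return int(sources[np.argmax(weights)])

    def learn_value(self, g: int, s_now: int, r: int) -> float:
        self.learn_step += 1
        acfg = self.config.agent
        alpha_t = learning_rate(self.learn_step, acfg.alpha0, acfg.lr_clamp_t)
        phi_tilde = accumulate_future_conjugate(
            self.value, self.transition, g, s_now, acfg.learning_sweep_depth
        )
        self.value.td_update(g, s_now, r, phi_tilde, alpha_t)
        return alpha_t

    # -- action selection ------------------------------------------------
    def select_action(self, s: int, g: int | None) -> tuple[int, SweepTrace | None]:
        """Choose an action; g=None engages the goal-pooled free-run mode."""
        acfg = self.config.agent
        if g is not None and acfg.controller == "shallow":
            return shallow_select(s, g, self.transition, self.value), None
        return adaptive_sweep_select(
            s,
            g,
            self.transition,
            self.value,
            self.rng_policy,
            beta=acfg.softmax_beta,
            d_thr=acfg.d_thr,
            l_cap=acfg.l_cap,
            pooling=acfg.cx_pooling,
        )

    # -- checkpointing ---------------------------------------------------
    def checkpoint(self) -> AgentCheckpoint:
        scfg = self.config.sensors
        return AgentCheckpoint(
            config=self.config.to_dict(),
            categorization=self.categorization.state_dict(),
            transition=self.transition.state_dict(),
            value=self.value.state_dict(),
            bank={
                "frequencies": self.bank.frequencies.copy(),
                "orientations": self.bank.orientations.copy(),
                "phases": self.bank.phases.copy(),
                "threshold": scfg.threshold,
                "sample_step": scfg.sample_step,
                "maze_extent": scfg.maze_extent,
            },
            rng_state={
                "env": self.rng_env.bit_generator.state,
                "reward": self.rng_reward.bit_generator.state,
                "policy": self.rng_policy.bit_generator.state,
                "start": self.rng_start.bit_generator.state,
            },
            learn_step=self.learn_step,
        )

    @classmethod
    def from_checkpoint(
        cls, ckpt: AgentCheckpoint, geometry: MazeGeometry | None = None
    ) -> "Agent":
        config = ExperimentConfig.from_dict(ckpt.config)
        geometry = geometry or MazeGeometry(config.maze)
        agent = cls(config, geometry, seed_seq=0)
        agent.bank = GridCellBank.from_params(
            config.sensors,
            np.asarray(ckpt.bank["frequencies"]),
            np.asarray(ckpt.bank["orientations"]),
            np.asarray(ckpt.bank["phases"]),
        )
        agent.categorization = CategorizationModel.from_state_dict(ckpt.categorization)
        agent.transition = TransitionModel.from_state_dict(ckpt.transition)
        agent.value = ValueModel.from_state_dict(ckpt.value)
        n = agent.categorization.n_states
        agent.transition.ensure_states(n)
        agent.value.ensure_states(n)
        agent.learn_step = int(ckpt.learn_step)
        for name, rng in (
            ("env", agent.rng_env),
            ("reward", agent.rng_reward),
            ("policy", agent.rng_policy),
            ("start", agent.rng_start),
        ):
            rng.bit_generator.state = ckpt.rng_state[name]
        return agent
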