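"""Experiment configuration: dataclasses, validation, YAML round-trip.

Defaults reproduce the study conditions of the Y-maze conditioning
experiment: a ~16-unit three-chamber maze, 11 grid cells, CRP
concentration alpha=20, softmax exponent beta=80, discount gamma=0.90,
certainty threshold 0.15, learning-rate scale 1.5, sweep cap 9, and a
2,000-trial cue phase followed by a 700-trial context phase.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent experiment configuration."""


@dataclass
class MazeConfig:
    chamber_side: float = 6.0
    chamber_distance: float = 5.0  # chamber-center distance from origin
    chamber_bearings_deg: tuple[float, float, float] = (90.0, 210.0, 330.0)
    goal_inset: float = 0.5  # goal offset inward from chamber walls
    passage_scale: float = 1.0  # passage size relative to the connecting fit
    goal_radius: float = 1.0  # detection distance around a goal site
    step_size: float = 1.5
    motion_noise_sd: float = 0.1  # applies to step length (units) and turn (rad)
    diameter_target: float = 16.0
    diameter_tol: float = 1.0

    def validate(self) -> None:
        if self.chamber_side <= 0 or self.chamber_distance <= 0:
            raise ConfigError("chamber dimensions must be positive")
        if self.goal_inset <= 0:
            raise ConfigError("goal_inset must be positive")
        if self.chamber_distance <= self.chamber_side / 2:
            raise ConfigError("chambers would overlap the maze center")
        if self.passage_scale <= 0:
            raise ConfigError("passage_scale must be positive")


@dataclass
class SensorConfig:
    n_cells: int = 11
    freq_min: float = 2.0  # cycles per maze
    freq_max: float = 7.0
    freq_step: float = 0.5
    # binarization cutoff on the [0, 1] activation; the default is the
    # grating's spatial mean (2/3 * 1/2 = 1/3): a cell is active where its
    # hexagonal pattern exceeds its own average, which maximizes the
    # entropy of the binary code far better than the range midpoint
    threshold: float = 1.0 / 3.0
    sample_step: float = 1.0  # spatial sampling grid for the binary code
    maze_extent: float = 16.0  # "per maze" length scale of the frequencies

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigError("threshold must lie in (0, 1)")
        if self.sample_step <= 0:
            raise ConfigError("sample_step must be positive")


@dataclass
class AgentConfig:
    crp_alpha: float = 20.0  # CRP concentration
    softmax_beta: float = 80.0  # exponent on normalized sweep evidence
    gamma: float = 0.90  # discount of future value counts
    d_thr: float = 0.15  # decision-certainty stop threshold (bits)
    alpha0: float = 1.5  # learning-rate scale, alpha_t = alpha0/log10(t)
    lr_clamp_t: int = 10  # clamp alpha_t to alpha0 for t <= this
    l_cap: int = 9  # control-sweep depth cap
    learning_sweep_depth: int = 9  # 1 = baseline learner, 9 = sweep learner
    controller: str = "sweep"  # {"shallow", "sweep"}
    # transition prior pseudo-count per successor; small enough that the
    # congruence likelihood ratio between observed evidence and the
    # smoothing floor is decisive (larger values collapse the latent
    # state space onto a few high-popularity categories)
    dirichlet_eps: float = 0.001
    value_floor: float = 1e-3  # lower clamp on Beta counts after TD update
    cx_pooling: str = "sum"  # pooled free-run value: {"sum", "max"}

    def validate(self) -> None:
        if self.crp_alpha <= 0:
            raise ConfigError("crp_alpha must be positive")
        if not (0.0 <= self.gamma < 1.0):
            raise ConfigError("gamma must lie in [0, 1)")
        if self.softmax_beta <= 0 or self.alpha0 <= 0:
            raise ConfigError("softmax_beta and alpha0 must be positive")
        if self.d_thr < 0:
            raise ConfigError("d_thr must be non-negative")
        if self.l_cap < 1 or self.learning_sweep_depth < 1:
            raise ConfigError("sweep depths must be >= 1")
        if self.controller not in ("shallow", "sweep"):
            raise ConfigError(f"unknown controller {self.controller!r}")
        if self.dirichlet_eps <= 0:
            raise ConfigError("dirichlet_eps must be positive")
        if self.cx_pooling not in ("sum", "max"):
            raise ConfigError(f"unknown cx_pooling {self.cx_pooling!r}")


@dataclass
class ScheduleConfig:
    cue_trials: int = 2000
    context_trials: int = 700
    cue_central_trials: int = 360  # early trials start near the center
    central_radius: float = 4.0
    trial_limit: int = 32  # steps per trial
    high_reward_room: int = 0
    context_high_p: float = 0.75
    context_low_p: float = 0.25
    cx_steps: int = 2000
    cx_start_half: float = 1.5  # half-side of the central start square

    def validate(self) -> None:
        if min(self.cue_trials, self.context_trials, self.trial_limit) < 1:
            raise ConfigError("trial counts and trial_limit must be >= 1")
        for p in (self.context_high_p, self.context_low_p):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("reward probabilities must lie in [0, 1]")
        if self.high_reward_room not in (0, 1, 2):
            raise ConfigError("high_reward_room must be 0, 1 or 2")


@dataclass
class ExperimentConfig:
    maze: MazeConfig = field(default_factory=MazeConfig)
    sensors: SensorConfig = field(default_factory=SensorConfig)
    agent: AgentConfig = field(default_factory=AgentConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    n_learners: int = 10
    seed: int = 0

    def validate(self) -> "ExperimentConfig":
        self.maze.validate()
        self.sensors.validate()
        self.agent.validate()
        self.schedule.validate()
        if self.n_learners < 1:
            raise ConfigError("n_learners must be >= 1")
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ExperimentConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        for name, sub_cls in (
            ("maze", MazeConfig),
            ("sensors", SensorConfig),
            ("agent", AgentConfig),
            ("schedule", ScheduleConfig),
        ):
            block = data.pop(name, {}) or {}
            _check_keys(block, sub_cls, name)
            if "chamber_bearings_deg" in block:
                block["chamber_bearings_deg"] = tuple(block["chamber_bearings_deg"])
            kwargs[name] = sub_cls(**block)
        _check_keys(data, cls, "experiment", skip=("maze", "sensors", "agent", "schedule"))
        return cls(**kwargs, **data).validate()


def _check_keys(block: dict, sub_cls: type, name: str, skip: tuple[str, ...] = ()) -> None:
    known = {f.name for f in dataclasses.fields(sub_cls)} - set(skip)
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown {name} config keys: {sorted(unknown)}")


def load_config(path: str | None = None, text: str | None = None) -> ExperimentConfig:
    """Load a YAML/JSON config file; absent keys take the study defaults."""
    if text is None:
        if path is None:
            return ExperimentConfig().validate()
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return ExperimentConfig.from_dict(data)


def dump_config(config: ExperimentConfig, path: str | None = None) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
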