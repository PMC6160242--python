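"""Y-maze geometry, agent kinematics and probabilistic reward delivery.

The arena is three congruent square chambers rotated 120 degrees apart
around a central triangular passage; each chamber carries three goal
sites along its non-entrance walls.  The agent moves with three noisy
action primitives (forward, turn-left-step, turn-right-step) and is
rewarded on approaching the cued goal site within a unit distance, with
a probability set by the experimental phase.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .config import ConfigError, MazeConfig, ScheduleConfig

FORWARD, TURN_LEFT, TURN_RIGHT = 0, 1, 2
ACTION_NAMES = ("forward", "turn-left-step", "turn-right-step")
_TURNS = (0.0, math.pi / 2.0, -math.pi / 2.0)
N_ACTIONS = 3


class Phase(enum.Enum):
    CUE = "cue"
    CONTEXT = "context"
    CX_TEST = "cx_test"


@dataclass(frozen=True)
class AgentPose:
    x: float
    y: float
    heading: float  # radians, counter-clockwise from +x


class MazeGeometry:
    """Walkable region, chamber polygons and goal sites of the Y-maze."""

    def __init__(self, config: MazeConfig | None = None):
        cfg = config or MazeConfig()
        cfg.validate()
        self.config = cfg
        half = cfg.chamber_side / 2.0
        bearings = [math.radians(b) for b in cfg.chamber_bearings_deg]

        self.chambers: list[Polygon] = []
        goals: list[tuple[float, float]] = []
        goal_rooms: list[int] = []
        for room, b in enumerate(bearings):
            cx, cy = cfg.chamber_distance * math.cos(b), cfg.chamber_distance * math.sin(b)
            # square with the entrance wall facing the maze center
            rot = b - math.pi / 2.0
            corners = [(-half, -half), (half, -half), (half, half), (-half, half)]
            poly = Polygon(
                [
                    (
                        cx + u * math.cos(rot) - v * math.sin(rot),
                        cy + u * math.sin(rot) + v * math.cos(rot),
                    )
                    for u, v in corners
                ]
            )
            # snap to a coarse precision grid so that collinear chamber
            # and passage walls merge exactly in the union
            poly = shapely.set_precision(poly, 1e-6)
            self.chambers.append(poly)
            # goals at midpoints of the 3 non-entrance walls, inset inward
            g = cfg.goal_inset
            for u, v in ((0.0, half - g), (-(half - g), 0.0), (half - g, 0.0)):
                goals.append(
                    (
                        cx + u * math.cos(rot) - v * math.sin(rot),
                        cy + u * math.sin(rot) + v * math.cos(rot),
                    )
                )
                goal_rooms.append(room)

        # equilateral triangular passage whose edges coincide with the
        # chamber entrance walls (apothem = distance of those walls)
        apothem = (cfg.chamber_distance - half) * cfg.passage_scale
        circum = 2.0 * apothem
        vertex_bearings = [b + math.pi / 3.0 for b in bearings]
        self.passage = shapely.set_precision(
            Polygon(
                [(circum * math.cos(a), circum * math.sin(a)) for a in vertex_bearings]
            ),
            1e-6,
        )

        self.walkable: Polygon = unary_union(self.chambers + [self.passage])
        if self.walkable.geom_type != "Polygon":
            raise ConfigError("maze is not connected: chambers do not reach the passage")
        for room, ch in enumerate(self.chambers):
            if ch.intersection(self.passage).length <= 1e-9:
                raise ConfigError(f"chamber {room} does not connect to the passage")

        self.goal_sites = np.asarray(goals, dtype=float)  # (9, 2)
        self.goal_rooms = np.asarray(goal_rooms, dtype=int)
        for gx, gy in self.goal_sites:
            if not self.walkable.contains(Point(gx, gy)):
                raise ConfigError("a goal site lies outside the walkable region")

        hull = np.asarray(self.walkable.convex_hull.exterior.coords)
        d = np.linalg.norm(hull[:, None, :] - hull[None, :, :], axis=-1)
        self.diameter = float(d.max())
        if abs(self.diameter - cfg.diameter_target) > cfg.diameter_tol:
            raise ConfigError(
                f"maze diameter {self.diameter:.2f} outside "
                f"{cfg.diameter_target} +- {cfg.diameter_tol}"
            )
        shapely.prepare(self.walkable)

    # -- queries ---------------------------------------------------------
    def contains(self, x: float, y: float) -> bool:
        return bool(self.walkable.covers(Point(x, y)))

    def segment_clear(self, x0: float, y0: float, x1: float, y1: float) -> bool:
        """True when the move from (x0,y0) to (x1,y1) stays inside the walls."""
        return bool(self.walkable.covers(LineString([(x0, y0), (x1, y1)])))

    def room_of(self, x: float, y: float) -> int | None:
        """Chamber index containing the point, or None for the passage."""
        p = Point(x, y)
        for room, ch in enumerate(self.chambers):
            if ch.covers(p):
                return room
        return None

    def nearest_room(self, x: float, y: float) -> int:
        room = self.room_of(x, y)
        if room is not None:
            return room
        d = [ch.centroid.distance(Point(x, y)) for ch in self.chambers]
        return int(np.argmin(d))

    def random_pose(
        self,
        rng: np.random.Generator,
        radius: float | None = None,
        square_half: float | None = None,
    ) -> AgentPose:
        """Uniform pose over the walkable region, optionally restricted to a
        central disk (radius) or central square (half-side)."""
        minx, miny, maxx, maxy = self.walkable.bounds
        if radius is not None:
            minx, miny = max(minx, -radius), max(miny, -radius)
            maxx, maxy = min(maxx, radius), min(maxy, radius)
        if square_half is not None:
            minx, miny = max(minx, -square_half), max(miny, -square_half)
            maxx, maxy = min(maxx, square_half), min(maxy, square_half)
        for _ in range(10_000):
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if radius is not None and math.hypot(x, y) > radius:
                continue
            if self.contains(x, y):
                return AgentPose(x, y, rng.uniform(0.0, 2.0 * math.pi))
        raise RuntimeError("failed to sample a start pose")


def build_maze(config: MazeConfig | None = None) -> MazeGeometry:
    """Construct the Y-maze from geometry parameters (study defaults)."""
    return MazeGeometry(config)


def apply_action(
    pose: AgentPose,
    action: int,
    geometry: MazeGeometry,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> AgentPose:
    """Execute one action primitive with Gaussian motor noise.

    The heading turns by 0 or +-90 degrees plus noise (sd 0.1 rad); the
    position advances 1.5 + N(0, 0.1) units along the new heading.  A
    move whose path would cross a wall leaves the position unchanged
    (the turn still applies).
    """
    cfg = geometry.config
    sd = cfg.motion_noise_sd if noise else 0.0
    if noise and rng is None:
        raise ValueError("rng required when noise is enabled")
    heading = pose.heading + _TURNS[action]
    step = cfg.step_size
    if noise:
        heading += rng.normal(0.0, sd)
        step += rng.normal(0.0, sd)
    heading %= 2.0 * math.pi
    nx = pose.x + step * math.cos(heading)
    ny = pose.y + step * math.sin(heading)
    if geometry.segment_clear(pose.x, pose.y, nx, ny):
        return AgentPose(nx, ny, heading)
    return AgentPose(pose.x, pose.y, heading)


def goal_check(pose: AgentPose, geometry: MazeGeometry) -> int | None:
    """Id of the nearest goal site within the unit detection distance.

    The boundary is closed (distance exactly 1.0 detects); distance ties
    resolve to the lowest goal id.
    """
    d = np.hypot(
        geometry.goal_sites[:, 0] - pose.x, geometry.goal_sites[:, 1] - pose.y
    )
    i = int(np.argmin(d))
    return i if d[i] <= geometry.config.goal_radius else None


@dataclass(frozen=True)
class PhaseSchedule:
    """Reward contingencies and trial structure of one experimental phase."""

    phase: Phase
    schedule: ScheduleConfig

    def reward_prob(self, goal: int, geometry: MazeGeometry) -> float:
        if self.phase is Phase.CUE:
            return 1.0
        if self.phase is Phase.CX_TEST:
            return 0.0
        room = int(geometry.goal_rooms[goal])
        if room == self.schedule.high_reward_room:
            return self.schedule.context_high_p
        return self.schedule.context_low_p

    @property
    def n_trials(self) -> int:
        if self.phase is Phase.CUE:
            return self.schedule.cue_trials
        if self.phase is Phase.CONTEXT:
            return self.schedule.context_trials
        raise ValueError("the CX test is a free run, not a trial phase")


def sample_reward(
    goal: int,
    phase: PhaseSchedule,
    geometry: MazeGeometry,
    rng: np.random.Generator,
) -> int:
    """Bernoulli reward draw for reaching `goal` under the phase contingencies."""
    p = phase.reward_prob(goal, geometry)
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return 1
    return int(rng.random() < p)


def rotate_pose(pose: AgentPose, angle: float) -> AgentPose:
    c, s = math.cos(angle), math.sin(angle)
    return AgentPose(
        c * pose.x - s * pose.y,
        s * pose.x + c * pose.y,
        (pose.heading + angle) % (2.0 * math.pi),
    )
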