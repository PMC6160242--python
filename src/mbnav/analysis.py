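"""Results-level readouts: decoded maps, change distributions, curves.

Latent states are decoded back to maze coordinates by enumerating the
finite token space: every sampling-grid position produces a grid code,
every (code, head-sector) token argmax-categorizes to a state, and the
state's location is the centroid of its supporting positions.  The
decoding is deliberately not forced to be perfect: states without token
support are flagged undecodable rather than erased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agent import AgentCheckpoint
from .maze import MazeGeometry
from .protocol import CXLog, TrialLog
from .state_space import CategorizationModel
from .world_model import N_ACTIONS


@dataclass
class DecodedAtlas:
    """Spatial decoding of latent states (NaN / -1 mark undecodable)."""

    xy: np.ndarray  # (n_states, 2)
    sector: np.ndarray  # (n_states,), majority head sector
    support: np.ndarray  # (n_states,), number of supporting sample points
    rooms: np.ndarray  # (n_states,), nearest chamber of the centroid

    @property
    def decodable(self) -> np.ndarray:
        return self.support > 0


def _bank_from_checkpoint(ckpt: AgentCheckpoint):
    from .config import ExperimentConfig
    from .sensors import GridCellBank

    config = ExperimentConfig.from_dict(ckpt.config)
    return GridCellBank.from_params(
        config.sensors,
        np.asarray(ckpt.bank["frequencies"]),
        np.asarray(ckpt.bank["orientations"]),
        np.asarray(ckpt.bank["phases"]),
    )


def decode_atlas(ckpt: AgentCheckpoint, geometry: MazeGeometry) -> DecodedAtlas:
    """Invert the sensory mapping by enumeration of the token space."""
    cat = CategorizationModel.from_state_dict(ckpt.categorization)
    bank = _bank_from_checkpoint(ckpt)
    code_pos = bank.code_positions(geometry)
    n = cat.n_states
    sums = np.zeros((n, 2), dtype=float)
    counts = np.zeros(n, dtype=float)
    sector_votes = np.zeros((n, 4), dtype=float)
    table = cat.table
    for j, (code, sector) in enumerate(cat.token_keys()):
        pos = code_pos.get(code)
        if pos is None:
            continue  # token experienced off the sampling enumeration
        s = int(np.argmax(table[:, j]))
        sums[s] += pos.sum(axis=0)
        counts[s] += len(pos)
        sector_votes[s, sector] += len(pos)
    xy = np.full((n, 2), np.nan)
    rooms = np.full(n, -1, dtype=np.int64)
    sector = np.full(n, -1, dtype=np.int64)
    mask = counts > 0
    xy[mask] = sums[mask] / counts[mask, None]
    sector[mask] = np.argmax(sector_votes[mask], axis=1)
    for s in np.nonzero(mask)[0]:
        rooms[s] = geometry.nearest_room(xy[s, 0], xy[s, 1])
    return DecodedAtlas(xy=xy, sector=sector, support=counts.astype(np.int64), rooms=rooms)


# -- spatial rasters -----------------------------------------------------

def _raster_cells(geometry: MazeGeometry, resolution: float):
    minx, miny, maxx, maxy = geometry.walkable.bounds
    ix0, iy0 = math.floor(minx / resolution), math.floor(miny / resolution)
    nx = math.ceil(maxx / resolution) - ix0 + 1
    ny = math.ceil(maxy / resolution) - iy0 + 1
    return ix0, iy0, nx, ny


@dataclass
class SpatialMap:
    """Scalar raster over the maze extent; NaN cells are undecoded."""

    values: np.ndarray
    origin: tuple[int, int]
    resolution: float
    statistic: str = ""
    goal: int | None = None

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        return (
            math.floor(x / self.resolution) - self.origin[0],
            math.floor(y / self.resolution) - self.origin[1],
        )


def value_map(
    ckpt: AgentCheckpoint,
    atlas: DecodedAtlas,
    geometry: MazeGeometry,
    g: int | None = None,
    resolution: float = 1.0,
    pooling: str = "sum",
) -> SpatialMap:
    """Greatest value P_v(r=1|g, xy(s)) across head directions per place.

    g=None produces the goal-pooled map used for the free-run probe.
    """
    from .world_model import ValueModel

    value = ValueModel.from_state_dict(ckpt.value)
    table = value.value_table()  # (n_goals, n_states)
    if g is None:
        vals = table.max(axis=0) if pooling == "max" else table.sum(axis=0)
    else:
        vals = table[g]
    ix0, iy0, nx, ny = _raster_cells(geometry, resolution)
    raster = np.full((nx, ny), np.nan)
    n = min(len(atlas.xy), len(vals))
    for s in range(n):
        if not atlas.decodable[s]:
            continue
        cx = math.floor(atlas.xy[s, 0] / resolution) - ix0
        cy = math.floor(atlas.xy[s, 1] / resolution) - iy0
        if np.isnan(raster[cx, cy]) or vals[s] > raster[cx, cy]:
            raster[cx, cy] = vals[s]
    stat = "pooled_value" if g is None else "value"
    return SpatialMap(raster, (ix0, iy0), resolution, statistic=stat, goal=g)


def transition_map(
    ckpt: AgentCheckpoint,
    atlas: DecodedAtlas,
    geometry: MazeGeometry,
    resolution: float = 1.0,
    reach: float = 1.8,  # one action range: step 1.5 plus 3 sd of noise
) -> dict[tuple[int, int], dict[tuple[int, int], float]]:
    """Per source place, the greatest transition probability to each
    nearby place (max over head directions and actions)."""
    from .world_model import TransitionModel

    trans = TransitionModel.from_state_dict(ckpt.transition)
    n = trans.n_states
    decod = np.nonzero(atlas.decodable[:n])[0]
    cell = {
        int(s): (
            math.floor(atlas.xy[s, 0] / resolution),
            math.floor(atlas.xy[s, 1] / resolution),
        )
        for s in decod
    }
    out: dict[tuple[int, int], dict[tuple[int, int], float]] = {}
    for s in decod:
        src = cell[int(s)]
        dest = out.setdefault(src, {})
        for a in range(N_ACTIONS):
            row = trans.probs(int(s), a, n)
            for s2 in decod:
                d = np.hypot(
                    atlas.xy[s2, 0] - atlas.xy[s, 0],
                    atlas.xy[s2, 1] - atlas.xy[s, 1],
                )
                if d > reach:
                    continue
                key = cell[int(s2)]
                p = float(row[s2])
                if p > dest.get(key, 0.0):
                    dest[key] = p
    return out


# -- conditioning change statistics --------------------------------------

def change_distribution(
    ckpt_pre: AgentCheckpoint,
    ckpt_post: AgentCheckpoint,
    geometry: MazeGeometry,
    high_reward_room: int | None = None,
    value_threshold: float = 0.5,
    transition_threshold: float = 0.05,
) -> dict[str, np.ndarray]:
    """Post-minus-pre changes of the two models across a conditioning phase.

    Value entries with pre > 0.5 are grouped by the room of the decoded
    state (high- vs low-reward); transition entries use pre > 0.05.
    """
    from .config import ExperimentConfig
    from .world_model import TransitionModel, ValueModel

    if high_reward_room is None:
        cfg = ExperimentConfig.from_dict(ckpt_post.config)
        high_reward_room = cfg.schedule.high_reward_room

    v_pre = ValueModel.from_state_dict(ckpt_pre.value).value_table()
    v_post_model = ValueModel.from_state_dict(ckpt_post.value)
    n_pre = v_pre.shape[1]
    if v_post_model.n_states < n_pre:
        raise ValueError("checkpoints are not from the same learner (state spaces shrink)")
    v_post = v_post_model.value_table()[:, :n_pre]

    atlas = decode_atlas(ckpt_post, geometry)
    rooms = atlas.rooms[:n_pre]
    vmask = v_pre > value_threshold
    vmask &= rooms[None, :] >= 0  # drop undecodable states
    changes = v_post - v_pre
    state_room = np.broadcast_to(rooms[None, :], vmask.shape)
    high = vmask & (state_room == high_reward_room)
    low = vmask & (state_room != high_reward_room)

    t_pre_model = TransitionModel.from_state_dict(ckpt_pre.transition)
    t_post_model = TransitionModel.from_state_dict(ckpt_post.transition)
    n_post = t_post_model.n_states
    t_pre = np.stack(
        [
            np.stack([t_pre_model.probs(s, a, n_pre) for s in range(n_pre)])
            for a in range(N_ACTIONS)
        ]
    )
    t_post = np.stack(
        [
            np.stack([t_post_model.probs(s, a, n_post)[:n_pre] for s in range(n_pre)])
            for a in range(N_ACTIONS)
        ]
    )
    tmask = t_pre > transition_threshold
    return {
        "value_low": changes[low],
        "value_high": changes[high],
        "transition": (t_post - t_pre)[tmask],
    }


# -- behavioral summaries -------------------------------------------------

def room_preference(
    cx_logs: list[CXLog], geometry: MazeGeometry, high_reward_room: int = 0
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Reward-site visit counts per room and paired t-tests across learners
    of the high-reward room against each low-reward room."""
    counts = pd.DataFrame(
        [log.room_counts for log in cx_logs],
        columns=[f"room{r}" for r in range(3)],
    )
    counts.index.name = "learner"
    tests: dict[str, tuple[float, float]] = {}
    lows = [r for r in range(3) if r != high_reward_room]
    for r in lows:
        diff = counts[f"room{high_reward_room}"] - counts[f"room{r}"]
        if len(counts) <= 1:
            t, p = float("nan"), float("nan")
        elif np.allclose(diff, 0.0):
            t, p = 0.0, 1.0  # identical visit counts: no preference
        else:
            t, p = stats.ttest_rel(
                counts[f"room{high_reward_room}"], counts[f"room{r}"]
            )
        tests[f"room{high_reward_room}_vs_room{r}"] = (float(t), float(p))
    return counts, tests


def learning_curves(logs: list[TrialLog], window: int = 100) -> pd.DataFrame:
    """Per-trial accuracy, path length, sweep depth and certainty, with a
    rolling-window smooth."""
    df = pd.DataFrame(
        {
            "trial": [t.trial for t in logs],
            "phase": [t.phase for t in logs],
            "success": [float(t.success) for t in logs],
            "path_length": [t.path_length for t in logs],
            "steps": [t.steps for t in logs],
            "sweep_depth": [t.mean_sweep_depth for t in logs],
            "certainty": [t.mean_certainty for t in logs],
        }
    )
    roll = df[["success", "path_length", "sweep_depth", "certainty"]].rolling(
        window, min_periods=1
    ).mean()
    for col in roll:
        df[f"{col}_smooth"] = roll[col]
    return df


def sweep_length_map(
    logs: list[TrialLog],
    geometry: MazeGeometry,
    goal: int | None = None,
    resolution: float = 1.0,
) -> SpatialMap:
    """Mean control-sweep stop depth per place (per cued goal), from
    per-step trial records."""
    ix0, iy0, nx, ny = _raster_cells(geometry, resolution)
    total = np.zeros((nx, ny))
    count = np.zeros((nx, ny))
    for t in logs:
        if goal is not None and t.goal != goal:
            continue
        if not t.step_records:
            continue
        for x, y, _, _, depth in t.step_records:
            cx = math.floor(x / resolution) - ix0
            cy = math.floor(y / resolution) - iy0
            total[cx, cy] += depth
            count[cx, cy] += 1
    values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return SpatialMap(values, (ix0, iy0), resolution, statistic="sweep_depth", goal=goal)


def render_map(spatial_map: SpatialMap, path: str, cmap: str = "viridis") -> None:
    """Render a spatial raster to an image file (undecoded cells blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ix0, iy0 = spatial_map.origin
    res = spatial_map.resolution
    nx, ny = spatial_map.values.shape
    extent = (ix0 * res, (ix0 + nx) * res, iy0 * res, (iy0 + ny) * res)
    ax.imshow(
        spatial_map.values.T, origin="lower", extent=extent, cmap=cmap,
        interpolation="nearest",
    )
    title = spatial_map.statistic
    if spatial_map.goal is not None:
        title += f" (goal {spatial_map.goal})"
    ax.set_title(title)
    ax.set_xlabel("x (units)")
    ax.set_ylabel("y (units)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def rotational_symmetry(map_a: SpatialMap, geometry: MazeGeometry) -> float:
    """Correlation between a map and its 120-degree rotation about the
    origin (cells present in both)."""
    res = map_a.resolution
    ix0, iy0 = map_a.origin
    vals = map_a.values
    pairs = []
    c, s = math.cos(2 * math.pi / 3), math.sin(2 * math.pi / 3)
    nx, ny = vals.shape
    for i in range(nx):
        for j in range(ny):
            if np.isnan(vals[i, j]):
                continue
            x = (i + ix0 + 0.5) * res
            y = (j + iy0 + 0.5) * res
            rx, ry = c * x - s * y, s * x + c * y
            ri = math.floor(rx / res) - ix0
            rj = math.floor(ry / res) - iy0
            if 0 <= ri < nx and 0 <= rj < ny and not np.isnan(vals[ri, rj]):
                pairs.append((vals[i, j], vals[ri, rj]))
    if len(pairs) < 3:
        return float("nan")
    arr = np.asarray(pairs)
    if np.allclose(arr.std(axis=0), 0.0):
        return 1.0
    return float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
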