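"""Simplified grid-cell bank and head-direction sensor.

Each grid cell is a hexagonal grating built from three plane waves 60
degrees apart:

    G(x, y) = 2/3 * (1/3 * sum_{i=1..3} cos(k_i . (r - r0)) + 1/2)

with wave vectors k_i of a common spatial frequency (cycles per maze)
and random orientation/phase frozen per agent.  Activations are
binarized at a threshold on a fixed spatial sampling grid and packed
into an integer code; together with the 4-sector head-direction signal
this yields the discrete sensory token x = G x h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SensorConfig
from .maze import AgentPose, MazeGeometry

N_HEAD_SECTORS = 4
_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SensoryToken:
    grid_code: int
    head_sector: int


class GridCellBank:
    """Bank of thresholded grid-cell gratings with frozen random parameters."""

    def __init__(self, config: SensorConfig | None = None, rng: np.random.Generator | None = None):
        cfg = config or SensorConfig()
        cfg.validate()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = cfg
        n = cfg.n_cells
        freqs = cfg.freq_min + cfg.freq_step * np.arange(n, dtype=float)
        if abs(freqs[-1] - cfg.freq_max) > 1e-9:
            freqs = np.linspace(cfg.freq_min, cfg.freq_max, n)
        self.frequencies = freqs  # cycles per maze extent
        self.orientations = rng.uniform(0.0, math.pi / 3.0, size=n)
        half = cfg.maze_extent / 2.0
        self.phases = rng.uniform(-half, half, size=(n, 2))  # r0 per cell
        self._wave_vectors = self._build_wave_vectors()
        self._code_cache: dict[tuple[int, int], int] = {}

    @classmethod
    def from_params(
        cls,
        config: SensorConfig,
        frequencies: np.ndarray,
        orientations: np.ndarray,
        phases: np.ndarray,
    ) -> "GridCellBank":
        bank = cls.__new__(cls)
        bank.config = config
        bank.frequencies = np.asarray(frequencies, dtype=float)
        bank.orientations = np.asarray(orientations, dtype=float)
        bank.phases = np.asarray(phases, dtype=float)
        bank._wave_vectors = bank._build_wave_vectors()
        bank._code_cache = {}
        return bank

    def _build_wave_vectors(self) -> np.ndarray:
        # (n_cells, 3, 2): three wave directions 60 degrees apart per cell
        mags = _TWO_PI * self.frequencies / self.config.maze_extent
        angles = self.orientations[:, None] + (math.pi / 3.0) * np.arange(3)[None, :]
        return mags[:, None, None] * np.stack(
            [np.cos(angles), np.sin(angles)], axis=-1
        )

    # -- activations -----------------------------------------------------
    def activations(self, x: float | np.ndarray, y: float | np.ndarray) -> np.ndarray:
        """Grating values of every cell at (x, y); each lies in [0, 1]."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx = x[..., None, None] - self.phases[:, 0][:, None]
        dy = y[..., None, None] - self.phases[:, 1][:, None]
        phase = (
            self._wave_vectors[..., 0] * dx + self._wave_vectors[..., 1] * dy
        )
        s = np.cos(phase).sum(axis=-1)  # (..., n_cells)
        return (2.0 / 3.0) * (s / 3.0 + 0.5)

    def code_at_cell(self, ix: int, iy: int) -> int:
        """Binary grid code at sampling-grid cell (ix, iy)."""
        key = (ix, iy)
        code = self._code_cache.get(key)
        if code is None:
            step = self.config.sample_step
            act = self.activations(ix * step, iy * step)
            bits = act >= self.config.threshold
            code = int(sum(1 << i for i, b in enumerate(bits) if b))
            self._code_cache[key] = code
        return code

    def grid_code(self, x: float, y: float) -> int:
        """Integer code of the thresholded bank, on the sampling grid."""
        step = self.config.sample_step
        return self.code_at_cell(math.floor(x / step), math.floor(y / step))

    def sensory_token(self, pose: AgentPose) -> SensoryToken:
        return SensoryToken(self.grid_code(pose.x, pose.y), head_sector(pose.heading))

    # -- maze-wide enumeration ------------------------------------------
    def walkable_cells(self, geometry: MazeGeometry) -> list[tuple[int, int]]:
        """Sampling-grid cells whose sample point lies in the walkable region."""
        step = self.config.sample_step
        minx, miny, maxx, maxy = geometry.walkable.bounds
        cells = []
        for ix in range(math.floor(minx / step) - 1, math.ceil(maxx / step) + 2):
            for iy in range(math.floor(miny / step) - 1, math.ceil(maxy / step) + 2):
                if geometry.contains(ix * step, iy * step):
                    cells.append((ix, iy))
        return cells

    def code_positions(self, geometry: MazeGeometry) -> dict[int, np.ndarray]:
        """Map each grid code to the walkable sample points producing it."""
        step = self.config.sample_step
        groups: dict[int, list[tuple[float, float]]] = {}
        for ix, iy in self.walkable_cells(geometry):
            groups.setdefault(self.code_at_cell(ix, iy), []).append(
                (ix * step, iy * step)
            )
        return {c: np.asarray(p, dtype=float) for c, p in groups.items()}


def grid_activation(
    frequency: float,
    orientation: float,
    phase_xy: tuple[float, float],
    x: float,
    y: float,
    maze_extent: float = 16.0,
) -> float:
    """Three-grating hexagonal activation of a single grid cell, in [0, 1]."""
    mag = _TWO_PI * frequency / maze_extent
    dx, dy = x - phase_xy[0], y - phase_xy[1]
    s = 0.0
    for j in range(3):
        a = orientation + j * math.pi / 3.0
        s += math.cos(mag * (math.cos(a) * dx + math.sin(a) * dy))
    return (2.0 / 3.0) * (s / 3.0 + 0.5)


def head_sector(heading: float) -> int:
    """Quadrant sector of the heading, boundaries at -45/45/135/225 degrees.

    Sector 0 is centered on 0 degrees; intervals are half-open
    [-45, 45) -> 0, [45, 135) -> 1, etc.
    """
    return int(((heading + math.pi / 4.0) % _TWO_PI) // (math.pi / 2.0))


def sensory_token(bank: GridCellBank, pose: AgentPose) -> SensoryToken:
    """Combined grid-code x head-direction observation at a pose."""
    return bank.sensory_token(pose)
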