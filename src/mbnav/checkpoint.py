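"""Checkpoint serialization: learned models + sensor bank + RNG state.

One NPZ file holds the dense arrays; a JSON sidecar string inside the
archive holds the configuration, scalar hyperparameters, RNG states and
a format version.  ``restore`` of a checkpoint reproduces identical
subsequent behavior under the archived RNG state.
"""

from __future__ import annotations

import json

import numpy as np

from .agent import Agent, AgentCheckpoint
from .maze import MazeGeometry

FORMAT_VERSION = 1


class CheckpointError(RuntimeError):
    """Corrupt, truncated or incompatible checkpoint file."""


def save_checkpoint(ckpt: AgentCheckpoint, path: str) -> None:
    meta = {
        "version": FORMAT_VERSION,
        "config": ckpt.config,
        "learn_step": ckpt.learn_step,
        "rng_state": ckpt.rng_state,
        "categorization_alpha": ckpt.categorization["alpha"],
        "transition_eps": ckpt.transition["eps"],
        "value_gamma": ckpt.value["gamma"],
        "value_alpha0": ckpt.value["alpha0"],
        "value_floor": ckpt.value["floor"],
        "bank_scalars": {
            k: ckpt.bank[k] for k in ("threshold", "sample_step", "maze_extent")
        },
    }
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        cat_table=ckpt.categorization["table"],
        cat_token_keys=ckpt.categorization["token_keys"],
        trans_counts=ckpt.transition["counts"],
        value_phi=ckpt.value["phi"],
        bank_frequencies=ckpt.bank["frequencies"],
        bank_orientations=ckpt.bank["orientations"],
        bank_phases=ckpt.bank["phases"],
    )


def load_checkpoint(path: str) -> AgentCheckpoint:
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            if meta.get("version") != FORMAT_VERSION:
                raise CheckpointError(
                    f"checkpoint format version {meta.get('version')} "
                    f"is not supported (expected {FORMAT_VERSION})"
                )
            return AgentCheckpoint(
                config=meta["config"],
                categorization={
                    "alpha": meta["categorization_alpha"],
                    "table": data["cat_table"],
                    "token_keys": data["cat_token_keys"],
                },
                transition={
                    "eps": meta["transition_eps"],
                    "counts": data["trans_counts"],
                },
                value={
                    "gamma": meta["value_gamma"],
                    "alpha0": meta["value_alpha0"],
                    "floor": meta["value_floor"],
                    "phi": data["value_phi"],
                },
                bank={
                    "frequencies": data["bank_frequencies"],
                    "orientations": data["bank_orientations"],
                    "phases": data["bank_phases"],
                    **meta["bank_scalars"],
                },
                rng_state=meta["rng_state"],
                learn_step=int(meta["learn_step"]),
                version=FORMAT_VERSION,
            )
    except CheckpointError:
        raise
    except Exception as exc:  # zipfile/json/key errors on truncated files
        raise CheckpointError(f"cannot read checkpoint {path!r}: {exc}") from exc


def restore_agent(path: str, geometry: MazeGeometry | None = None) -> Agent:
    return Agent.from_checkpoint(load_checkpoint(path), geometry)
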