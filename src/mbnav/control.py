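"""Action selection: shallow controller, forward sweeps, adaptive depth.

The shallow controller maximizes the one-step reward expectancy

    a_t = argmax_a P_v(r=1 | g, argmax_{s'} P_M(s'|s_t, a)).

The sweep controller runs one rollout per action primitive: the first
simulated transition applies that action, subsequent steps follow the
greedy local maximization over all actions, and reward evidence
accumulates as the running sum of state values.  All three rollouts
deepen in lockstep until the decision certainty between the two best
actions,

    d = log2(evidence_best) - log2(evidence_second),

exceeds a threshold (or the depth cap is hit), after which the action
is sampled by a softmax over the raw accumulated evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .world_model import N_ACTIONS, TransitionModel, ValueModel, greedy_step


@dataclass
class SweepTrace:
    """Record of one adaptive-depth sweep decision."""

    states: list[list[int]] = field(default_factory=lambda: [[], [], []])
    evidence: np.ndarray = field(default_factory=lambda: np.zeros(N_ACTIONS))
    stop_depth: int = 0
    stop_certainty: float = 0.0
    action: int = -1


def shallow_select(
    s: int,
    g: int | None,
    transition: TransitionModel,
    value: ValueModel,
    pooling: str = "sum",
) -> int:
    """One-step local maximization; ties resolve in action order
    forward < turn-left < turn-right.

    The landing state of each action is the transition argmax (lowest
    state id on ties, including the untrained uniform row).
    """
    best_a = 0
    best_v = -np.inf
    for a in range(N_ACTIONS):
        cand = transition.greedy_successor(s, a)
        v = value.value(g, cand) if g is not None else value.pooled_value(cand, pooling)
        if v > best_v:
            best_v = v
            best_a = a
    return best_a


def decision_certainty(e_best: float, e_second: float) -> float:
    """log2 ratio of the two largest accumulated evidences, in bits.

    Zero evidence on either side yields certainty 0, which keeps the
    sweeps deepening early in training.
    """
    if e_best <= 0.0 or e_second <= 0.0:
        return 0.0
    return math.log2(e_best) - math.log2(e_second)


def sweep_rollout(
    s_t: int,
    a_first: int,
    l_max: int,
    g: int | None,
    transition: TransitionModel,
    value: ValueModel,
    pooling: str = "sum",
) -> tuple[list[int], np.ndarray]:
    """Single rollout for action `a_first`: simulated states and the
    per-depth cumulative reward evidence (non-decreasing).

    Rollouts truncate at dead ends (states whose transition rows hold
    no observations); the cumulative evidence then stays frozen at the
    remaining depths.
    """
    states: list[int] = []
    evidence = np.zeros(l_max, dtype=float)
    acc = 0.0
    dead = transition.row_count(s_t, a_first) <= 0.0
    s = -1 if dead else transition.greedy_successor(s_t, a_first)
    for j in range(l_max):
        if not dead and j > 0:
            nxt = greedy_step(transition, value, g, s, pooling)
            if nxt is None:
                dead = True
        if not dead:
            if j > 0:
                s = nxt
            states.append(s)
            acc += value.value(g, s) if g is not None else value.pooled_value(s, pooling)
        evidence[j] = acc
    return states, evidence


def _softmax_sample(
    evidence: np.ndarray, beta: float, rng: np.random.Generator
) -> int:
    """Softmax over the raw accumulated evidence (exponent beta).

    Working on raw sums keeps the choice sharpness independent of sweep
    depth: rollouts that merge onto a shared continuation contribute
    identical terms to every action's evidence, which cancel in the
    softmax differences.
    """
    if evidence.sum() <= 0.0:
        return int(rng.integers(N_ACTIONS))
    z = beta * evidence
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(N_ACTIONS, p=p))


def adaptive_sweep_select(
    s: int,
    g: int | None,
    transition: TransitionModel,
    value: ValueModel,
    rng: np.random.Generator,
    beta: float = 80.0,
    d_thr: float = 0.15,
    l_cap: int = 9,
    pooling: str = "sum",
) -> tuple[int, SweepTrace]:
    """Adaptive-depth sweep decision: three lockstep rollouts, an
    information stop rule, and softmax selection over the raw
    accumulated evidence (exponent beta)."""
    trace = SweepTrace()
    cur = np.full(N_ACTIONS, -1, dtype=np.int64)  # current simulated state
    alive = np.zeros(N_ACTIONS, dtype=bool)
    evidence = trace.evidence
    for a in range(N_ACTIONS):
        if transition.row_count(s, a) > 0.0:
            alive[a] = True
            cur[a] = transition.greedy_successor(s, a)
    depth = 0
    certainty = 0.0
    while depth < l_cap and alive.any():
        depth += 1
        for a in range(N_ACTIONS):
            if not alive[a]:
                continue
            if depth > 1:
                nxt = greedy_step(transition, value, g, int(cur[a]), pooling)
                if nxt is None:
                    alive[a] = False
                    continue
                cur[a] = nxt
            sa = int(cur[a])
            trace.states[a].append(sa)
            evidence[a] += (
                value.value(g, sa) if g is not None else value.pooled_value(sa, pooling)
            )
        top = np.sort(evidence)[-2:]
        certainty = decision_certainty(float(top[1]), float(top[0]))
        if certainty > d_thr:
            break
    trace.stop_depth = depth
    trace.stop_certainty = certainty
    trace.action = _softmax_sample(evidence, beta, rng)
    return trace.action, trace


def pooled_free_run_select(
    s: int,
    transition: TransitionModel,
    value: ValueModel,
    rng: np.random.Generator,
    beta: float = 80.0,
    d_thr: float = 0.15,
    l_cap: int = 9,
    pooling: str = "sum",
) -> tuple[int, SweepTrace]:
    """CX-test selection: adaptive sweeps with every value lookup pooled
    over the nine goal sites (no cued goal)."""
    return adaptive_sweep_select(
        s, None, transition, value, rng, beta=beta, d_thr=d_thr, l_cap=l_cap,
        pooling=pooling,
    )
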