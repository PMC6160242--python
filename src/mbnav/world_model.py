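"""Conjugate world models of the MB-RL controller.

Two halves mirror the hippocampus / ventral-striatum division of labor:

* ``TransitionModel`` — Dirichlet pseudo-counts theta_{s,a}(s') over
  latent successor states; the posterior P_M(s'|s,a) is the normalized
  count vector with a small symmetric prior epsilon per successor.
* ``ValueModel`` — goal-conditioned Beta counts phi_{g,s} = (failures,
  successes); P_v(r=1|g,s) is the Beta posterior mean, 0.5 for fresh
  entries (Beta(1,1)).

Value learning is a Bayesian analogue of TD learning: counts move a
fraction alpha_t toward the observed outcome phi_Obs = [1-r, r] plus the
discounted future counts phi_tilde accumulated along a greedy forward
sweep through the transition model.
"""

from __future__ import annotations

import math

import numpy as np

N_ACTIONS = 3
N_GOALS = 9


def learning_rate(t: int, alpha0: float = 1.5, clamp_t: int = 10) -> float:
    """Log-schedule learning rate alpha0 / log10(t), clamped for t <= clamp_t.

    The printed schedule is singular at t = 1; clamping to alpha0 (the
    schedule's value at t = 10) keeps early updates finite.
    """
    if t < 1:
        raise ValueError("learning step index must be >= 1")
    if t <= clamp_t:
        return alpha0
    return alpha0 / math.log10(t)


class TransitionModel:
    """Dirichlet-multinomial successor model theta_{s,a}(s')."""

    def __init__(self, eps: float = 0.01, capacity: int = 256):
        if eps <= 0:
            raise ValueError("Dirichlet prior pseudo-count must be positive")
        self.eps = float(eps)
        self._cap = capacity
        self._counts = np.zeros((N_ACTIONS, capacity, capacity), dtype=float)
        self._row_total = np.zeros((N_ACTIONS, capacity), dtype=float)
        # cached per-row argmax of the raw counts (prior is symmetric, so
        # it never changes the ordering; empty rows argmax to state 0,
        # the lowest-id tie of the uniform prior)
        self._row_argmax = np.zeros((N_ACTIONS, capacity), dtype=np.int64)
        self._row_max = np.zeros((N_ACTIONS, capacity), dtype=float)
        self.n_states = 0

    def ensure_states(self, n: int) -> None:
        while n > self._cap:
            new_cap = self._cap * 2
            counts = np.zeros((N_ACTIONS, new_cap, new_cap), dtype=float)
            counts[:, : self._cap, : self._cap] = self._counts
            self._counts = counts
            for name in ("_row_total", "_row_max"):
                arr = np.zeros((N_ACTIONS, new_cap), dtype=float)
                arr[:, : self._cap] = getattr(self, name)
                setattr(self, name, arr)
            amax = np.zeros((N_ACTIONS, new_cap), dtype=np.int64)
            amax[:, : self._cap] = self._row_argmax
            self._row_argmax = amax
            self._cap = new_cap
        self.n_states = max(self.n_states, n)

    # -- learning --------------------------------------------------------
    def update(self, s: int, a: int, s_next: int) -> None:
        """Count one observed transition (s, a) -> s_next."""
        self.ensure_states(max(s, s_next) + 1)
        c = self._counts[a, s, s_next] + 1.0
        self._counts[a, s, s_next] = c
        self._row_total[a, s] += 1.0
        if c > self._row_max[a, s] or (
            c == self._row_max[a, s] and s_next < self._row_argmax[a, s]
        ):
            self._row_max[a, s] = c
            self._row_argmax[a, s] = s_next

    def update_soft(
        self, sources: np.ndarray, weights: np.ndarray, a: int, s_next: int
    ) -> None:
        """Distribute one observed transition over a source-state belief.

        Each candidate source s_i receives fractional count w_i; the
        weights are the (truncated, renormalized) categorization belief
        of the previous observation.  Spreading the conjugate update
        over the belief keeps the rows of plausible-but-not-yet-argmax
        states trained, which the congruence likelihood needs in order
        to retain newly founded categories.
        """
        n = int(max(np.max(sources), s_next)) + 1
        self.ensure_states(n)
        counts, totals = self._counts, self._row_total
        rmax, rarg = self._row_max, self._row_argmax
        for s, w in zip(sources, weights):
            c = counts[a, s, s_next] + w
            counts[a, s, s_next] = c
            totals[a, s] += w
            if c > rmax[a, s] or (c == rmax[a, s] and s_next < rarg[a, s]):
                rmax[a, s] = c
                rarg[a, s] = s_next

    # -- posterior queries ----------------------------------------------
    def probs(self, s: int, a: int, n: int | None = None) -> np.ndarray:
        """Posterior row P_M(.|s, a) over the first n registered states."""
        n = self.n_states if n is None else n
        self.ensure_states(max(n, s + 1))
        row = self._counts[a, s, :n] + self.eps
        return row / (self._row_total[a, s] + n * self.eps)

    def prob_to(self, a: int, s_next: int, n: int | None = None) -> np.ndarray:
        """Column P_M(s_next | s_i, a) for all source states s_i < n."""
        n = self.n_states if n is None else n
        self.ensure_states(max(n, s_next + 1))
        col = self._counts[a, :n, s_next] + self.eps
        return col / (self._row_total[a, :n] + n * self.eps)

    def greedy_successor(self, s: int, a: int) -> int:
        """argmax_{s'} P_M(s'|s,a); lowest id on ties / empty rows."""
        if s >= self.n_states:
            return 0
        return int(self._row_argmax[a, s])

    def row_count(self, s: int, a: int) -> float:
        """Total observed transitions out of (s, a); 0 marks a dead end."""
        if s >= self.n_states:
            return 0.0
        return float(self._row_total[a, s])

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        n = self.n_states
        return {"eps": self.eps, "counts": self._counts[:, :n, :n].copy()}

    @classmethod
    def from_state_dict(cls, state: dict) -> "TransitionModel":
        counts = np.asarray(state["counts"], dtype=float)
        n = counts.shape[1]
        cap = max(256, 1 << int(np.ceil(np.log2(max(n, 1)))))
        model = cls(eps=float(state["eps"]), capacity=cap)
        model._counts[:, :n, :n] = counts
        model._row_total[:, :n] = counts.sum(axis=2)
        model._row_argmax[:, :n] = counts.argmax(axis=2)
        model._row_max[:, :n] = counts.max(axis=2)
        model.n_states = n
        return model


class ValueModel:
    """Goal-conditioned Beta-binomial reward model phi_{g,s}(r)."""

    def __init__(
        self,
        gamma: float = 0.90,
        alpha0: float = 1.5,
        n_goals: int = N_GOALS,
        capacity: int = 256,
        floor: float = 1e-3,
    ):
        if not (0.0 <= gamma < 1.0):
            raise ValueError("discount gamma must lie in [0, 1)")
        self.gamma = float(gamma)
        self.alpha0 = float(alpha0)
        self.n_goals = int(n_goals)
        self.floor = float(floor)
        self._cap = capacity
        self._phi = np.ones((n_goals, capacity, 2), dtype=float)  # Beta(1,1)
        self.n_states = 0

    def ensure_states(self, n: int) -> None:
        while n > self._cap:
            new_cap = self._cap * 2
            phi = np.ones((self.n_goals, new_cap, 2), dtype=float)
            phi[:, : self._cap] = self._phi
            self._phi = phi
            self._cap = new_cap
        self.n_states = max(self.n_states, n)

    @property
    def phi(self) -> np.ndarray:
        return self._phi[:, : self.n_states]

    def counts(self, g: int, s: int) -> np.ndarray:
        self.ensure_states(s + 1)
        return self._phi[g, s]

    def value(self, g: int, s: int) -> float:
        """Posterior reward probability P_v(r=1|g,s)."""
        self.ensure_states(s + 1)
        f, r = self._phi[g, s]
        return float(r / (f + r))

    def values(self, g: int, states: np.ndarray) -> np.ndarray:
        self.ensure_states(int(np.max(states)) + 1 if len(states) else 0)
        phi = self._phi[g, states]
        return phi[:, 1] / phi.sum(axis=1)

    def pooled_value(self, s: int, mode: str = "sum") -> float:
        """Goal-pooled value used in the cue-free CX test."""
        self.ensure_states(s + 1)
        phi = self._phi[:, s]
        v = phi[:, 1] / phi.sum(axis=1)
        return float(v.max()) if mode == "max" else float(v.sum())

    def value_table(self) -> np.ndarray:
        """P_v(r=1|g,s) for all goals and registered states, (n_goals, n)."""
        phi = self.phi
        return phi[..., 1] / phi.sum(axis=-1)

    def td_update(
        self, g: int, s: int, r: int, phi_tilde: np.ndarray, alpha_t: float
    ) -> None:
        """Move counts a fraction alpha_t toward phi_Obs + phi_tilde."""
        self.ensure_states(s + 1)
        obs = np.array([1.0 - r, float(r)])
        phi = self._phi[g, s]
        phi += alpha_t * (obs + phi_tilde - phi)
        np.maximum(phi, self.floor, out=phi)

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "alpha0": self.alpha0,
            "floor": self.floor,
            "phi": self.phi.copy(),
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "ValueModel":
        phi = np.asarray(state["phi"], dtype=float)
        n_goals, n, _ = phi.shape
        cap = max(256, 1 << int(np.ceil(np.log2(max(n, 1)))))
        model = cls(
            gamma=float(state["gamma"]),
            alpha0=float(state["alpha0"]),
            n_goals=n_goals,
            capacity=cap,
            floor=float(state["floor"]),
        )
        model._phi[:, :n] = phi
        model.n_states = n
        return model


def greedy_step(
    transition: TransitionModel,
    value: ValueModel,
    g: int | None,
    s: int,
    pooling: str = "sum",
) -> int | None:
    """One step of the local maximization shared by all sweeps.

    Among the three candidate landing states (the transition-argmax of
    each action), return the one with the greatest reward expectancy
    for goal g (or the goal-pooled expectancy when g is None).  Actions
    whose transition row is empty contribute no candidate; None marks a
    dead end.
    """
    best_s = -1
    best_v = -np.inf
    for a in range(N_ACTIONS):
        if transition.row_count(s, a) <= 0.0:
            continue
        cand = transition.greedy_successor(s, a)
        v = value.value(g, cand) if g is not None else value.pooled_value(cand, pooling)
        if v > best_v:
            best_v = v
            best_s = cand
    return None if best_s < 0 else best_s


def accumulate_future_conjugate(
    value: ValueModel,
    transition: TransitionModel,
    g: int,
    s_t: int,
    depth: int,
    gamma: float | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Discounted sum of Beta parameter vectors along a greedy learning sweep.

        phi_tilde = sum_{i=1..l} gamma^i * phi_{g, s_i}

    with s_0 = s_t and each s_i chosen by `greedy_step`.  The sweep
    truncates at dead ends (states with no observed outgoing
    transitions).

    With ``normalize=True`` (the default used during training) the sweep
    is read as a multi-step lookahead backup: the reward expectancy
    bootstrapped into the target is the best discounted value found
    along the sweep,

        v* = max_{i=1..l} gamma^{i-1} * P_v(r=1|g, s_i),

    returned as the parameter vector [1-v*, v*] scaled to total mass
    gamma / (1 - gamma) — the self-consistent stationary count magnitude
    of the one-step scheme (mass M solves M = 1 + gamma*M).  Mixing the
    target phi_Obs + phi_tilde then reproduces the Bellman backup
    v <- (1-gamma)*r + gamma^i * v_i per step, at depth 1 it is exactly
    the one-step bootstrap, and deeper sweeps merely propagate distant
    reward expectancy faster.

    ``normalize=False`` accumulates the literal discounted raw-count sum
    sum_i gamma^i * phi_i; that form is only stable in closed-loop
    training when sum_{i=1..l} gamma^i < 1 (depth 1) — for deeper sweeps
    the count magnitudes grow geometrically.
    """
    if depth < 1:
        raise ValueError("sweep depth must be >= 1")
    gamma = value.gamma if gamma is None else gamma
    acc = np.zeros(2, dtype=float)
    best = 0.0
    s = s_t
    disc = 1.0
    visited = False
    for _ in range(depth):
        s = greedy_step(transition, value, g, s)
        if s is None:
            break
        visited = True
        phi = value.counts(g, s)
        if normalize:
            v = disc * (phi[1] / phi.sum())  # disc = gamma^(i-1)
            if v > best:
                best = v
            disc *= gamma
        else:
            disc *= gamma  # disc = gamma^i
            acc += disc * phi
    if not normalize:
        return acc
    if not visited or gamma >= 1.0:
        return acc
    mass = gamma / (1.0 - gamma)
    return np.array([mass * (1.0 - best), mass * best])
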