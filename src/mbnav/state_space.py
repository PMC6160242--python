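"""Nonparametric latent-state categorization of sensory tokens.

The categorization model P_c(s|x) maps every experienced sensory token
to a probability column over an open-ended set of latent states.  Novel
tokens receive a Chinese-restaurant-process column: existing states in
proportion to their popularity (total probability mass across all
columns) and one brand-new state with mass alpha / A, where
A = alpha + total popularity.  A transition-congruence update then
continually reshapes columns so that category assignments that agree
with the learned state-transition model gain mass:

    P_c^{t+1}(s_i|x_{t-1})  ∝  P_M(s_t|s_i, a_{t-1}) * P_c^t(s_i|x_{t-1})

which is exactly a Bayes posterior over the category of x_{t-1} with the
previous column as prior and the observed transition as likelihood.
"""

from __future__ import annotations

import numpy as np

TokenKey = tuple[int, int]  # (grid_code, head_sector)


class UnknownTokenError(KeyError):
    """A token was queried before being observed."""


class CategorizationModel:
    """Expandable conditional table P_c(s|x) with a CRP prior."""

    def __init__(self, alpha: float = 20.0, capacity: int = 256):
        if alpha <= 0:
            raise ValueError("CRP concentration alpha must be positive")
        self.alpha = float(alpha)
        self._cap = capacity
        # one state row is created per novel token, so the table is square
        self._table = np.zeros((capacity, capacity), dtype=float)
        self._popularity = np.zeros(capacity, dtype=float)
        self._token_index: dict[TokenKey, int] = {}
        self.n_states = 0
        self.n_tokens = 0

    # -- introspection ---------------------------------------------------
    @property
    def table(self) -> np.ndarray:
        """Dense view P_c(s|x), shape (n_states, n_tokens)."""
        return self._table[: self.n_states, : self.n_tokens]

    @property
    def popularity(self) -> np.ndarray:
        """Per-state mass sum_j P_c(s|x_j), maintained incrementally."""
        return self._popularity[: self.n_states]

    def token_keys(self) -> list[TokenKey]:
        keys: list[TokenKey] = [None] * self.n_tokens  # type: ignore[list-item]
        for k, j in self._token_index.items():
            keys[j] = k
        return keys

    def has_token(self, token: TokenKey) -> bool:
        return tuple(token) in self._token_index

    def token_column(self, token: TokenKey) -> np.ndarray:
        j = self._token_index.get(tuple(token))
        if j is None:
            raise UnknownTokenError(token)
        return self._table[: self.n_states, j]

    def token_id(self, token: TokenKey) -> int:
        j = self._token_index.get(tuple(token))
        if j is None:
            raise UnknownTokenError(token)
        return j

    def active_states(self) -> np.ndarray:
        """States that are the argmax category of at least one token."""
        if self.n_tokens == 0:
            return np.zeros(0, dtype=int)
        return np.unique(np.argmax(self.table, axis=0))

    # -- growth ----------------------------------------------------------
    def _grow(self) -> None:
        new_cap = self._cap * 2
        table = np.zeros((new_cap, new_cap), dtype=float)
        table[: self._cap, : self._cap] = self._table
        self._table = table
        pop = np.zeros(new_cap, dtype=float)
        pop[: self._cap] = self._popularity
        self._popularity = pop
        self._cap = new_cap

    def observe_token(self, token: TokenKey) -> int:
        """Add a CRP column for a novel token; idempotent for known ones.

        Returns the token's column index.
        """
        key = tuple(token)
        j = self._token_index.get(key)
        if j is not None:
            return j
        if self.n_tokens >= self._cap:
            self._grow()
        j = self.n_tokens
        n = self.n_states
        total = float(self._popularity[:n].sum())
        A = self.alpha + total
        col = self._table[: n + 1, j]
        col[:n] = self._popularity[:n] / A
        col[n] = self.alpha / A  # brand-new state
        self._popularity[: n + 1] += col
        self._token_index[key] = j
        self.n_tokens = j + 1
        self.n_states = n + 1
        return j

    # -- inference & learning -------------------------------------------
    def infer_state(self, token: TokenKey) -> int:
        """Most likely latent state for a known token (ties: lowest id)."""
        return int(np.argmax(self.token_column(token)))

    def infer_state_by_id(self, j: int) -> int:
        """Argmax category of column j (ties: lowest state id)."""
        return int(np.argmax(self._table[: self.n_states, j]))

    def belief(self, j: int, floor: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
        """Truncated, renormalized belief of column j: states with mass
        above `floor` and their weights."""
        col = self._table[: self.n_states, j]
        idx = np.nonzero(col > floor)[0]
        if len(idx) == 0:
            idx = np.array([int(np.argmax(col))])
        w = col[idx]
        return idx, w / w.sum()

    def congruence_update(
        self,
        token_prev: TokenKey | int,
        s_now: int,
        a_prev: int,
        transition,
    ) -> None:
        """Rescale the previous token's column by the transition likelihood
        P_M(s_now | s_i, a_prev) and renormalize.

        A degenerate all-zero product leaves the column unchanged.
        """
        j = (
            token_prev
            if isinstance(token_prev, (int, np.integer))
            else self.token_id(token_prev)
        )
        n = self.n_states
        col = self._table[:n, j]
        factors = transition.prob_to(a_prev, s_now, n)
        new = col * factors
        z = new.sum()
        if z <= 0.0 or not np.isfinite(z):
            return
        new /= z
        self._popularity[:n] += new - col
        self._table[:n, j] = new

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        keys = self.token_keys()
        return {
            "alpha": self.alpha,
            "table": self.table.copy(),
            "token_keys": np.asarray(keys, dtype=np.int64).reshape(self.n_tokens, 2),
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "CategorizationModel":
        table = np.asarray(state["table"], dtype=float)
        n_states, n_tokens = table.shape
        cap = max(256, 1 << int(np.ceil(np.log2(max(n_states, n_tokens, 1)))))
        model = cls(alpha=float(state["alpha"]), capacity=cap)
        model._table[:n_states, :n_tokens] = table
        model._popularity[:n_states] = table.sum(axis=1)
        model.n_states = n_states
        model.n_tokens = n_tokens
        for j, (code, sector) in enumerate(np.asarray(state["token_keys"])):
            model._token_index[(int(code), int(sector))] = j
        return model
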