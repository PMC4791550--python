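"""Continuous-time Bayesian network model objects.

A CTBN factors a joint continuous-time Markov process over a set of
discrete variables: each variable evolves with transition intensities
that depend on the current states of its parent variables.  For one
variable under one parent configuration the dynamics are given by a
conditional intensity matrix (CIM): a square matrix with non-negative
off-diagonal rates (1/h) and rows summing to zero.

Parent configurations are encoded in mixed radix with the *first*
parent varying fastest, i.e. ``code = sum_i state_i * prod_{j<i} k_j``
where parents are taken in the order stored on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "CTBNModel",
    "Trajectory",
    "SufficientStats",
    "validate_cim",
    "parent_config_codes",
    "n_parent_configs",
]


def validate_cim(rates: np.ndarray, atol: float = 1e-9) -> None:
    """Check that ``rates`` is a valid intensity matrix.

    Off-diagonal entries must be non-negative and every row must sum to
    zero (the diagonal holds the negated leave-state rate).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 2 or rates.shape[0] != rates.shape[1]:
        raise DataError(f"CIM must be square, got shape {rates.shape}")
    off = rates.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        raise DataError("CIM off-diagonal entries must be non-negative")
    if not np.allclose(rates.sum(axis=1), 0.0, atol=atol):
        raise DataError("CIM rows must sum to zero")


def n_parent_configs(cards: list[int]) -> int:
    out = 1
    for k in cards:
        out *= k
    return out


def parent_config_codes(parent_states: np.ndarray, cards: list[int]) -> np.ndarray:
    """Mixed-radix encode parent state columns (first parent fastest).

    ``parent_states`` has one column per parent; returns one code per row.
    """
    parent_states = np.atleast_2d(np.asarray(parent_states))
    if parent_states.shape[1] != len(cards):
        raise DataError("parent state columns do not match cardinalities")
    codes = np.zeros(parent_states.shape[0], dtype=np.int64)
    stride = 1
    for j, k in enumerate(cards):
        codes += parent_states[:, j] * stride
        stride *= k
    return codes


@dataclass
class CTBNModel:
    """A CTBN: variables, parent sets and one CIM per parent configuration.

    Attributes
    ----------
    variables : list of str
        Variable (gene) names; order fixes the column layout of
        trajectories sampled from the model.
    n_states : dict
        State cardinality per variable (>= 2).
    parents : dict
        Tuple of parent names per variable; a variable is never its own
        parent.
    cims : dict
        Per variable, an array of shape ``(n_configs, k, k)`` where
        ``n_configs`` is the product of the parent cardinalities and
        rows of each ``k x k`` slice sum to zero.
    initial_state : dict or None
        Deterministic initial state per variable; ``None`` means every
        variable starts in its middle state ``(k - 1) // 2``.
    """

    variables: list[str]
    n_states: dict[str, int]
    parents: dict[str, tuple[str, ...]]
    cims: dict[str, np.ndarray]
    initial_state: dict[str, int] | None = None

    def __post_init__(self):
        names = set(self.variables)
        for v in self.variables:
            if self.n_states[v] < 2:
                raise ConfigError(f"variable {v} must have >= 2 states")
            for p in self.parents.get(v, ()):
                if p not in names:
                    raise ConfigError(f"unknown parent {p} of {v}")
                if p == v:
                    raise ConfigError(f"variable {v} cannot be its own parent")
            expected = n_parent_configs([self.n_states[p] for p in self.parents[v]])
            cim = np.asarray(self.cims[v], dtype=float)
            if cim.shape != (expected, self.n_states[v], self.n_states[v]):
                raise ConfigError(
                    f"{v}: CIM array shape {cim.shape} != "
                    f"({expected}, {self.n_states[v]}, {self.n_states[v]})"
                )
            for u in range(expected):
                validate_cim(cim[u])
            self.cims[v] = cim

    @property
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    def initial_joint_state(self) -> np.ndarray:
        """Initial joint state vector in variable order."""
        if self.initial_state is not None:
            return np.array([self.initial_state[v] for v in self.variables], dtype=np.int64)
        return np.array([(self.n_states[v] - 1) // 2 for v in self.variables], dtype=np.int64)

    def arcs(self) -> set[tuple[str, str]]:
        """Directed (parent, child) pairs."""
        return {(p, v) for v in self.variables for p in self.parents[v]}

    def leave_rate(self, var: str, state: int, joint: np.ndarray) -> float:
        """Leave-state intensity of ``var`` in ``state`` given joint state."""
        idx = self.index
        cards = [self.n_states[p] for p in self.parents[var]]
        pstates = np.array([[joint[idx[p]] for p in self.parents[var]]], dtype=np.int64)
        u = int(parent_config_codes(pstates, cards)[0]) if cards else 0
        return float(-self.cims[var][u, state, state])


@dataclass
class Trajectory:
    """Piecewise-constant joint state path over continuous time.

    Segments are contiguous: segment ``i`` covers
    ``[t0 + cum_durations[i], t0 + cum_durations[i+1])`` with joint state
    ``states[i]``.  Zero-duration segments are allowed (a final grid
    observation contributes zero dwell).
    """

    variables: list[str]
    durations: np.ndarray  # (n_seg,)
    states: np.ndarray  # (n_seg, n_vars) int
    t0: float = 0.0

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=np.int64))
        if self.states.shape[0] != self.durations.shape[0]:
            raise DataError("segment count mismatch between durations and states")
        if self.states.shape[1] != len(self.variables):
            raise DataError("state columns do not match variable list")
        if (self.durations < 0).any():
            raise DataError("segment durations must be >= 0")

    @property
    def n_segments(self) -> int:
        return len(self.durations)

    @property
    def duration(self) -> float:
        return float(self.durations.sum())

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def start_times(self) -> np.ndarray:
        return self.t0 + np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])

    def state_at(self, t: float) -> np.ndarray:
        """Joint state at time ``t`` (right-continuous: the state entered at t)."""
        if t < self.t0 - 1e-12 or t > self.t_end + 1e-12:
            raise DataError(f"time {t} outside trajectory span [{self.t0}, {self.t_end}]")
        starts = self.start_times()
        i = int(np.searchsorted(starts, t + 1e-12, side="right")) - 1
        return self.states[i].copy()

    def n_transitions(self, var: str | None = None) -> int:
        """Count segment boundaries where ``var`` (or any variable) changes."""
        if self.n_segments < 2:
            return 0
        diff = self.states[1:] != self.states[:-1]
        if var is None:
            return int(diff.any(axis=1).sum())
        return int(diff[:, self.variables.index(var)].sum())


@dataclass
class SufficientStats:
    """Dwell times and transition counts for one family (X, U).

    ``T[u, x]`` is the total time X dwelt in state x while the parents
    held configuration u; ``M[u, x, x']`` counts x -> x' transitions of
    X under configuration u (diagonal is zero).
    """

    variable: str
    parent_set: tuple[str, ...]
    T: np.ndarray  # (n_configs, k)
    M: np.ndarray  # (n_configs, k, k)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if (self.T < 0).any():
            raise DataError("dwell times must be non-negative")
        if (self.M < 0).any():
            raise DataError("transition counts must be non-negative")
        if np.trace(self.M.sum(axis=0)) != 0:
            raise DataError("diagonal transition counts must be zero")

    @property
    def n_states(self) -> int:
        return self.T.shape[1]

    @property
    def M_total(self) -> np.ndarray:
        """M[u, x] = total departures from x under configuration u."""
        return self.M.sum(axis=2)

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        if (self.variable, self.parent_set) != (other.variable, other.parent_set):
            raise DataError("cannot add statistics for different families")
        return SufficientStats(self.variable, self.parent_set, self.T + other.T, self.M + other.M)
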