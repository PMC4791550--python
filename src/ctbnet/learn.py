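"""CTBN structure learning: sufficient statistics, Bayesian family score,
greedy hill-climbing and exhaustive search, and parameter posteriors.

The score is the log marginal likelihood of a family's trajectory data
with the intensity and transition-probability parameters integrated out
under conjugate priors: each leave-state intensity q_{x|u} carries a
Gamma(alpha + 1, tau) prior and each row of the embedded transition
matrix theta_{x -> .|u} a symmetric Dirichlet(alpha) prior over the
k - 1 target states.  With dwell times T[x;u], departure counts M[x;u]
and transition counts M[x,x';u]:

    lnML_q     = sum_{u,x} [ lnG(a + M[x;u] + 1) - lnG(a + 1)
                             + (a + 1) ln tau
                             - (a + M[x;u] + 1) ln(tau + T[x;u]) ]
    lnML_theta = sum_{u,x} [ lnG(a (k-1)) - lnG(a (k-1) + M[x;u])
                             + sum_{x' != x} ( lnG(a + M[x,x';u]) - lnG(a) ) ]

The score decomposes over families, so each variable's parent set is
optimized independently; CTBN structures may contain cycles and no
acyclicity constraint applies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import ConfigError, DataError
from .model import SufficientStats, Trajectory, parent_config_codes

__all__ = [
    "LearnConfig",
    "trajectory_from_observations",
    "sufficient_statistics",
    "family_log_score",
    "network_log_score",
    "greedy_structure_search",
    "exhaustive_structure_search",
    "estimate_parameters",
    "SearchResult",
]


@dataclass
class LearnConfig:
    """Structure-learning hyperparameters.

    alpha is the prior pseudo-count, tau the prior pseudo-dwell in
    hours; defaults (0.01, 5) with at most 5 parents per node.
    """

    alpha: float = 0.01
    tau: float = 5.0
    max_parents: int = 5
    search: str = "greedy"

    def __post_init__(self):
        errs = []
        if self.alpha <= 0:
            errs.append("alpha must be > 0")
        if self.tau <= 0:
            errs.append("tau must be > 0")
        if self.max_parents < 0:
            errs.append("max_parents must be >= 0")
        if self.search not in ("greedy", "exhaustive"):
            errs.append("search must be 'greedy' or 'exhaustive'")
        if errs:
            raise ConfigError(errs)


def trajectory_from_observations(states, grid, variables=None) -> Trajectory:
    """Build a piecewise-constant trajectory from point observations.

    ``states`` is (n_vars, n_grid): the state observed at grid time t_i
    is held on [t_i, t_{i+1}); a transition is recorded at t_{i+1} when
    consecutive observations differ.  The final observation contributes
    zero dwell (it opens a segment of zero duration).
    """
    grid = np.asarray(grid, dtype=float)
    states = np.atleast_2d(np.asarray(states, dtype=np.int64))
    if len(grid) < 2:
        raise DataError("grid must contain at least 2 time points")
    if (np.diff(grid) <= 0).any():
        raise DataError("grid must be strictly increasing")
    if states.shape[1] != len(grid):
        raise DataError("states must be defined at every grid point")
    if variables is None:
        variables = [f"X{i}" for i in range(states.shape[0])]
    durations = np.concatenate([np.diff(grid), [0.0]])
    return Trajectory(
        variables=list(variables),
        durations=durations,
        states=states.T.copy(),
        t0=float(grid[0]),
    )


class TrajectoryData:
    """Stacked segment arrays over a collection of trajectories.

    Concatenates all segments; transitions are only counted within a
    trajectory (never across the seam between two trajectories).  Built
    once per learning run so that family statistics reduce to bincounts.
    """

    def __init__(self, trajectories: list[Trajectory], n_states: dict[str, int] | None = None):
        if not trajectories:
            raise DataError("need at least one trajectory")
        self.variables = list(trajectories[0].variables)
        for tr in trajectories:
            if tr.variables != self.variables:
                raise DataError("all trajectories must share the same variable list")
        self.states = np.concatenate([tr.states for tr in trajectories], axis=0)
        self.durations = np.concatenate([tr.durations for tr in trajectories])
        # indices i such that segment i -> i+1 is a within-trajectory boundary
        bounds = []
        offset = 0
        for tr in trajectories:
            n = tr.n_segments
            bounds.append(np.arange(offset, offset + n - 1))
            offset += n
        self.trans_idx = np.concatenate(bounds) if bounds else np.empty(0, dtype=np.int64)
        if n_states is None:
            n_states = {
                v: int(self.states[:, i].max()) + 1 for i, v in enumerate(self.variables)
            }
        self.n_states = n_states
        self.index = {v: i for i, v in enumerate(self.variables)}
        self.total_duration = float(self.durations.sum())

    def family_stats(self, variable: str, parent_set) -> SufficientStats:
        parent_set = tuple(parent_set)
        if variable not in self.index:
            raise DataError(f"variable {variable} absent from trajectories")
        xi = self.index[variable]
        k = self.n_states[variable]
        cards = [self.n_states[p] for p in parent_set]
        n_cfg = int(np.prod(cards)) if cards else 1
        if parent_set:
            pidx = [self.index[p] for p in parent_set]
            codes = parent_config_codes(self.states[:, pidx], cards)
        else:
            codes = np.zeros(len(self.durations), dtype=np.int64)
        x = self.states[:, xi]
        T = np.bincount(codes * k + x, weights=self.durations, minlength=n_cfg * k)
        T = T.reshape(n_cfg, k)
        M = np.zeros((n_cfg, k, k))
        if self.trans_idx.size:
            i = self.trans_idx
            changed = x[i] != x[i + 1]
            j = i[changed]
            # transition attributed to the parent configuration before it
            flat = (codes[j] * k + x[j]) * k + x[j + 1]
            counts = np.bincount(flat, minlength=n_cfg * k * k)
            M = counts.reshape(n_cfg, k, k).astype(float)
        return SufficientStats(variable, parent_set, T, M)


def sufficient_statistics(
    trajectories: list[Trajectory],
    variable: str,
    parent_set=(),
    n_states: dict[str, int] | None = None,
) -> SufficientStats:
    """Dwell times and transition counts for one family, accumulated
    over all trajectories and stratified by the parent configuration in
    force at each instant."""
    if not trajectories:
        k = 2 if n_states is None else n_states[variable]
        cards = [] if n_states is None else [n_states[p] for p in parent_set]
        n_cfg = int(np.prod(cards)) if cards else 1
        return SufficientStats(
            variable, tuple(parent_set), np.zeros((n_cfg, k)), np.zeros((n_cfg, k, k))
        )
    return TrajectoryData(trajectories, n_states).family_stats(variable, parent_set)


def family_log_score(stats: SufficientStats, config: LearnConfig | None = None) -> float:
    """Log marginal likelihood of one family under Gamma/Dirichlet priors.

    Exactly zero for all-zero statistics (the marginal likelihood of no
    data is 1); strictly decreasing in any dwell time at fixed counts.
    """
    config = config or LearnConfig()
    a, tau = config.alpha, config.tau
    T, M = stats.T, stats.M
    Mtot = stats.M_total
    k = stats.n_states
    ln_q = np.sum(
        gammaln(a + Mtot + 1.0)
        - gammaln(a + 1.0)
        + (a + 1.0) * np.log(tau)
        - (a + Mtot + 1.0) * np.log(tau + T)
    )
    off = ~np.eye(k, dtype=bool)
    ln_theta = np.sum(
        gammaln(a * (k - 1)) - gammaln(a * (k - 1) + Mtot)
    ) + np.sum(gammaln(a + M[:, off]) - gammaln(a))
    return float(ln_q + ln_theta)


def network_log_score(
    parent_sets: dict[str, tuple[str, ...]],
    data: TrajectoryData | list[Trajectory],
    config: LearnConfig | None = None,
) -> float:
    """Total structure score: the sum of family scores (decomposability)."""
    config = config or LearnConfig()
    if not isinstance(data, TrajectoryData):
        data = TrajectoryData(data)
    total = 0.0
    for v in data.variables:
        ps = tuple(parent_sets.get(v, ()))
        if len(ps) > config.max_parents:
            raise ConfigError(f"parent set of {v} exceeds max_parents={config.max_parents}")
        total += family_log_score(data.family_stats(v, ps), config)
    return total


@dataclass
class SearchResult:
    parent_sets: dict[str, tuple[str, ...]]
    family_scores: dict[str, float]

    @property
    def score(self) -> float:
        return float(sum(self.family_scores.values()))

    def arcs(self) -> set[tuple[str, str]]:
        return {(p, v) for v, ps in self.parent_sets.items() for p in ps}


def _hill_climb_family(data: TrajectoryData, var: str, config: LearnConfig, cache: dict):
    """Best-improvement hill climb over add/remove-single-parent moves.

    Ties are broken deterministically: smallest candidate-variable index
    first, additions before removals.  Only strictly improving moves are
    taken, so the climb terminates at a local optimum.
    """

    def score_of(ps: tuple) -> float:
        key = (var, ps)
        if key not in cache:
            cache[key] = family_log_score(data.family_stats(var, ps), config)
        return cache[key]

    others = [v for v in data.variables if v != var]
    current: tuple[str, ...] = ()
    current_score = score_of(current)
    while True:
        best_move, best_score = None, current_score
        for cand in others:  # additions, in variable order
            if cand in current or len(current) >= config.max_parents:
                continue
            ps = tuple(sorted(current + (cand,)))
            s = score_of(ps)
            if s > best_score:
                best_move, best_score = ps, s
        for cand in others:  # removals, after additions at equal gain
            if cand not in current:
                continue
            ps = tuple(p for p in current if p != cand)
            s = score_of(ps)
            if s > best_score:
                best_move, best_score = ps, s
        if best_move is None:
            return current, current_score
        current, current_score = best_move, best_score


def greedy_structure_search(
    data: list[Trajectory] | TrajectoryData,
    config: LearnConfig | None = None,
    n_states: dict[str, int] | None = None,
) -> SearchResult:
    """Per-variable greedy hill climbing from the empty parent set."""
    config = config or LearnConfig()
    if not isinstance(data, TrajectoryData):
        data = TrajectoryData(data, n_states)
    cache: dict = {}
    parent_sets, scores = {}, {}
    for v in data.variables:
        ps, s = _hill_climb_family(data, v, config, cache)
        parent_sets[v], scores[v] = ps, s
    return SearchResult(parent_sets, scores)


def exhaustive_structure_search(
    data: list[Trajectory] | TrajectoryData,
    config: LearnConfig | None = None,
    n_states: dict[str, int] | None = None,
    max_space: int = 100_000,
) -> SearchResult:
    """Exact optimizer by family-wise enumeration of all parent sets.

    Intended as an oracle on small problems; refuses when the search
    space (families x candidate parent sets) exceeds ``max_space``.
    """
    config = config or LearnConfig()
    if not isinstance(data, TrajectoryData):
        data = TrajectoryData(data, n_states)
    n = len(data.variables)
    per_family = sum(math.comb(n - 1, d) for d in range(min(config.max_parents, n - 1) + 1))
    if n * per_family > max_space:
        raise ConfigError(
            f"exhaustive search space too large: {n} families x {per_family} "
            f"candidate sets > {max_space}"
        )
    parent_sets, scores = {}, {}
    for v in data.variables:
        others = [u for u in data.variables if u != v]
        best_ps, best_s = (), -np.inf
        for d in range(min(config.max_parents, len(others)) + 1):
            for combo in itertools.combinations(others, d):
                s = family_log_score(data.family_stats(v, combo), config)
                if s > best_s:
                    best_ps, best_s = tuple(combo), s
        parent_sets[v], scores[v] = best_ps, best_s
    return SearchResult(parent_sets, scores)


def estimate_parameters(
    stats: SufficientStats, config: LearnConfig | None = None
) -> np.ndarray:
    """Posterior-mean CIMs for one family.

    q_hat_{x|u} = (alpha + M[x;u] + 1) / (tau + T[x;u]);
    theta_hat_{x->x'|u} = (alpha + M[x,x';u]) / (alpha (k-1) + M[x;u]).
    Returns an (n_configs, k, k) intensity array with rows summing to 0.
    """
    config = config or LearnConfig()
    a, tau = config.alpha, config.tau
    k = stats.n_states
    q = (a + stats.M_total + 1.0) / (tau + stats.T)  # (n_cfg, k)
    theta = (a + stats.M) / (a * (k - 1) + stats.M_total)[:, :, None]
    cims = q[:, :, None] * theta
    for u in range(cims.shape[0]):
        np.fill_diagonal(cims[u], 0.0)
        np.fill_diagonal(cims[u], -cims[u].sum(axis=1))
    return cims
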