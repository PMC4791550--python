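"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the marginal
likelihood is estimated by Monte-Carlo integration over the priors, and
Benjamini-Hochberg is re-derived from its textbook definition.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import betaln

from ctbnet.model import SufficientStats


def mc_family_log_score(
    stats: SufficientStats,
    alpha: float,
    tau: float,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
    include_theta: bool = True,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the family log marginal likelihood by
    prior sampling.

    Draws intensities q_{x|u} ~ Gamma(shape=alpha+1, rate=tau) and
    transition rows theta_{x|u} ~ Dirichlet(alpha, ..., alpha) from the
    prior, averages the likelihood, and returns (log estimate, standard
    error on the log scale).

    Reliable for 2-state variables (theta is then degenerate).  For
    k > 2 at small alpha the Dirichlet prior concentrates on the simplex
    corners and prior sampling degenerates; use
    :func:`quad_theta_log_ml` for the transition factor instead.
    """
    rng = rng or np.random.default_rng(0)
    k = stats.n_states
    n_cfg = stats.T.shape[0]
    loglik = np.zeros(n_draws)
    off = ~np.eye(k, dtype=bool)
    for u in range(n_cfg):
        for x in range(k):
            T, Mx = stats.T[u, x], stats.M_total[u, x]
            q = rng.gamma(shape=alpha + 1.0, scale=1.0 / tau, size=n_draws)
            loglik += Mx * np.log(q) - q * T
            m_row = stats.M[u, x][off[x]]
            if include_theta and m_row.sum() > 0 and k > 2:
                theta = rng.dirichlet([alpha] * (k - 1), size=n_draws)
                pos = m_row > 0
                with np.errstate(divide="ignore"):
                    # theta may underflow to 0 at tiny alpha: such draws have
                    # zero likelihood (-inf log), which is correct to average in
                    loglik += (m_row[None, pos] * np.log(theta[:, pos])).sum(axis=1)
    shift = loglik.max()
    w = np.exp(loglik - shift)
    mean_w = w.mean()
    se_w = w.std(ddof=1) / np.sqrt(n_draws)
    return float(shift + np.log(mean_w)), float(se_w / mean_w)


def quad_theta_log_ml(stats: SufficientStats, alpha: float) -> float:
    """Transition-probability factor of the marginal likelihood for a
    3-state family, by direct numerical integration over each Dirichlet
    row (a 1-D integral on the 2-simplex)."""
    assert stats.n_states == 3
    total = 0.0
    off = ~np.eye(3, dtype=bool)
    for u in range(stats.T.shape[0]):
        for x in range(3):
            m1, m2 = stats.M[u, x][off[x]]
            if m1 + m2 == 0:
                continue
            val, err = quad(
                lambda th: th ** (m1 + alpha - 1) * (1 - th) ** (m2 + alpha - 1),
                0.0,
                1.0,
                limit=200,
            )
            total += np.log(val) - betaln(alpha, alpha)
    return float(total)


def brute_force_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, from the definition:
    q_(i) = min_{j >= i} min(1, p_(j) * n / j) in sorted order."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def random_stats(
    rng: np.random.Generator,
    k: int = 2,
    n_cfg: int = 1,
    max_count: int = 4,
    max_dwell: float = 8.0,
    variable: str = "X",
) -> SufficientStats:
    """A random small sufficient-statistics instance."""
    T = rng.uniform(0.0, max_dwell, size=(n_cfg, k))
    M = rng.integers(0, max_count + 1, size=(n_cfg, k, k)).astype(float)
    for u in range(n_cfg):
        np.fill_diagonal(M[u], 0.0)
    return SufficientStats(variable, (), T, M)
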