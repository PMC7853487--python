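"""Evolutionary dynamics in the low-mutation limit.

A well-mixed population of ``N`` players evolves by a frequency-dependent
Moran (pairwise-imitation) process with Fermi update: a player switches to a
co-player's strategy with probability ``1 / (1 + exp[sigma * (own - other)])``
where ``sigma`` is the selection strength.  Mutations are rare, so the
population is homogeneous except while a single mutant lineage sweeps or
dies out; the fixation probability of one mutant has the standard closed
form, and strategy abundances follow from the stationary distribution of the
embedded jump chain over homogeneous populations.

Long-term payoffs between strategies come from the exact joint-history
chains of :mod:`capri.dynamics`; evolutionary experiments use the donation
parameterization of the public-goods game (benefit ``b``, unit cost).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .dynamics import StrategyProfile, analyze
from .game import GameParams, newest_joint, donation_payoffs
from .strategies import DeterministicStrategy, random_strategy

__all__ = [
    "PayoffTable",
    "group_payoffs",
    "fixation_probability",
    "fixation_probability_closed_form",
    "abundance",
    "sample_mutant_fixation",
    "sweep",
]


def joint_action_distribution(members, eps: float) -> np.ndarray:
    """Stationary distribution of the newest joint action (2**n outcomes,
    player i's action in bit i) for a strategy profile at error rate eps."""
    profile = StrategyProfile(members)
    n, m = profile.n, profile.m_star
    # payoffs are irrelevant to the chain; any valid params do
    params = GameParams(n=n, rho=(1 + n) / 2)
    res = analyze(profile, params, eps=eps)
    codes = np.arange(profile.n_states, dtype=np.uint64)
    acts = newest_joint(codes, n, m)  # (n, S)
    joint = np.zeros(profile.n_states, dtype=np.int64)
    for i in range(n):
        joint |= acts[i] << i
    out = np.zeros(1 << n)
    np.add.at(out, joint, res.distribution)
    return out


def _donation_payoff_vectors(n: int, b: float) -> np.ndarray:
    """Donation payoffs of every joint action, shape (2**n, n)."""
    out = np.empty((1 << n, n))
    for a in range(1 << n):
        acts = [(a >> i) & 1 for i in range(n)]
        out[a] = donation_payoffs(acts, b)
    return out


class PayoffTable:
    """Long-term payoffs among a strategy set at fixed error rate.

    For ``n = 2`` exposes ``s(x, y)`` — x's payoff against y; for ``n = 3``,
    ``s(x, y, z)`` — x's payoff against co-players y and z (symmetric in the
    last two).  The newest-joint-action distribution of each profile is
    cached, so payoffs for a new benefit ``b`` cost only a dot product.
    """

    def __init__(self, strategies, n: int, eps: float, b: float):
        self.strategies = list(strategies)
        self.n = n
        self.eps = eps
        self._dists: dict[tuple[int, ...], np.ndarray] = {}
        self._payoffs = _donation_payoff_vectors(n, b)
        self.b = b

    def set_benefit(self, b: float) -> None:
        """Re-price all cached profiles at a new donation benefit."""
        self._payoffs = _donation_payoff_vectors(self.n, b)
        self.b = b

    def _dist(self, idxs: tuple[int, ...]) -> np.ndarray:
        """Joint-action distribution for players (idxs[0], idxs[1], ...)."""
        # canonicalize: co-players are exchangeable in payoff terms only if
        # symmetric strategies; we cache by the full ordered profile of the
        # sorted multiset and read the needed player's marginal via mapping
        if idxs not in self._dists:
            members = [self.strategies[i] for i in idxs]
            self._dists[idxs] = joint_action_distribution(members, self.eps)
        return self._dists[idxs]

    def payoff(self, idxs: tuple[int, ...], player: int = 0) -> float:
        """Long-term payoff of ``player`` in the profile ``idxs``."""
        dist = self._dist(tuple(idxs))
        return float(dist @ self._payoffs[:, player])

    def s(self, x: int, *co: int) -> float:
        """x's long-term payoff against co-players ``co`` (strategy indices)."""
        if len(co) != self.n - 1:
            raise ValueError(f"need {self.n - 1} co-player indices")
        co = tuple(sorted(co))
        return self.payoff((x,) + co, player=0)

    def precompute(self) -> None:
        """Evaluate every profile multiset (all chains) up front."""
        K = len(self.strategies)
        for x in range(K):
            for co in itertools.combinations_with_replacement(range(K), self.n - 1):
                self._dist((x,) + co)


def group_payoffs(
    j: int, N: int, x: int, y: int, table: PayoffTable
) -> tuple[float, float]:
    """Average payoffs (s_x, s_y) when j of N players are mutants x.

    Co-players of a sampled individual are drawn without replacement from
    the other ``N - 1`` members, giving the hypergeometric averages: for a
    pairwise game ``s_x = [(j-1) s_xx + (N-j) s_xy] / (N-1)`` and analogously
    for ``s_y``; for the three-player game the weights are the binomial
    counts of mutant/resident co-player pairs.
    """
    if not 1 <= j <= N - 1:
        raise ValueError("mutant count j must lie in [1, N-1]")
    if table.n == 2:
        s_x = ((j - 1) * table.s(x, x) + (N - j) * table.s(x, y)) / (N - 1)
        s_y = ((N - j - 1) * table.s(y, y) + j * table.s(y, x)) / (N - 1)
        return s_x, s_y
    if table.n == 3:
        if N < 3:
            raise ValueError("three-player sampling requires N >= 3")
        denom = (N - 1) * (N - 2) / 2  # unordered co-player pairs
        s_x = (
            _c2(j - 1) * table.s(x, x, x)
            + (j - 1) * (N - j) * table.s(x, x, y)
            + _c2(N - j) * table.s(x, y, y)
        ) / denom
        s_y = (
            _c2(j) * table.s(y, x, x)
            + j * (N - j - 1) * table.s(y, x, y)
            + _c2(N - j - 1) * table.s(y, y, y)
        ) / denom
        return s_x, s_y
    raise NotImplementedError("group payoffs implemented for n = 2 and 3")


def _c2(k: int) -> float:
    return k * (k - 1) / 2


def fixation_probability(
    x: int,
    y: int,
    table: PayoffTable,
    N: int,
    sigma: float,
) -> float:
    """Fixation probability of a single mutant x in a resident-y population.

    The birth-death structure of the imitation process gives
    ``phi = 1 / sum_{i=0}^{N-1} prod_{j=1}^{i} Gamma_j`` with
    ``Gamma_j = exp[sigma (s_y(j) - s_x(j))]``; accumulated in the log
    domain to stay finite at large ``sigma * N``.
    """
    if N < 2:
        raise ValueError("population size must be at least 2")
    if sigma < 0:
        raise ValueError("selection strength must be non-negative")
    log_gamma = np.empty(N - 1)
    for j in range(1, N):
        s_x, s_y = group_payoffs(j, N, x, y, table)
        log_gamma[j - 1] = sigma * (s_y - s_x)
    log_terms = np.concatenate([[0.0], np.cumsum(log_gamma)])
    return float(np.exp(-logsumexp(log_terms)))


def fixation_probability_closed_form(
    s_xx: float,
    s_xy: float,
    s_yx: float,
    s_yy: float,
    N: int,
    sigma: float,
) -> float:
    """Pairwise (n = 2) fixation probability as a single explicit sum.

    Summing the exponents of the Gamma product in closed form gives
    ``phi^{-1} = sum_i exp( sigma i [ (2N-3-i) s_yy + (i+1) s_yx
    - (2N-1-i) s_xy - (i-1) s_xx ] / [2(N-1)] )``; must agree with the
    product form to floating-point accuracy.
    """
    i = np.arange(N, dtype=float)
    expo = (
        sigma
        * i
        * ((2 * N - 3 - i) * s_yy + (i + 1) * s_yx - (2 * N - 1 - i) * s_xy - (i - 1) * s_xx)
        / (2 * (N - 1))
    )
    return float(np.exp(-logsumexp(expo)))


def fixation_matrix(table: PayoffTable, N: int, sigma: float) -> np.ndarray:
    """phi[x, y]: fixation probability of mutant x in resident y."""
    K = len(table.strategies)
    phi = np.zeros((K, K))
    for y in range(K):
        for x in range(K):
            if x == y:
                continue
            phi[x, y] = fixation_probability(x, y, table, N, sigma)
    return phi


@dataclass(frozen=True)
class AbundanceResult:
    """Low-mutation stationary abundance per strategy."""

    strategies: list
    abundance: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.abundance, index=[s.name for s in self.strategies]
        )


def abundance(
    strategies,
    N: int,
    sigma: float,
    b: float,
    eps: float = 1e-4,
    table: PayoffTable | None = None,
) -> AbundanceResult:
    """Stationary abundance of each strategy in the low-mutation limit.

    The population jumps between homogeneous states: from resident y, a
    uniformly chosen mutant x arrives and fixates with probability phi_xy,
    giving the embedded chain ``T[y -> x] = phi_xy / (K - 1)``; the returned
    vector is its stationary distribution.
    """
    strategies = list(strategies)
    K = len(strategies)
    if K < 2:
        raise ValueError("abundance needs at least two strategies")
    n = strategies[0].n
    if table is None:
        table = PayoffTable(strategies, n=n, eps=eps, b=b)
    elif table.b != b:
        table.set_benefit(b)
    phi = fixation_matrix(table, N, sigma)
    T = phi.T / (K - 1)  # T[y, x] = phi_xy / (K-1)
    T[np.arange(K), np.arange(K)] = 1.0 - T.sum(axis=1)
    A = T.T - np.eye(K)
    A[-1, :] = 1.0
    rhs = np.zeros(K)
    rhs[-1] = 1.0
    v = np.linalg.solve(A, rhs)
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    return AbundanceResult(strategies=strategies, abundance=v)


def sample_mutant_fixation(
    resident: DeterministicStrategy,
    n_samples: int,
    seed: int | np.random.Generator,
    N: int,
    sigma: float,
    b: float,
    eps: float = 1e-4,
    mutant_memory: int | None = None,
    symmetric_mutants: bool = False,
) -> np.ndarray:
    """Fixation probabilities of random deterministic mutants against a
    resident strategy.

    Mutants are uniformly random lookup tables with the resident's memory
    (unconstrained by default; ``symmetric_mutants`` restricts sampling to
    co-player-symmetric tables).  Each probability is exact: the four (n=2)
    or six (n=3) long-term payoffs come from the joint-history chains, then
    the closed-form fixation expression is evaluated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = resident.n
    m = mutant_memory if mutant_memory is not None else resident.m
    resident_dist = joint_action_distribution([resident] * n, eps)
    out = np.empty(n_samples)
    for k in range(n_samples):
        mutant = random_strategy(n, m, rng)
        if symmetric_mutants:
            mutant = _symmetrize(mutant)
        table = PayoffTable([mutant, resident], n=n, eps=eps, b=b)
        table._dists[(1,) * n] = resident_dist  # resident-vs-resident reused
        out[k] = fixation_probability(0, 1, table, N, sigma)
    return out


def _symmetrize(s: DeterministicStrategy) -> DeterministicStrategy:
    """Force co-player symmetry by re-reading each entry at the
    lexicographically smallest co-player ordering."""
    from itertools import permutations

    from .game import player_fields

    codes = np.arange(1 << (s.n * s.m), dtype=np.uint64)
    fields = player_fields(codes, s.n, s.m)
    canonical = None
    for perm in permutations(range(1, s.n)):
        candidate = fields[0].copy()
        for new_i, old_i in zip(range(1, s.n), perm):
            candidate |= fields[old_i] << np.uint64(new_i * s.m)
        canonical = candidate if canonical is None else np.minimum(canonical, candidate)
    table = s.table[canonical.astype(np.int64)]
    return DeterministicStrategy(s.n, s.m, table=table, name=s.name + "-sym")


def sweep(
    strategies,
    b_values,
    N_values,
    sigma: float = 1.0,
    eps: float = 1e-4,
) -> pd.DataFrame:
    """Abundance of every strategy across a (benefit, population-size) grid.

    Joint-action distributions are computed once per strategy profile and
    re-priced per benefit, so the grid costs one chain solve per profile
    plus cheap algebra per cell.  Returns a long-format frame with columns
    ``strategy, b, N, abundance``.
    """
    strategies = list(strategies)
    n = strategies[0].n
    rows = []
    table = PayoffTable(strategies, n=n, eps=eps, b=float(b_values[0]))
    table.precompute()
    for b in b_values:
        table.set_benefit(float(b))
        for N in N_values:
            res = abundance(strategies, N=N, sigma=sigma, b=float(b), table=table)
            for s, a in zip(strategies, res.abundance):
                rows.append(
                    {"strategy": s.name, "b": float(b), "N": int(N), "abundance": float(a)}
                )
    return pd.DataFrame(rows)
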