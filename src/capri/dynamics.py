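"""Exact stationary analysis of the joint-history Markov chain.

For a profile of ``n`` strategies with common (lifted) memory ``m*`` and
implementation-error rate ``eps > 0``, the joint history of the last ``m*``
rounds is a finite Markov chain over ``2**(n*m*)`` states: from history ``h``
each player's intended action (its strategy's prescription, or a Bernoulli
draw for stochastic members) is flipped independently with probability
``eps``, and the realized joint action is appended to the window.  For
``eps > 0`` the chain is irreducible and aperiodic, so it has a unique
stationary distribution from which long-term payoffs and the probability of
a fully cooperative round follow directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .game import GameParams, newest_joint, perspective_code, shift_codes
from .strategies import DeterministicStrategy, MemoryOneStochastic

__all__ = [
    "StrategyProfile",
    "StationaryResult",
    "transition_matrix",
    "stationary",
    "stationary_power",
    "stationary_iad",
    "long_term_payoffs",
    "full_coop_probability",
    "analyze",
]

#: Residual tolerance for stationary solves.
_TOL = 1e-10
_POWER_ITER_CAP = 1_000_000


class StrategyProfile:
    """An ordered assignment of one strategy to each of the ``n`` players.

    Members may be :class:`DeterministicStrategy` (any memory) or
    :class:`MemoryOneStochastic`.  All members are lifted to the common
    memory ``m* = max member memory``: a shorter-memory member reads only the
    newest columns of the shared window.  Strategy tables are stored from the
    focal perspective, so member ``i`` evaluates the window re-encoded with
    row ``i`` first.
    """

    def __init__(self, members: Sequence[DeterministicStrategy | MemoryOneStochastic]):
        self.n = len(members)
        if self.n < 2:
            raise ValueError("a profile needs at least two players")
        for s in members:
            if s.n != self.n:
                raise ValueError(
                    f"member built for {s.n} players used in an {self.n}-player profile"
                )
        self.members = list(members)
        mems = [s.m if isinstance(s, DeterministicStrategy) else 1 for s in members]
        self.m_star = max(mems)
        self.n_states = 1 << (self.n * self.m_star)

    @classmethod
    def homogeneous(cls, s, n: int | None = None) -> "StrategyProfile":
        n = n if n is not None else s.n
        return cls([s] * n)

    def coop_prob_arrays(self) -> np.ndarray:
        """Per-player cooperation probability at every joint-history state.

        Returns an array of shape ``(n, 2**(n*m*))``; deterministic members
        contribute 0/1 entries.
        """
        n, m = self.n, self.m_star
        codes = np.arange(self.n_states, dtype=np.uint64)
        out = np.empty((n, self.n_states), dtype=float)
        for i, s in enumerate(self.members):
            view = perspective_code(codes, i, n, m)
            if isinstance(s, MemoryOneStochastic):
                out[i] = s.coop_probs(view, m)
            else:
                lifted = s if s.m == m else s.lift(m)
                out[i] = 1.0 - lifted.actions(view.astype(np.int64)).astype(float)
        return out

    def prescribed_actions(self) -> np.ndarray:
        """Deterministic prescriptions (0/1) per player per state.

        Only valid when every member is deterministic.
        """
        probs = self.coop_prob_arrays()
        if np.any((probs != 0.0) & (probs != 1.0)):
            raise ValueError("profile contains stochastic members")
        return (probs < 0.5).astype(np.uint8)

    @property
    def deterministic(self) -> bool:
        return all(isinstance(s, DeterministicStrategy) for s in self.members)

    def flow_successors(self) -> np.ndarray:
        """Error-free successor of every state (all players follow their
        prescriptions); the functional graph of the eps = 0 dynamics."""
        pres = self.prescribed_actions()
        n, m = self.n, self.m_star
        joint = np.zeros(self.n_states, dtype=np.int64)
        for i in range(n):
            joint |= pres[i].astype(np.int64) << i
        codes = np.arange(self.n_states, dtype=np.uint64)
        succ = np.zeros(self.n_states, dtype=np.int64)
        for a in range(1 << n):
            sel = joint == a
            succ[sel] = shift_codes(codes[sel], a, n, m).astype(np.int64)
        return succ

    def flow_partition(self) -> np.ndarray:
        """Group label per state: which terminal cycle of the error-free flow
        the state drains into.  Used to precondition the stationary solve of
        metastable chains."""
        succ = self.flow_successors()
        t = succ.copy()
        steps = max(1, int(np.ceil(np.log2(self.n_states))) + 1)
        for _ in range(steps):
            t = t[t]
        _, group = np.unique(t, return_inverse=True)
        return group.astype(np.int64)


@dataclass(frozen=True)
class StationaryResult:
    """Stationary distribution with derived per-player statistics."""

    distribution: np.ndarray
    payoffs: np.ndarray
    full_coop_prob: float
    coop_rates: np.ndarray
    params: GameParams


def transition_matrix(
    profile: StrategyProfile, eps: float, sparse: bool | None = None
) -> sp.csr_matrix | np.ndarray:
    """Row-stochastic transition matrix of the joint-history chain.

    Each row has ``2**n`` nonzero entries: one per realized joint action,
    with probability ``prod_i [eps if player i's realized action differs from
    its intent else 1-eps]`` (intent marginalized for stochastic members).
    """
    if not 0.0 <= eps < 0.5:
        raise ValueError(f"eps must lie in [0, 1/2), got {eps}")
    n, m = profile.n, profile.m_star
    n_states = profile.n_states
    if sparse is None:
        sparse = n_states > 256
    coop = profile.coop_prob_arrays()  # (n, S) probability of intending c
    # probability that player i *realizes* d at each state
    q_defect = coop * eps + (1.0 - coop) * (1.0 - eps)
    codes = np.arange(n_states, dtype=np.uint64)
    cols = np.empty((1 << n, n_states), dtype=np.int64)
    data = np.empty((1 << n, n_states), dtype=float)
    for joint in range(1 << n):
        p = np.ones(n_states, dtype=float)
        for i in range(n):
            if (joint >> i) & 1:
                p *= q_defect[i]
            else:
                p *= 1.0 - q_defect[i]
        cols[joint] = shift_codes(codes, joint, n, m).astype(np.int64)
        data[joint] = p
    rows = np.broadcast_to(codes.astype(np.int64), (1 << n, n_states))
    if sparse:
        M = sp.coo_matrix(
            (data.ravel(), (rows.ravel(), cols.ravel())), shape=(n_states, n_states)
        ).tocsr()
        return M
    M = np.zeros((n_states, n_states), dtype=float)
    np.add.at(M, (rows.ravel(), cols.ravel()), data.ravel())
    return M


def stationary(M) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix via a direct linear solve.

    Solves ``v (M - I) = 0`` with the normalization ``sum(v) = 1`` by
    replacing one equation; requires an irreducible chain (``eps > 0``).
    """
    n_states = M.shape[0]
    if sp.issparse(M) and n_states <= 2048:
        M = M.toarray()
    if sp.issparse(M):
        A = (M.T - sp.identity(n_states, format="csr")).tolil()
        A[-1, :] = 1.0
        rhs = np.zeros(n_states)
        rhs[-1] = 1.0
        v = spla.spsolve(A.tocsc(), rhs)
    else:
        A = M.T - np.eye(n_states)
        A[-1, :] = 1.0
        rhs = np.zeros(n_states)
        rhs[-1] = 1.0
        v = np.linalg.solve(A, rhs)
    v = np.clip(v, 0.0, None)
    total = v.sum()
    if not np.isfinite(total) or total <= 0:
        raise ArithmeticError("stationary solve failed to produce a distribution")
    v /= total
    resid = np.abs(v @ M - v).max()
    if resid > 1e-8:
        raise ArithmeticError(f"stationary residual too large: {resid:.2e}")
    return v


def stationary_power(
    M, tol: float = _TOL, max_iter: int = _POWER_ITER_CAP
) -> np.ndarray:
    """Stationary vector by power iteration; independent cross-check of
    :func:`stationary`."""
    n_states = M.shape[0]
    v = np.full(n_states, 1.0 / n_states)
    for it in range(max_iter):
        w = v @ M
        w = np.asarray(w).ravel()
        w /= w.sum()
        if np.abs(w - v).max() < tol:
            return w
        v = w
    raise ArithmeticError(
        f"power iteration did not converge within {max_iter} sweeps"
    )


def stationary_iad(
    M: sp.spmatrix,
    group: np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 2000,
    smooth: int = 5,
) -> np.ndarray:
    """Stationary vector by iterative aggregation/disaggregation.

    Metastable chains (for example a homogeneous friendly-rivalry population,
    which spends long stretches near full cooperation or full defection and
    crosses between them only through rare error bursts) mix far too slowly
    for plain power iteration, and direct factorization of the shift-
    structured transition matrix suffers severe fill-in.  IAD alternates
    power-iteration smoothing with an exact solve of the K x K chain
    aggregated over ``group`` (here: the basins of the error-free dynamics),
    which corrects the slow inter-basin mass balance in one step.  The fixed
    point is the exact stationary distribution; the residual is checked.
    """
    S = M.shape[0]
    group = np.asarray(group, dtype=np.int64)
    K = int(group.max()) + 1
    Mcsr = M.tocsr()
    onehot = sp.coo_matrix(
        (np.ones(S), (np.arange(S), group)), shape=(S, K)
    ).tocsr()
    move_to = Mcsr @ onehot  # (S, K): P(state -> group J)
    v = np.full(S, 1.0 / S)
    for _ in range(max_iter):
        for _ in range(smooth):
            v = v @ Mcsr
        v_group = onehot.T @ v
        if K > 1:
            coupling = (move_to.multiply(v[:, None]).T @ onehot).toarray().T
            coupling /= v_group[:, None]
            A = coupling.T - np.eye(K)
            A[-1, :] = 1.0
            rhs = np.zeros(K)
            rhs[-1] = 1.0
            w = np.linalg.solve(A, rhs)
            w = np.clip(w, 0.0, None)
            w /= w.sum()
            v = v * (w / v_group)[group]
        v /= v.sum()
        resid = np.abs(v @ Mcsr - v).max()
        if resid < tol:
            return v
    raise ArithmeticError(
        f"aggregation/disaggregation did not reach residual {tol:g} "
        f"within {max_iter} cycles (last residual {resid:.2e})"
    )


def _newest_payoffs(params: GameParams, n: int, m: int, n_states: int) -> np.ndarray:
    """Per-player payoff of the newest column of every state, shape (n, S)."""
    codes = np.arange(n_states, dtype=np.uint64)
    acts = newest_joint(codes, n, m)  # (n, S), 1 = defect
    n_c = (acts == 0).sum(axis=0)
    if params.payoff_scheme == "pg":
        return params.rho * n_c / n + acts
    coop_co = n_c - (acts == 0)
    return (params.b / (n - 1)) * coop_co - (acts == 0)


#: Above this state count, dense/direct solves give way to IAD or power
#: iteration (the de Bruijn-like shift structure defeats sparse LU).
_DIRECT_LIMIT = 2048


def analyze(
    profile: StrategyProfile, params: GameParams, eps: float | None = None
) -> StationaryResult:
    """Stationary distribution, long-term payoffs, and full-cooperation
    probability of a strategy profile.

    Small chains are solved directly; large deterministic-profile chains use
    aggregation/disaggregation over the error-free basins; large chains with
    stochastic members (which mix quickly) use power iteration.
    """
    eps = params.epsilon if eps is None else eps
    if eps <= 0:
        raise ValueError("stationary analysis requires eps > 0 (unique distribution)")
    M = transition_matrix(profile, eps)
    if profile.n_states <= _DIRECT_LIMIT:
        v = stationary(M)
    elif profile.deterministic:
        v = stationary_iad(M, profile.flow_partition())
    else:
        v = stationary_power(M, tol=1e-13)
    n, m = profile.n, profile.m_star
    pay = _newest_payoffs(params, n, m, profile.n_states)
    payoffs = pay @ v
    codes = np.arange(profile.n_states, dtype=np.uint64)
    acts = newest_joint(codes, n, m)
    full_coop = float(v[(acts.sum(axis=0) == 0)].sum())
    coop_rates = (1.0 - acts) @ v
    return StationaryResult(
        distribution=v,
        payoffs=payoffs,
        full_coop_prob=full_coop,
        coop_rates=coop_rates,
        params=params,
    )


def long_term_payoffs(
    profile: StrategyProfile, params: GameParams, eps: float | None = None
) -> np.ndarray:
    """Per-player long-term (time-average) payoffs at error rate ``eps``."""
    return analyze(profile, params, eps).payoffs


def full_coop_probability(
    profile: StrategyProfile, params: GameParams, eps: float | None = None
) -> float:
    """Stationary probability that the newest round is fully cooperative."""
    return analyze(profile, params, eps).full_coop_prob
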