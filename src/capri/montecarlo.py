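"""Monte Carlo trajectory simulation of the repeated game with error.

Exact joint-history chains are materialized only up to ``n = 3``; for four
players (CAPRI-4 has a 2**28-entry history space) long-run statistics come
from direct simulation: starting from an all-cooperate prehistory, every
round each player's prescribed action is flipped independently with
probability ``eps``.  The same machinery cross-validates the exact results
at ``n = 2, 3``.  Standard errors use batch means (100 batches).

Also here: deterministic error-schedule replay (forced deviations at zero
error rate, used to trace how the strategy repairs mistakes) and the
random memory-one tournament.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .dynamics import StrategyProfile, analyze
from .game import COOPERATE, GameParams, HistoryProfile, shift
from .strategies import (
    DeterministicStrategy,
    MemoryOneStochastic,
    _capri_label_scalar,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate",
    "error_schedule_replay",
    "trace_to_csv",
    "random_memory_one_tournament",
]

_N_BATCHES = 100


@dataclass(frozen=True)
class SimConfig:
    """Run configuration for :func:`simulate`."""

    members: list
    params: GameParams
    rounds: int = 10_000_000
    burn_in: int = 10_000
    seed: int = 0
    eps: float | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.rounds <= self.burn_in:
            raise ValueError("need rounds > burn_in >= 0")


@dataclass(frozen=True)
class SimResult:
    """Post-burn-in statistics of one simulated trajectory."""

    payoffs: np.ndarray
    coop_rates: np.ndarray
    full_coop_freq: float
    full_coop_se: float
    joint_distribution: np.ndarray
    rounds_counted: int


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _popcount(x: np.uint64) -> int:
    c = 0
    while x:
        x &= x - np.uint64(1)
        c += 1
    return c


@njit(cache=True)
def _capri_action_nb(code: np.uint64, n: int, m: int, focal: int) -> int:
    """CAPRI prescription (0/1) for player ``focal`` at a canonical code."""
    mask = np.uint64((1 << m) - 1)
    one = np.uint64(1)
    union = np.uint64(0)
    inter = mask
    max_full = 0
    min_full = m + 1
    for i in range(n):
        r = (code >> np.uint64(i * m)) & mask
        union |= r
        inter &= r
        pc = _popcount(r)
        if pc > max_full:
            max_full = pc
        if pc < min_full:
            min_full = pc
    n_d = max_full - min_full
    # trailing ones of the union
    z = 0
    u = union
    while u & one:
        u >>= one
        z += 1
    if z < m:
        if n_d >= n:
            return 1
        if z == 0:
            return 0  # C
        since_mask = (one << np.uint64(z)) - one
        own = _popcount((code >> np.uint64(focal * m)) & since_mask)
        co_max = 0
        for i in range(n):
            if i == focal:
                continue
            pc = _popcount((code >> np.uint64(i * m)) & since_mask)
            if pc > co_max:
                co_max = pc
        return 0 if own >= co_max else 1  # A or P
    # no full cooperation remembered: R requires all-defect older columns
    if (inter >> one) == (mask >> one):
        defectors = 0
        for i in range(n):
            defectors += int((code >> np.uint64(i * m)) & one)
        if defectors == 1:
            return 0  # R
    return 1  # I


@njit(cache=True)
def _shift_nb(code: np.uint64, joint: np.uint64, n: int, m: int) -> np.uint64:
    mask = np.uint64((1 << m) - 1)
    out = np.uint64(0)
    for i in range(n):
        field = (code >> np.uint64(i * m)) & mask
        field = ((field << np.uint64(1)) & mask) | ((joint >> np.uint64(i)) & np.uint64(1))
        out |= field << np.uint64(i * m)
    return out


@njit(cache=True)
def _run_capri_homogeneous(n, m, eps, rounds, burn_in, seed):
    np.random.seed(seed)
    code = np.uint64(0)
    joint_counts = np.zeros(1 << n, dtype=np.int64)
    counted = rounds - burn_in
    batch_size = counted // _N_BATCHES
    batch_full = np.zeros(_N_BATCHES, dtype=np.int64)
    for t in range(rounds):
        joint = np.uint64(0)
        for i in range(n):
            a = _capri_action_nb(code, n, m, i)
            if np.random.random() < eps:
                a = 1 - a
            joint |= np.uint64(a) << np.uint64(i)
        if t >= burn_in:
            k = t - burn_in
            joint_counts[joint] += 1
            if joint == np.uint64(0) and k < batch_size * _N_BATCHES:
                batch_full[k // batch_size] += 1
        code = _shift_nb(code, joint, n, m)
    return joint_counts, batch_full, batch_size


@njit(cache=True)
def _run_profile(q, n, m, eps, rounds, burn_in, seed):
    """General profile: q[i, state] = player i's probability of intending c."""
    np.random.seed(seed)
    code = np.uint64(0)
    joint_counts = np.zeros(1 << n, dtype=np.int64)
    counted = rounds - burn_in
    batch_size = counted // _N_BATCHES
    batch_full = np.zeros(_N_BATCHES, dtype=np.int64)
    for t in range(rounds):
        joint = np.uint64(0)
        for i in range(n):
            qi = q[i, code]
            if qi >= 1.0:  # deterministic entries skip the intent draw so
                a = 0      # that table and rule kernels share RNG streams
            elif qi <= 0.0:
                a = 1
            else:
                a = 0 if np.random.random() < qi else 1
            if np.random.random() < eps:
                a = 1 - a
            joint |= np.uint64(a) << np.uint64(i)
        if t >= burn_in:
            k = t - burn_in
            joint_counts[joint] += 1
            if joint == np.uint64(0) and k < batch_size * _N_BATCHES:
                batch_full[k // batch_size] += 1
        code = _shift_nb(code, joint, n, m)
    return joint_counts, batch_full, batch_size


@njit(cache=True)
def _run_capri_vs_memory_one(probs, n, m, eps, rounds, burn_in, seed):
    """Focal CAPRI (player 0, rule-evaluated) against memory-one stochastic
    co-players; probs[j, a, k] = co-player j+1's cooperation probability
    after own action a with k cooperating co-players."""
    np.random.seed(seed)
    code = np.uint64(0)
    one = np.uint64(1)
    joint_counts = np.zeros(1 << n, dtype=np.int64)
    counted = rounds - burn_in
    batch_size = counted // _N_BATCHES
    batch_full = np.zeros(_N_BATCHES, dtype=np.int64)
    for t in range(rounds):
        joint = np.uint64(0)
        a0 = _capri_action_nb(code, n, m, 0)
        if np.random.random() < eps:
            a0 = 1 - a0
        joint |= np.uint64(a0)
        for j in range(1, n):
            own = int((code >> np.uint64(j * m)) & one)
            k = 0
            for i in range(n):
                if i != j and ((code >> np.uint64(i * m)) & one) == np.uint64(0):
                    k += 1
            a = 0 if np.random.random() < probs[j - 1, own, k] else 1
            if np.random.random() < eps:
                a = 1 - a
            joint |= np.uint64(a) << np.uint64(j)
        if t >= burn_in:
            kk = t - burn_in
            joint_counts[joint] += 1
            if joint == np.uint64(0) and kk < batch_size * _N_BATCHES:
                batch_full[kk // batch_size] += 1
        code = _shift_nb(code, joint, n, m)
    return joint_counts, batch_full, batch_size


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _scheme_payoffs_by_joint(params: GameParams, n: int) -> np.ndarray:
    out = np.empty((1 << n, n))
    for a in range(1 << n):
        out[a] = params.round_payoffs([(a >> i) & 1 for i in range(n)])
    return out


def _is_rule_capri(s) -> bool:
    return isinstance(s, DeterministicStrategy) and s.table is None


def simulate(cfg: SimConfig) -> SimResult:
    """Simulate one seeded trajectory and summarize it.

    Dispatch: a homogeneous profile of rule-evaluated CAPRI uses the
    rule kernel (any n, no table); a rule-evaluated CAPRI against
    memory-one stochastic co-players uses a dedicated kernel; any other
    profile must fit in a materialized joint-history space (n*m <= 22).
    """
    members = list(cfg.members)
    n = len(members)
    params = cfg.params
    eps = cfg.eps if cfg.eps is not None else params.epsilon
    seed = int(cfg.seed) % (2**31)
    if all(_is_rule_capri(s) for s in members):
        m = members[0].m
        jc, bf, bs = _run_capri_homogeneous(
            n, m, eps, cfg.rounds, cfg.burn_in, seed
        )
    elif _is_rule_capri(members[0]) and all(
        isinstance(s, MemoryOneStochastic) for s in members[1:]
    ):
        m = members[0].m
        probs = np.stack([s.probs for s in members[1:]])
        jc, bf, bs = _run_capri_vs_memory_one(
            probs, n, m, eps, cfg.rounds, cfg.burn_in, seed
        )
    else:
        profile = StrategyProfile(members)
        m = profile.m_star
        q = profile.coop_prob_arrays()
        jc, bf, bs = _run_profile(q, n, m, eps, cfg.rounds, cfg.burn_in, seed)
    counted = int(jc.sum())
    dist = jc / counted
    pay = _scheme_payoffs_by_joint(params, n)
    payoffs = dist @ pay
    coop_rates = np.array(
        [dist[[(a >> i) & 1 == 0 for a in range(1 << n)]].sum() for i in range(n)]
    )
    batch_means = bf / bs
    full = float(dist[0])
    se = float(batch_means.std(ddof=1) / np.sqrt(len(batch_means)))
    return SimResult(
        payoffs=payoffs,
        coop_rates=coop_rates,
        full_coop_freq=full,
        full_coop_se=se,
        joint_distribution=dist,
        rounds_counted=counted,
    )


# ---------------------------------------------------------------------------
# Deterministic replay of error schedules
# ---------------------------------------------------------------------------

def error_schedule_replay(
    strategy: DeterministicStrategy,
    schedule: dict[tuple[int, int], int] | list,
    horizon: int = 20,
) -> list[dict]:
    """Replay a homogeneous error-free population with forced deviations.

    ``schedule`` maps ``(round, player) -> forced action`` (rounds start at
    1) or is a list of ``(round, player, action)`` triples.  All players
    start from the all-cooperate prehistory and otherwise follow their
    prescriptions exactly.  Returns one record per round with the realized
    joint action, each player's rule label (for CAPRI-style memory
    ``2n - 1``), and whether the round was fully cooperative.
    """
    if not isinstance(schedule, dict):
        schedule = {(t, i): a for (t, i, a) in schedule}
    n, m = strategy.n, strategy.m
    if schedule and max(t for (t, _) in schedule) > horizon:
        raise ValueError("schedule extends beyond the replay horizon")
    h = HistoryProfile(n, m, 0)  # all-cooperate prehistory
    is_capri = m == 2 * n - 1
    trace = []
    for t in range(1, horizon + 1):
        joint = []
        labels = []
        for i in range(n):
            view = HistoryProfile(
                n, m, _perspective_scalar(h.code, i, n, m)
            )
            prescribed = strategy.action(view)
            labels.append(
                _capri_label_scalar(view.code, n, m) if is_capri else "-"
            )
            joint.append(schedule.get((t, i), prescribed))
        trace.append(
            {
                "round": t,
                "joint": joint,
                "labels": labels,
                "full_coop": all(a == COOPERATE for a in joint),
            }
        )
        h = shift(h, joint)
    return trace


def trace_to_csv(trace: list[dict], path) -> None:
    """Write a replay trace as CSV: round, per-player actions, rule labels."""
    import pandas as pd

    n = len(trace[0]["joint"])
    rows = []
    for rec in trace:
        row = {"round": rec["round"], "full_coop": rec["full_coop"]}
        for i in range(n):
            row[f"action_{i}"] = "cd"[rec["joint"][i]]
            row[f"rule_{i}"] = rec["labels"][i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def first_full_coop_round(trace: list[dict]) -> int | None:
    """Index (1-based round) of the first fully cooperative round."""
    for rec in trace:
        if rec["full_coop"]:
            return rec["round"]
    return None


def _perspective_scalar(code: int, player: int, n: int, m: int) -> int:
    mask = (1 << m) - 1
    order = [player] + [j for j in range(n) if j != player]
    out = 0
    for new_i, old_i in enumerate(order):
        out |= ((code >> (old_i * m)) & mask) << (new_i * m)
    return out


# ---------------------------------------------------------------------------
# Random memory-one tournament
# ---------------------------------------------------------------------------

def random_memory_one_tournament(
    strategy: DeterministicStrategy,
    n_samples: int,
    params: GameParams,
    seed: int | np.random.Generator,
    eps: float | None = None,
    mc_rounds: int = 1_000_000,
) -> np.ndarray:
    """Long-term payoffs of a focal strategy against random memory-one
    stochastic co-players (all cooperation probabilities i.i.d. uniform).

    Returns an array of shape ``(n_samples, n)``: column 0 is the focal
    payoff, the rest the co-players'.  Uses the exact chain for ``n <= 3``
    and seeded simulation otherwise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = strategy.n
    eps = eps if eps is not None else params.epsilon
    out = np.empty((n_samples, n))
    exact = strategy.table is not None and n <= 3
    for k in range(n_samples):
        cos = [
            MemoryOneStochastic(n, rng.uniform(size=(2, n))) for _ in range(n - 1)
        ]
        if exact:
            res = analyze(StrategyProfile([strategy] + cos), params, eps=eps)
            out[k] = res.payoffs
        else:
            sub_seed = int(rng.integers(0, 2**31))
            cfg = SimConfig(
                members=[strategy] + cos,
                params=params,
                rounds=mc_rounds,
                burn_in=10_000,
                seed=sub_seed,
                eps=eps,
            )
            out[k] = simulate(cfg).payoffs
    return out
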