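"""Certification of strategies against the three friendly-rivalry criteria.

* **Defensibility** — with no implementation error, no co-player can secure a
  strictly higher long-term payoff from any initial condition.  Because a
  public-goods payoff difference between two players reduces to the
  difference in their defection counts, this is equivalent to the absence of
  a positive-total-weight cycle in the strategy's game graph, whose nodes are
  the focal player's (automaton) states, whose edges are the co-players'
  joint choices, and whose edge weight for co-player j is
  ``[j defects] - [focal defects]``.
* **Efficiency** — a homogeneous population reaches full cooperation with
  probability one as the error rate vanishes.  Diagnosed by the
  full-cooperation probability along a decreasing error grid together with
  the error-resistances between the recurrent classes of the error-free
  dynamics: falling out of full cooperation must cost strictly more
  simultaneous errors than climbing back.
* **Distinguishability** — against unconditional cooperators the strategy
  earns a strictly higher long-term payoff in the vanishing-error limit.

A strategy satisfying the first two is a *friendly rival*; all three make it
*successful*.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .automaton import StrategyAutomaton, minimize, to_automaton
from .dynamics import GameParams, StrategyProfile, analyze
from .game import HistoryProfile, shift
from .strategies import DeterministicStrategy, build_allc

__all__ = [
    "CriteriaReport",
    "DEFAULT_EPS_GRID",
    "check_defensibility",
    "recurrent_classes",
    "min_error_resistance",
    "check_efficiency",
    "check_distinguishability",
    "certify",
    "classify",
]

#: Default error-rate grid for the vanishing-error diagnostics.
DEFAULT_EPS_GRID = (1e-3, 1e-4, 1e-5)

#: Required shrink factor of 1 - P(full cooperation) per error-rate decade.
_EFFICIENCY_SHRINK = 5.0

#: Extrapolated payoff gap (vs AllC) that counts as strictly positive; well
#: above solver tolerance and well below any genuine O(1) exploitation gap.
_DISTINGUISH_THRESHOLD = 1e-3

_INF = float("inf")


@dataclass
class CriteriaReport:
    """Verdicts, witnesses and diagnostics of the three criteria."""

    n: int
    name: str
    defensible: bool
    defensibility_witness: list | None
    efficient: bool
    coop_probs: dict[float, float]
    resistance_coop_to_defect: float
    resistance_defect_to_coop: float
    distinguishing: bool
    payoff_gap: float

    @property
    def friendly_rival(self) -> bool:
        return self.defensible and self.efficient

    @property
    def successful(self) -> bool:
        return self.friendly_rival and self.distinguishing

    @property
    def labels(self) -> set[str]:
        out = set()
        if self.efficient:
            out.add("efficient")
        if self.defensible:
            out.add("defensible")
        return out or {"other"}

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "name": self.name,
            "defensible": self.defensible,
            "defensibility_witness": self.defensibility_witness,
            "efficient": self.efficient,
            "coop_probs": {str(k): v for k, v in self.coop_probs.items()},
            "resistance_coop_to_defect": self.resistance_coop_to_defect,
            "resistance_defect_to_coop": self.resistance_defect_to_coop,
            "distinguishing": self.distinguishing,
            "payoff_gap": self.payoff_gap,
            "labels": sorted(self.labels),
            "friendly_rival": self.friendly_rival,
            "successful": self.successful,
        }


# ---------------------------------------------------------------------------
# Defensibility: positive-cycle detection in the game graph
# ---------------------------------------------------------------------------

def _game_graph_edges(auto: StrategyAutomaton, n: int):
    """Edges (u, v, co_mask, focal_action) of the error-free game graph."""
    n_states = auto.n_states
    states = np.arange(n_states, dtype=np.int64)
    f = auto.output.astype(np.int64)  # focal action per state
    u_list, v_list, mask_list, f_list = [], [], [], []
    for co_mask in range(1 << (n - 1)):
        joint = f | (co_mask << 1)
        v = auto.transition[states, joint]
        u_list.append(states)
        v_list.append(v)
        mask_list.append(np.full(n_states, co_mask, dtype=np.int64))
        f_list.append(f)
    return (
        np.concatenate(u_list),
        np.concatenate(v_list),
        np.concatenate(mask_list),
        np.concatenate(f_list),
    )


def _positive_cycle(u, v, w, n_states) -> list[int] | None:
    """Bellman-Ford longest-path relaxation from a virtual super-source over
    all nodes; returns edge indices of a positive-total-weight cycle, or
    ``None``.  Early exit on the first stationary sweep."""
    dist = np.zeros(n_states)
    pred = np.full(n_states, -1, dtype=np.int64)  # improving edge index
    edge_idx = np.arange(len(u))
    for sweep in range(n_states + 1):
        cand = dist[u] + w
        best = np.full(n_states, -np.inf)
        np.maximum.at(best, v, cand)
        improved = best > dist + 1e-12
        if not improved.any():
            return None
        # record one improving edge per improved node
        winners = (cand >= best[v] - 1e-15) & improved[v]
        pred[v[winners]] = edge_idx[winners]
        dist = np.maximum(dist, best)
    # still improving after n_states sweeps: walk predecessors into a cycle
    node = int(np.flatnonzero(improved)[0])
    for _ in range(n_states):
        node = int(u[pred[node]])
    seen = set()
    while node not in seen:
        seen.add(node)
        node = int(u[pred[node]])
    # node now lies on the cycle; collect its edges (pred points backwards)
    edges = []
    first = node
    while True:
        e = int(pred[node])
        edges.append(e)
        node = int(u[e])
        if node == first:
            break
    edges.reverse()
    return edges


def check_defensibility(
    s: DeterministicStrategy, all_coplayers: bool | None = None
) -> tuple[bool, list | None]:
    """Defensibility verdict with a witness cycle when it fails.

    The game graph is built on the minimized automaton (behaviorally
    equivalent, so the verdict transfers to the full history graph).  For a
    co-player-symmetric strategy, checking co-player 1 suffices; pass
    ``all_coplayers=True`` to check every co-player of an asymmetric table.

    The witness, when present, is a list of steps
    ``{"history": str, "joint": [actions]}`` tracing a cycle along which some
    co-player accumulates a strictly higher payoff than the focal player.
    """
    if s.table is None:
        raise ValueError(
            "defensibility certification requires a materialized table"
        )
    n = s.n
    auto = minimize(to_automaton(s))
    # a representative history per minimized state, for readable witnesses
    rep = np.full(auto.n_states, -1, dtype=np.int64)
    rep[auto.state_of[::-1]] = np.arange(len(auto.state_of))[::-1]
    u, v, co_mask, f = _game_graph_edges(auto, n)
    if all_coplayers is None:
        from .strategies import is_symmetric

        all_coplayers = n > 2 and not is_symmetric(s)
    coplayers = range(1, n) if all_coplayers else (1,)
    for j in coplayers:
        w = (((co_mask >> (j - 1)) & 1) - f).astype(float)
        cycle = _positive_cycle(u, v, w, auto.n_states)
        if cycle is not None:
            witness = []
            for e in cycle:
                h = HistoryProfile(n, s.m, int(rep[u[e]]))
                joint = [int(f[e])] + [
                    (int(co_mask[e]) >> (k - 1)) & 1 for k in range(1, n)
                ]
                witness.append({"history": str(h), "joint": joint})
            return False, witness
    return True, None


def replay_witness_gain(s: DeterministicStrategy, witness: list) -> float:
    """Best total relative payoff (co-player minus focal) accumulated over
    one lap of a witness cycle; positive confirms the defensibility
    violation."""
    best = -_INF
    n = s.n
    for j in range(1, n):
        total = 0.0
        h = HistoryProfile.from_string(witness[0]["history"])
        ok = True
        for step in witness:
            joint = step["joint"]
            if s.action(h) != joint[0]:
                ok = False
                break
            total += joint[j] - joint[0]
            h = shift(h, joint)
        if ok:
            best = max(best, total)
    return best


# ---------------------------------------------------------------------------
# Recurrent classes and error resistance of the error-free dynamics
# ---------------------------------------------------------------------------

def recurrent_classes(s: DeterministicStrategy) -> list[list[int]]:
    """Terminal cycles of the homogeneous error-free dynamics.

    Every player follows the prescription, so the joint history evolves
    deterministically; the recurrent classes are the cycles of this
    functional graph, returned as lists of history codes.
    """
    profile = StrategyProfile.homogeneous(s)
    succ = profile.flow_successors()
    t = succ.copy()
    for _ in range(max(1, int(np.ceil(np.log2(len(succ)))) + 1)):
        t = t[t]
    classes = []
    for rep in np.unique(t):
        cycle = [int(rep)]
        node = int(succ[rep])
        while node != rep:
            cycle.append(node)
            node = int(succ[node])
        classes.append(cycle)
    return classes


def _class_with(classes: list[list[int]], code: int) -> list[int] | None:
    for c in classes:
        if code in c:
            return c
    return None


def min_error_resistance(
    s: DeterministicStrategy,
    from_class: list[int],
    to_class: list[int],
) -> float:
    """Minimum number of mistaken actions needed to drive a homogeneous
    population from one recurrent class into the basin of another.

    Shortest path in the joint-history graph where moving along joint action
    ``a`` from history ``h`` costs the number of players whose action in
    ``a`` deviates from the prescription at ``h``; the path ends as soon as
    the error-free flow drains into ``to_class``.  Returns ``inf`` when
    unreachable.
    """
    profile = StrategyProfile.homogeneous(s)
    n, m = profile.n, profile.m_star
    pres = profile.prescribed_actions()
    joint_pres = np.zeros(profile.n_states, dtype=np.int64)
    for i in range(n):
        joint_pres |= pres[i].astype(np.int64) << i
    group = profile.flow_partition()
    succ = profile.flow_successors()
    t = succ.copy()
    for _ in range(max(1, int(np.ceil(np.log2(len(succ)))) + 1)):
        t = t[t]
    target_group = group[to_class[0]]
    targets = group == target_group

    from .game import shift_codes

    codes = np.arange(profile.n_states, dtype=np.uint64)
    dest = np.empty((1 << n, profile.n_states), dtype=np.int64)
    for a in range(1 << n):
        dest[a] = shift_codes(codes, a, n, m).astype(np.int64)
    popcount = np.bitwise_count(np.arange(1 << n, dtype=np.uint64)).astype(np.int64)

    dist = np.full(profile.n_states, np.inf)
    heap = []
    for h in from_class:
        dist[h] = 0.0
        heapq.heappush(heap, (0.0, h))
    while heap:
        d, h = heapq.heappop(heap)
        if d > dist[h]:
            continue
        if targets[h]:
            return d
        jp = joint_pres[h]
        for a in range(1 << n):
            cost = popcount[a ^ jp]
            nd = d + cost
            hv = dest[a, h]
            if nd < dist[hv]:
                dist[hv] = nd
                heapq.heappush(heap, (nd, hv))
    return _INF


# ---------------------------------------------------------------------------
# Efficiency and distinguishability
# ---------------------------------------------------------------------------

def _full_coop_code(n: int, m: int) -> int:
    return 0  # all-cooperate history: every bit clear


def _full_defect_code(n: int, m: int) -> int:
    return (1 << (n * m)) - 1


def check_efficiency(
    s: DeterministicStrategy,
    eps_grid=DEFAULT_EPS_GRID,
) -> tuple[bool, dict]:
    """Efficiency verdict with diagnostics.

    Requires (a) the full-cooperation probability of a homogeneous population
    to approach 1 along the decreasing error grid — operationalized as the
    residual ``1 - p`` shrinking at least 5x per decade — and (b), whenever
    full defection is also recurrent under error-free play, a strictly higher
    error-resistance out of full cooperation than out of full defection.
    """
    n = s.n
    params = GameParams(n=n, rho=(1 + n) / 2)
    profile = StrategyProfile.homogeneous(s)
    eps_grid = tuple(sorted(eps_grid, reverse=True))
    coop_probs = {}
    for eps in eps_grid:
        coop_probs[eps] = analyze(profile, params, eps=eps).full_coop_prob

    trend_ok = True
    for e_hi, e_lo in zip(eps_grid, eps_grid[1:]):
        decades = np.log10(e_hi / e_lo)
        required = _EFFICIENCY_SHRINK ** decades
        lo_resid = 1.0 - coop_probs[e_lo]
        hi_resid = 1.0 - coop_probs[e_hi]
        if lo_resid > 0 and hi_resid / lo_resid < required:
            trend_ok = False

    classes = recurrent_classes(s)
    m = s.m
    coop_class = _class_with(classes, _full_coop_code(n, m))
    defect_class = _class_with(classes, _full_defect_code(n, m))
    r_cd = r_dc = None
    resist_ok = coop_class is not None
    if coop_class is not None and defect_class is not None:
        r_cd = min_error_resistance(s, coop_class, defect_class)
        r_dc = min_error_resistance(s, defect_class, coop_class)
        resist_ok = r_cd > r_dc
    diag = {
        "coop_probs": coop_probs,
        "trend_ok": trend_ok,
        "resistance_coop_to_defect": r_cd if r_cd is not None else _INF,
        "resistance_defect_to_coop": r_dc if r_dc is not None else 0.0,
        "resist_ok": resist_ok,
        "n_recurrent_classes": len(classes),
    }
    return bool(trend_ok and resist_ok), diag


def check_distinguishability(
    s: DeterministicStrategy,
    eps_grid=DEFAULT_EPS_GRID,
) -> tuple[bool, float]:
    """Whether the strategy exploits unconditional cooperators.

    Computes the focal-minus-AllC long-term payoff gap in the profile
    ``(s, AllC, ..., AllC)`` along the error grid and extrapolates linearly
    to zero error; the verdict requires a strictly positive limit (threshold
    well above solver tolerance).
    """
    n = s.n
    params = GameParams(n=n, rho=(1 + n) / 2)
    allc = build_allc(n)
    profile = StrategyProfile([s] + [allc] * (n - 1))
    eps_grid = tuple(sorted(eps_grid, reverse=True))
    gaps = []
    for eps in eps_grid:
        r = analyze(profile, params, eps=eps)
        gaps.append(r.payoffs[0] - r.payoffs[1:].max())
    # linear extrapolation to eps -> 0 from the two smallest error rates
    e1, e2 = eps_grid[-2], eps_grid[-1]
    g1, g2 = gaps[-2], gaps[-1]
    gap0 = g2 - e2 * (g1 - g2) / (e1 - e2)
    return bool(gap0 > _DISTINGUISH_THRESHOLD), float(gap0)


# ---------------------------------------------------------------------------
# Full certification
# ---------------------------------------------------------------------------

def certify(
    s: DeterministicStrategy,
    eps_grid=DEFAULT_EPS_GRID,
) -> CriteriaReport:
    """Run all three criteria and assemble a :class:`CriteriaReport`."""
    defensible, witness = check_defensibility(s)
    efficient, diag = check_efficiency(s, eps_grid)
    distinguishing, gap = check_distinguishability(s, eps_grid)
    return CriteriaReport(
        n=s.n,
        name=s.name,
        defensible=defensible,
        defensibility_witness=witness,
        efficient=efficient,
        coop_probs=diag["coop_probs"],
        resistance_coop_to_defect=diag["resistance_coop_to_defect"],
        resistance_defect_to_coop=diag["resistance_defect_to_coop"],
        distinguishing=distinguishing,
        payoff_gap=gap,
    )


def classify(
    strategies,
    eps_grid=DEFAULT_EPS_GRID,
) -> dict[str, set[str]]:
    """Efficiency/defensibility labels per strategy (friendly rivals carry
    both); strategies failing both are labeled ``other``."""
    out = {}
    for s in strategies:
        defensible, _ = check_defensibility(s)
        efficient, _ = check_efficiency(s, eps_grid)
        labels = set()
        if efficient:
            labels.add("efficient")
        if defensible:
            labels.add("defensible")
        out[s.name] = labels or {"other"}
    return out
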