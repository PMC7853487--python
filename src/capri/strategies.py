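"""Deterministic strategies for the repeated n-person public-goods game.

The centrepiece is CAPRI-n, a memory ``m = 2n-1`` strategy assembled from
five rules — Cooperate, Accept, Punish, Recover, and In-all-other-cases
defect — designed to be simultaneously *efficient* (a homogeneous population
reaches full cooperation as the error rate vanishes) and *defensible* (no
co-player can ever secure a strictly higher long-term payoff).  The module
also provides the classical comparison strategies (AllC, AllD, TFT, WSLS,
the all-or-none family AON-k) and the deterministic memory-one families.

All strategies are focal-perspective lookup tables over encoded history
profiles (see :mod:`capri.game`).  For ``n >= 4`` the CAPRI table
(``2**(n*(2n-1))`` entries) is not materialized; the rule logic is evaluated
on demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .game import (
    COOPERATE,
    DEFECT,
    HistoryProfile,
    perspective_code,
    player_fields,
)

__all__ = [
    "DeterministicStrategy",
    "MemoryOneStochastic",
    "capri_rule",
    "capri_action_codes",
    "build_capri",
    "build_allc",
    "build_alld",
    "build_tft",
    "build_wsls",
    "build_aon",
    "build_named",
    "build_memory_one",
    "enumerate_memory_one",
    "memory_one_index",
    "is_symmetric",
    "random_strategy",
]

#: CAPRI tables are materialized only up to this many history bits.
_MAX_TABLE_BITS = 22


@dataclass(frozen=True, eq=False)
class DeterministicStrategy:
    """A total map from focal-perspective history profiles to an action.

    ``table[code]`` is the prescribed action (0 = cooperate, 1 = defect) for
    the history with integer code ``code``.  Strategies too large to tabulate
    carry ``fn`` instead, a callable ``fn(code) -> action``.
    """

    n: int
    m: int
    table: np.ndarray | None = None
    fn: Callable[[int], int] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.table is None and self.fn is None:
            raise ValueError("strategy needs a table or an evaluation function")
        if self.table is not None:
            expected = 1 << (self.n * self.m)
            if len(self.table) != expected:
                raise ValueError(
                    f"table has {len(self.table)} entries, expected {expected}"
                )
            object.__setattr__(
                self, "table", np.ascontiguousarray(self.table, dtype=np.uint8)
            )

    def action(self, h: HistoryProfile | int) -> int:
        """Prescribed action at a history (profile object or integer code)."""
        code = h.code if isinstance(h, HistoryProfile) else int(h)
        if self.table is not None:
            return int(self.table[code])
        return int(self.fn(code))

    def actions(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`action` over an array of codes."""
        if self.table is not None:
            return self.table[np.asarray(codes, dtype=np.int64)]
        return np.fromiter(
            (self.fn(int(c)) for c in np.asarray(codes).ravel()),
            dtype=np.uint8,
            count=np.asarray(codes).size,
        )

    def lift(self, m_star: int) -> "DeterministicStrategy":
        """Embed into a longer memory window; only the newest m columns are read."""
        if m_star == self.m:
            return self
        if m_star < self.m:
            raise ValueError("cannot lift to a shorter memory")
        if self.table is None:
            raise ValueError("lifting requires a materialized table")
        codes = np.arange(1 << (self.n * m_star), dtype=np.uint64)
        sub = np.zeros_like(codes)
        mask = np.uint64((1 << self.m) - 1)
        for i in range(self.n):
            row = (codes >> np.uint64(i * m_star)) & mask
            sub |= row << np.uint64(i * self.m)
        table = self.table[sub.astype(np.int64)]
        return DeterministicStrategy(
            self.n, m_star, table=table, name=self.name
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, DeterministicStrategy):
            return NotImplemented
        if (self.n, self.m) != (other.n, other.m):
            return False
        if self.table is not None and other.table is not None:
            return bool(np.array_equal(self.table, other.table))
        raise ValueError("equality of non-tabulated strategies is undecidable")

    def __hash__(self) -> int:
        if self.table is None:
            return hash((self.n, self.m, id(self.fn)))
        return hash((self.n, self.m, self.table.tobytes()))


@dataclass(frozen=True, eq=False)
class MemoryOneStochastic:
    """Memory-one stochastic strategy.

    ``probs[a, k]`` is the probability of cooperating after the player itself
    played ``a`` (0 = c, 1 = d) and ``k`` of the ``n-1`` co-players
    cooperated.  For ``n = 2`` this is the familiar
    ``(p_cc, p_cd, p_dc, p_dd)`` quadruple with ``p_cc = probs[0, 1]``,
    ``p_cd = probs[0, 0]``, ``p_dc = probs[1, 1]``, ``p_dd = probs[1, 0]``.
    """

    n: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2, self.n):
            raise ValueError(f"probs must have shape (2, n), got {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("cooperation probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_quadruple(cls, p_cc, p_cd, p_dc, p_dd) -> "MemoryOneStochastic":
        return cls(2, np.array([[p_cd, p_cc], [p_dd, p_dc]]))

    def coop_probs(self, codes: np.ndarray, m: int) -> np.ndarray:
        """Cooperation probability at each focal-perspective history code."""
        codes = np.asarray(codes, dtype=np.uint64)
        one = np.uint64(1)
        own = ((codes >> np.uint64(0)) & one).astype(np.int64)
        k = np.zeros(codes.shape, dtype=np.int64)
        for j in range(1, self.n):
            k += 1 - ((codes >> np.uint64(j * m)) & one).astype(np.int64)
        return self.probs[own, k]


# ---------------------------------------------------------------------------
# CAPRI-n
# ---------------------------------------------------------------------------

def capri_rule(h: HistoryProfile, strict_recovery: bool = True) -> tuple[str, int]:
    """Apply the five CAPRI rules at one history; returns (rule label, action).

    With t* the most recent round of full cooperation in the m-round window,
    D_i the number of defections of player i since t* (inclusive), and N_d
    the maximum pairwise difference in defection counts over the window:

    * ``C`` (cooperate): t* = t-1 and N_d < n  ->  c
    * ``A`` (accept):    t-m <= t* < t-1, N_d < n, and the focal player has
      defected at least as often as every co-player since t*  ->  c
    * ``P`` (punish):    t-m <= t* < t-1, N_d < n, and some co-player has
      defected more than the focal player since t*  ->  d
    * ``R`` (recover):   no full cooperation in memory, every column but the
      newest is all-defect, and exactly n-1 players cooperated in the newest
      round (the lone defector may be anyone)  ->  c
    * ``I`` (otherwise): defect.

    Exactly one rule fires at every history.  Requires ``m = 2n - 1``.

    With ``strict_recovery=False`` the R rule fires whenever no full
    cooperation is remembered and the newest round had exactly n-1
    cooperators, regardless of the older columns.  That looser reading
    breaks defensibility — a co-player can milk the recovery attempt
    indefinitely — and is provided only so the certifier can demonstrate
    the difference; the strict form is the defined strategy.
    """
    n, m = h.n, h.m
    if m != 2 * n - 1:
        raise ValueError(f"CAPRI-{n} requires memory m = 2n-1 = {2 * n - 1}")
    label = _capri_label_scalar(h.code, n, m, strict_recovery)
    return label, COOPERATE if label in ("C", "A", "R") else DEFECT


def _capri_label_scalar(
    code: int, n: int, m: int, strict_recovery: bool = True
) -> str:
    mask = (1 << m) - 1
    rows = [(code >> (i * m)) & mask for i in range(n)]
    union = 0
    intersection = mask
    for r in rows:
        union |= r
        intersection &= r
    full = [r.bit_count() for r in rows]
    n_d = max(full) - min(full)
    # lowest zero bit of the union marks the last all-cooperate column
    z = 0
    u = union
    while u & 1:
        u >>= 1
        z += 1
    if z < m:  # t* = t - (z+1) is in the window
        if n_d >= n:
            return "I"
        if z == 0:
            return "C"
        since_mask = (1 << z) - 1  # column t* itself is all-c, contributes 0
        since = [(r & since_mask).bit_count() for r in rows]
        if since[0] >= max(since[1:]):
            return "A"
        return "P"
    # no full cooperation remembered
    older_all_d = (intersection >> 1) == (mask >> 1)
    newest_defectors = sum(r & 1 for r in rows)
    if newest_defectors == 1 and (older_all_d or not strict_recovery):
        return "R"
    return "I"


def capri_label_codes(
    codes: np.ndarray, n: int, m: int, strict_recovery: bool = True
) -> np.ndarray:
    """Vectorized rule labels over history codes (values 'C','A','P','R','I')."""
    fields = player_fields(codes, n, m)
    mask = np.uint64((1 << m) - 1)
    union = fields[0].copy()
    inter = fields[0].copy()
    for i in range(1, n):
        union |= fields[i]
        inter &= fields[i]
    full_counts = np.bitwise_count(fields).astype(np.int64)
    n_d = full_counts.max(axis=0) - full_counts.min(axis=0)
    # trailing-ones count of the union = z; t* = t-(z+1) when z < m
    z = np.bitwise_count((~union & (union + np.uint64(1)) & mask) - np.uint64(1))
    z = z.astype(np.int64)
    # the expression above yields trailing-ones via lowest-zero-bit isolation
    has_star = z < m
    since_mask = (np.uint64(1) << z.astype(np.uint64)) - np.uint64(1)
    since = np.bitwise_count(fields & since_mask).astype(np.int64)
    co_max_since = since[1:].max(axis=0) if n > 1 else np.zeros_like(since[0])

    labels = np.full(np.asarray(codes).shape, "I", dtype="U1")
    nd_ok = n_d < n
    labels[has_star & nd_ok & (z == 0)] = "C"
    a_mask = has_star & nd_ok & (z > 0)
    labels[a_mask & (since[0] >= co_max_since)] = "A"
    labels[a_mask & (since[0] < co_max_since)] = "P"
    older_all_d = (inter >> np.uint64(1)) == (mask >> np.uint64(1))
    if not strict_recovery:
        older_all_d = np.ones_like(older_all_d, dtype=bool)
    newest_defectors = np.bitwise_count(fields & np.uint64(1)).sum(axis=0)
    labels[(~has_star) & older_all_d & (newest_defectors == 1)] = "R"
    return labels


def capri_action_codes(
    codes: np.ndarray, n: int, m: int, strict_recovery: bool = True
) -> np.ndarray:
    """Vectorized CAPRI-n prescription (0/1) over history codes."""
    labels = capri_label_codes(codes, n, m, strict_recovery)
    return np.where(np.isin(labels, ("C", "A", "R")), COOPERATE, DEFECT).astype(
        np.uint8
    )


def build_capri(
    n: int,
    materialize: bool | None = None,
    strict_recovery: bool = True,
) -> DeterministicStrategy:
    """Construct CAPRI-n (memory ``m = 2n - 1``).

    For ``n <= 3`` the full lookup table is materialized (64 entries at
    ``n = 2``, 32768 at ``n = 3``); beyond that the strategy is evaluated
    on demand from the rule logic.  ``strict_recovery`` selects the
    defensible form of the R rule (see :func:`capri_rule`).
    """
    if n < 2:
        raise ValueError("CAPRI-n requires n >= 2")
    m = 2 * n - 1
    bits = n * m
    if materialize is None:
        materialize = bits <= _MAX_TABLE_BITS
    name = f"CAPRI-{n}" if strict_recovery else f"CAPRI-{n}-looseR"
    if materialize:
        if bits > _MAX_TABLE_BITS:
            raise ValueError(f"CAPRI-{n} table (2**{bits} entries) is too large")
        codes = np.arange(1 << bits, dtype=np.uint64)
        table = capri_action_codes(codes, n, m, strict_recovery)
        return DeterministicStrategy(n, m, table=table, name=name)
    fn = lambda code: (
        COOPERATE
        if _capri_label_scalar(code, n, m, strict_recovery) in ("C", "A", "R")
        else DEFECT
    )
    return DeterministicStrategy(n, m, fn=fn, name=name)


# ---------------------------------------------------------------------------
# Comparison strategies
# ---------------------------------------------------------------------------

def build_allc(n: int, m: int = 1) -> DeterministicStrategy:
    table = np.zeros(1 << (n * m), dtype=np.uint8)
    return DeterministicStrategy(n, m, table=table, name="AllC")


def build_alld(n: int, m: int = 1) -> DeterministicStrategy:
    table = np.ones(1 << (n * m), dtype=np.uint8)
    return DeterministicStrategy(n, m, table=table, name="AllD")


def build_tft(n: int = 2, m: int = 1) -> DeterministicStrategy:
    """Tit-for-tat: copy the co-player's newest action (two players only)."""
    if n != 2:
        raise ValueError("TFT is defined for n = 2")
    codes = np.arange(1 << (2 * m), dtype=np.uint64)
    table = ((codes >> np.uint64(m)) & np.uint64(1)).astype(np.uint8)
    return DeterministicStrategy(n, m, table=table, name="TFT")


def build_wsls(n: int = 2, m: int = 1) -> DeterministicStrategy:
    """Win-stay-lose-shift (1,0,0,1): cooperate iff last round was unanimous."""
    if n != 2:
        raise ValueError("WSLS is defined for n = 2; use AON-1 otherwise")
    return build_aon(1, n, m).rename("WSLS")


def build_aon(k: int, n: int, m: int | None = None) -> DeterministicStrategy:
    """All-or-none AON-k: cooperate iff each of the newest k rounds was
    unanimous (everyone cooperated or everyone defected).  AON-1 coincides
    with WSLS for two players."""
    if m is None:
        m = k
    if not 1 <= k <= m:
        raise ValueError("AON-k requires 1 <= k <= m")
    codes = np.arange(1 << (n * m), dtype=np.uint64)
    fields = player_fields(codes, n, m)
    kmask = np.uint64((1 << k) - 1)
    union = np.zeros_like(codes)
    inter = np.full_like(codes, kmask)
    for i in range(n):
        union |= fields[i] & kmask
        inter &= fields[i]
    # each of the newest k columns is unanimous <=> OR and AND agree there
    table = np.where(union == inter, COOPERATE, DEFECT).astype(np.uint8)
    return DeterministicStrategy(n, m, table=table, name=f"AON-{k}")


def build_named(name: str, n: int, m: int | None = None) -> DeterministicStrategy:
    """Build a comparison strategy by name: AllC, AllD, TFT, WSLS, AON-k,
    CAPRI (memory fixed at 2n-1), optionally lifted to memory ``m``."""
    key = name.strip().lower()
    if key.startswith("aon-"):
        k = int(key[4:])
        return build_aon(k, n, m if m is not None else k)
    builders = {
        "allc": build_allc,
        "alld": build_alld,
        "tft": build_tft,
        "wsls": build_wsls,
    }
    if key in builders:
        return builders[key](n, m if m is not None else 1)
    if key in ("capri", f"capri-{n}"):
        s = build_capri(n)
        return s.lift(m) if m is not None and m != s.m else s
    raise ValueError(f"unknown strategy name {name!r}")


def _rename(self: DeterministicStrategy, name: str) -> DeterministicStrategy:
    return DeterministicStrategy(self.n, self.m, table=self.table, fn=self.fn, name=name)


DeterministicStrategy.rename = _rename


# ---------------------------------------------------------------------------
# Memory-one families
# ---------------------------------------------------------------------------

def build_memory_one(bits: Sequence[int], n: int) -> DeterministicStrategy:
    """Deterministic memory-one strategy from a (2, n) action assignment.

    ``bits[a][k]`` (flattened, own action major) is the action after the
    player itself played ``a`` and ``k`` co-players cooperated.
    """
    arr = np.asarray(bits, dtype=np.uint8).reshape(2, n)
    probs = 1.0 - arr  # cooperation probability 1 where action is c (=0)
    stochastic = MemoryOneStochastic(n, probs)
    codes = np.arange(1 << n, dtype=np.uint64)
    p = stochastic.coop_probs(codes, 1)
    table = np.where(p >= 0.5, COOPERATE, DEFECT).astype(np.uint8)
    name = "M1-" + "".join(str(int(x)) for x in arr.ravel())
    return DeterministicStrategy(n, 1, table=table, name=name)


def memory_one_index(s: DeterministicStrategy) -> tuple[int, ...]:
    """The (own action, co-op count) action assignment of a memory-one table."""
    if s.m != 1:
        raise ValueError("not a memory-one strategy")
    out = []
    for own in (COOPERATE, DEFECT):
        for k in range(s.n):
            # a representative history: own action + k cooperating co-players
            code = own
            for j in range(1, s.n):
                if j > k:
                    code |= 1 << j
            out.append(int(s.table[code]))
    return tuple(out)


def enumerate_memory_one(n: int) -> list[DeterministicStrategy]:
    """All ``2**(2n)`` deterministic memory-one strategies (16 for n=2, 64
    for n=3), indexed by (own previous action, number of cooperating
    co-players)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    out = []
    for idx in range(1 << (2 * n)):
        bits = [(idx >> j) & 1 for j in range(2 * n)]
        out.append(build_memory_one(bits, n))
    return out


# ---------------------------------------------------------------------------
# Symmetry and random sampling
# ---------------------------------------------------------------------------

def is_symmetric(s: DeterministicStrategy) -> bool:
    """True iff the prescription is invariant under every permutation of the
    co-player rows."""
    if s.table is None:
        raise ValueError("symmetry check requires a materialized table")
    from itertools import permutations

    codes = np.arange(1 << (s.n * s.m), dtype=np.uint64)
    fields = player_fields(codes, s.n, s.m)
    for perm in permutations(range(1, s.n)):
        if list(perm) == list(range(1, s.n)):
            continue
        permuted = fields[0].copy()
        for new_i, old_i in zip(range(1, s.n), perm):
            permuted |= fields[old_i] << np.uint64(new_i * s.m)
        if not np.array_equal(s.table, s.table[permuted.astype(np.int64)]):
            return False
    return True


def random_strategy(
    n: int, m: int, rng: np.random.Generator | int
) -> DeterministicStrategy:
    """A uniformly random deterministic strategy: every table entry is an
    independent fair coin from the seeded generator."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    table = rng.integers(0, 2, size=1 << (n * m), dtype=np.uint8)
    return DeterministicStrategy(n, m, table=table, name="random")
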