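"""Core primitives of the iterated n-person public-goods game.

Actions, joint actions, history profiles, payoff schemes, and the history
statistics (last round of full cooperation, per-player defection counts,
maximum defection gap) that conditional strategies are built from.

A history profile records the actions of all ``n`` players over the previous
``m`` rounds.  It is encoded as an ``n*m``-bit integer: player ``i`` occupies
bits ``[i*m, (i+1)*m)``; within a player's field, bit 0 is the most recent
round (t-1) and a set bit means *defect*.  This makes extraction of the
newest round and the append-a-round shift pure mask/shift operations, and it
gives a bijection between history profiles and the integers
``0 .. 2**(n*m) - 1``.  The focal player is row 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "COOPERATE",
    "DEFECT",
    "GameParams",
    "HistoryProfile",
    "pg_payoffs",
    "donation_payoffs",
    "rho_from_b",
    "encode_history",
    "decode_history",
    "last_full_coop",
    "defection_counts",
    "max_defection_gap",
    "shift",
    "player_fields",
    "shift_codes",
    "newest_joint",
    "perspective_code",
    "count_symmetric_history_classes",
]

#: Integer encoding of the two actions.  DEFECT is 1 so that a history
#: profile's bits directly count defections.
COOPERATE = 0
DEFECT = 1

_ACTION_CHARS = {"c": COOPERATE, "d": DEFECT}
_CHAR_OF = {COOPERATE: "c", DEFECT: "d"}


def _validate_action(a: int) -> int:
    if a not in (COOPERATE, DEFECT):
        raise ValueError(f"action must be 0 (cooperate) or 1 (defect), got {a!r}")
    return int(a)


# ---------------------------------------------------------------------------
# Payoff schemes
# ---------------------------------------------------------------------------

def pg_payoffs(joint: Sequence[int], rho: float) -> np.ndarray:
    """Per-player payoffs of one public-goods round.

    Each cooperator contributes one token; the ``n_c`` tokens are multiplied
    by ``rho`` and split equally, so a cooperator earns ``rho*n_c/n`` and a
    defector keeps the token and earns ``1 + rho*n_c/n``.

    Parameters
    ----------
    joint:
        Actions of the ``n`` players (0 = cooperate, 1 = defect).
    rho:
        Multiplication factor; the game is a dilemma only for
        ``1 < rho < n``.
    """
    a = np.asarray(joint, dtype=np.int64)
    n = a.size
    if not 1.0 < rho < n:
        raise ValueError(f"rho must satisfy 1 < rho < n={n}, got {rho}")
    n_c = int(np.sum(a == COOPERATE))
    base = rho * n_c / n
    return base + a  # defectors (=1) keep their token

def donation_payoffs(joint: Sequence[int], b: float) -> np.ndarray:
    """Per-player payoffs of one n-player donation-game round.

    A cooperator pays a unit cost and donates ``b/(n-1)`` to every co-player.
    Requires ``b > 1`` (otherwise the dilemma degenerates).
    """
    a = np.asarray(joint, dtype=np.int64)
    n = a.size
    if b <= 1:
        raise ValueError(f"donation benefit must exceed 1, got {b}")
    n_c = int(np.sum(a == COOPERATE))
    coop_coplayers = n_c - (a == COOPERATE)  # cooperating co-players of each i
    return (b / (n - 1)) * coop_coplayers - (a == COOPERATE)


def rho_from_b(b: float, n: int) -> float:
    """Multiplication factor equivalent to a donation game with benefit ``b``.

    The n-player donation game with benefit ``b > 1`` corresponds, up to an
    affine rescaling of payoffs, to the public-goods game with
    ``rho = n*b / (b + n - 1)``, which always lies in ``(1, n)``.
    """
    if b <= 1:
        raise ValueError(f"donation benefit must exceed 1, got {b}")
    return n * b / (b + n - 1)


@dataclass(frozen=True)
class GameParams:
    """Parameters of the repeated game.

    Either ``rho`` (public-goods multiplication factor) or ``b`` (donation
    benefit) may be given; the missing one is derived when possible.
    ``epsilon`` is the implementation-error rate: independently each round,
    each player executes the opposite of the intended action with this
    probability.
    """

    n: int
    rho: float | None = None
    b: float | None = None
    epsilon: float = 1e-4
    payoff_scheme: str = "pg"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two players")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must lie in [0, 1/2), got {self.epsilon}")
        if self.payoff_scheme not in ("pg", "donation"):
            raise ValueError(f"unknown payoff scheme {self.payoff_scheme!r}")
        if self.rho is None and self.b is not None:
            object.__setattr__(self, "rho", rho_from_b(self.b, self.n))
        if self.rho is not None and not 1.0 < self.rho < self.n:
            raise ValueError(f"rho must satisfy 1 < rho < n, got {self.rho}")
        if self.payoff_scheme == "pg" and self.rho is None:
            raise ValueError("pg scheme requires rho (or b to derive it)")
        if self.payoff_scheme == "donation" and self.b is None:
            raise ValueError("donation scheme requires b")

    def round_payoffs(self, joint: Sequence[int]) -> np.ndarray:
        if self.payoff_scheme == "pg":
            return pg_payoffs(joint, self.rho)
        return donation_payoffs(joint, self.b)


# ---------------------------------------------------------------------------
# History encoding (scalar and vectorized)
# ---------------------------------------------------------------------------

def encode_history(rows: Sequence[Sequence[int]], m: int | None = None) -> int:
    """Encode per-player action rows (oldest first) into the integer code."""
    n = len(rows)
    if m is None:
        m = len(rows[0])
    code = 0
    for i, row in enumerate(rows):
        if len(row) != m:
            raise ValueError("all rows must have length m")
        for k, a in enumerate(row):  # k=0 oldest -> bit m-1-k
            if _validate_action(a) == DEFECT:
                code |= 1 << (i * m + (m - 1 - k))
    return code


def decode_history(code: int, n: int, m: int) -> list[list[int]]:
    """Inverse of :func:`encode_history`; rows ordered oldest to newest."""
    if not 0 <= code < 1 << (n * m):
        raise ValueError("code out of range")
    rows = []
    for i in range(n):
        field = (code >> (i * m)) & ((1 << m) - 1)
        rows.append([(field >> (m - 1 - k)) & 1 for k in range(m)])
    return rows


class HistoryProfile:
    """The n x m grid of the most recent actions, focal player in row 0.

    Construct from rows of actions (oldest first), from a compact string such
    as ``"ccccc;cccdc;ccccc"``, or from the integer code.
    """

    __slots__ = ("n", "m", "code")

    def __init__(self, n: int, m: int, code: int):
        if not 0 <= code < 1 << (n * m):
            raise ValueError("code out of range for given n, m")
        self.n = n
        self.m = m
        self.code = int(code)

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "HistoryProfile":
        n, m = len(rows), len(rows[0])
        return cls(n, m, encode_history(rows, m))

    @classmethod
    def from_string(cls, s: str) -> "HistoryProfile":
        rows = [[_ACTION_CHARS[ch] for ch in part] for part in s.split(";")]
        return cls.from_rows(rows)

    def rows(self) -> list[list[int]]:
        return decode_history(self.code, self.n, self.m)

    def __str__(self) -> str:
        return ";".join("".join(_CHAR_OF[a] for a in row) for row in self.rows())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"HistoryProfile({self!s})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HistoryProfile)
            and (self.n, self.m, self.code) == (other.n, other.m, other.code)
        )

    def __hash__(self) -> int:
        return hash((self.n, self.m, self.code))

    def newest(self) -> list[int]:
        """The joint action of round t-1."""
        return [(self.code >> (i * self.m)) & 1 for i in range(self.n)]

    def permute_coplayers(self, perm: Sequence[int]) -> "HistoryProfile":
        """Reorder the non-focal rows by ``perm`` (a permutation of 1..n-1)."""
        rows = self.rows()
        new_rows = [rows[0]] + [rows[j] for j in perm]
        return HistoryProfile.from_rows(new_rows)


# -- history statistics ------------------------------------------------------

def last_full_coop(h: HistoryProfile) -> int | None:
    """Offset k such that round t-k was the last round of full cooperation.

    Returns ``None`` when no column in the window is all-cooperate.
    """
    mask = (1 << h.m) - 1
    union = 0
    for i in range(h.n):
        union |= (h.code >> (i * h.m)) & mask
    # lowest zero bit of the union = most recent all-c column
    z = _trailing_ones(union)
    return z + 1 if z < h.m else None


def _trailing_ones(x: int) -> int:
    count = 0
    while x & 1:
        x >>= 1
        count += 1
    return count


def defection_counts(h: HistoryProfile, from_offset: int) -> list[int]:
    """Each player's number of defections in rounds t-from_offset .. t-1."""
    if not 1 <= from_offset <= h.m:
        raise ValueError(f"from_offset must lie in [1, m={h.m}]")
    mask = (1 << from_offset) - 1
    return [
        int(((h.code >> (i * h.m)) & mask).bit_count()) for i in range(h.n)
    ]


def max_defection_gap(h: HistoryProfile) -> int:
    """Maximum pairwise difference in defection counts over the full window."""
    counts = defection_counts(h, h.m)
    return max(counts) - min(counts)


def shift(h: HistoryProfile, joint: Sequence[int]) -> HistoryProfile:
    """Drop the oldest round and append ``joint`` as the newest."""
    if len(joint) != h.n:
        raise ValueError("joint action arity must equal n")
    m, mask = h.m, (1 << h.m) - 1
    code = 0
    for i in range(h.n):
        field = (h.code >> (i * m)) & mask
        field = ((field << 1) & mask) | _validate_action(joint[i])
        code |= field << (i * m)
    return HistoryProfile(h.n, h.m, code)


# ---------------------------------------------------------------------------
# Vectorized counterparts operating on arrays of integer codes
# ---------------------------------------------------------------------------

def player_fields(codes: np.ndarray, n: int, m: int) -> np.ndarray:
    """Stack of per-player m-bit fields, shape (n, len(codes))."""
    codes = np.asarray(codes, dtype=np.uint64)
    mask = np.uint64((1 << m) - 1)
    return np.stack([(codes >> np.uint64(i * m)) & mask for i in range(n)])


def shift_codes(codes: np.ndarray, joint_mask: int, n: int, m: int) -> np.ndarray:
    """Vectorized :func:`shift`; ``joint_mask`` packs player i's action in bit i."""
    codes = np.asarray(codes, dtype=np.uint64)
    mask = np.uint64((1 << m) - 1)
    out = np.zeros_like(codes)
    for i in range(n):
        field = (codes >> np.uint64(i * m)) & mask
        field = ((field << np.uint64(1)) & mask) | np.uint64((joint_mask >> i) & 1)
        out |= field << np.uint64(i * m)
    return out


def newest_joint(codes: np.ndarray, n: int, m: int) -> np.ndarray:
    """Newest-round action of each player, shape (n, len(codes))."""
    codes = np.asarray(codes, dtype=np.uint64)
    one = np.uint64(1)
    return np.stack(
        [((codes >> np.uint64(i * m)) & one).astype(np.int64) for i in range(n)]
    )


def perspective_code(codes: np.ndarray, player: int, n: int, m: int) -> np.ndarray:
    """Re-encode histories from ``player``'s point of view.

    The player's own row becomes row 0; the co-players follow in ascending
    original index.  For co-player-symmetric strategies any co-player order
    gives the same prescription, but the convention is fixed so that
    arbitrary (asymmetric) tables are well defined.
    """
    fields = player_fields(codes, n, m)
    order = [player] + [j for j in range(n) if j != player]
    out = np.zeros_like(np.asarray(codes, dtype=np.uint64))
    for new_i, old_i in enumerate(order):
        out |= fields[old_i] << np.uint64(new_i * m)
    return out


def count_symmetric_history_classes(n: int, m: int) -> int:
    """Number of focal history profiles up to permutation of co-players.

    Burnside count over the symmetric group on the ``n-1`` co-player rows:
    a permutation with ``c`` cycles fixes ``2**(m*(c+1))`` profiles (the +1
    is the focal row).
    """
    from itertools import permutations

    total = 0
    count = 0
    for perm in permutations(range(n - 1)):
        count += 1
        c = _cycle_count(perm)
        total += 1 << (m * (c + 1))
    return total // count


def _cycle_count(perm: tuple[int, ...]) -> int:
    seen = [False] * len(perm)
    cycles = 0
    for i in range(len(perm)):
        if not seen[i]:
            cycles += 1
            j = i
            while not seen[j]:
                seen[j] = True
                j = perm[j]
    return cycles
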