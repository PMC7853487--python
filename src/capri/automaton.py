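"""Finite-state-machine view of lookup-table strategies.

A memory-m strategy is a Moore machine whose states are the ``2**(n*m)``
history profiles, whose output at a state is the prescribed action, and
whose input alphabet is the full joint action of the round (``2**n``
symbols, including the focal player's *realized* action, so error-perturbed
trajectories are representable).  Partition refinement collapses
behaviorally equivalent states, which makes graph-theoretic certification of
large-memory strategies tractable.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .game import shift_codes
from .strategies import DeterministicStrategy

__all__ = ["StrategyAutomaton", "to_automaton", "minimize", "equivalent"]


@dataclass(frozen=True, eq=False)
class StrategyAutomaton:
    """Moore machine: ``output[s]`` is the action at state ``s`` and
    ``transition[s, a]`` the next state on joint action ``a`` (player i's
    realized action in bit i).  ``state_of[h]`` maps a history code to its
    state (the identity for an unminimized machine)."""

    n: int
    output: np.ndarray          # (S,) uint8
    transition: np.ndarray      # (S, 2**n) int64
    state_of: np.ndarray        # (2**(n*m),) int64, history code -> state

    @property
    def n_states(self) -> int:
        return len(self.output)

    def run(self, start_code: int, inputs) -> np.ndarray:
        """Outputs emitted along an input word, starting from a history."""
        s = int(self.state_of[start_code])
        out = np.empty(len(inputs), dtype=np.uint8)
        for t, a in enumerate(inputs):
            out[t] = self.output[s]
            s = int(self.transition[s, a])
        return out

    def to_dict(self) -> dict:
        """JSON-serializable export."""
        return {
            "n": self.n,
            "n_states": self.n_states,
            "outputs": ["c" if o == 0 else "d" for o in self.output],
            "transitions": self.transition.tolist(),
        }

    def to_dot(self) -> str:
        """DOT-format rendering (states colored by action)."""
        lines = ["digraph strategy {", "  rankdir=LR;"]
        for s in range(self.n_states):
            color = "lightblue" if self.output[s] == 0 else "salmon"
            lines.append(
                f'  s{s} [label="{s}:{"c" if self.output[s] == 0 else "d"}",'
                f" style=filled, fillcolor={color}];"
            )
        for s in range(self.n_states):
            targets: dict[int, list[int]] = {}
            for a in range(self.transition.shape[1]):
                targets.setdefault(int(self.transition[s, a]), []).append(a)
            for t, symbols in targets.items():
                label = ",".join(format(a, f"0{self.n}b")[::-1] for a in symbols)
                lines.append(f'  s{s} -> s{t} [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


def to_automaton(s: DeterministicStrategy) -> StrategyAutomaton:
    """The unminimized machine: one state per history profile."""
    if s.table is None:
        raise ValueError("automaton construction requires a materialized table")
    n, m = s.n, s.m
    n_states = 1 << (n * m)
    codes = np.arange(n_states, dtype=np.uint64)
    transition = np.empty((n_states, 1 << n), dtype=np.int64)
    for joint in range(1 << n):
        transition[:, joint] = shift_codes(codes, joint, n, m).astype(np.int64)
    return StrategyAutomaton(
        n=n,
        output=s.table.copy(),
        transition=transition,
        state_of=np.arange(n_states, dtype=np.int64),
    )


def minimize(a: StrategyAutomaton) -> StrategyAutomaton:
    """Moore-style partition refinement to the unique minimal machine.

    Start from the partition by output; refine by transition signatures until
    stable.  The result is behaviorally equivalent to the input from every
    state (and therefore from every history).
    """
    n_states = a.n_states
    block = a.output.astype(np.int64)
    n_blocks = int(block.max()) + 1 if n_states else 0
    while True:
        # signature: own block + blocks of all successors
        sig = np.column_stack([block, block[a.transition]])
        _, new_block = np.unique(sig, axis=0, return_inverse=True)
        new_n = int(new_block.max()) + 1
        if new_n == n_blocks:
            break
        block, n_blocks = new_block.astype(np.int64), new_n
    reps = np.zeros(n_blocks, dtype=np.int64)
    reps[block] = np.arange(n_states)  # any member works as representative
    output = a.output[reps]
    transition = block[a.transition[reps]]
    return StrategyAutomaton(
        n=a.n,
        output=output,
        transition=transition,
        state_of=block[a.state_of],
    )


def equivalent(a: StrategyAutomaton, b: StrategyAutomaton) -> bool:
    """Behavioral equivalence by product-machine breadth-first search.

    Pairs every history's state in ``a`` with the same history's state in
    ``b`` and explores all reachable pairs under every input symbol; the
    machines are equivalent iff outputs agree on every reachable pair.
    """
    if a.n != b.n:
        raise ValueError("automata must share the player count")
    if len(a.state_of) != len(b.state_of):
        raise ValueError("automata must be built over the same history space")
    n_inputs = a.transition.shape[1]
    start_pairs = {(int(x), int(y)) for x, y in zip(a.state_of, b.state_of)}
    seen = set(start_pairs)
    queue = deque(start_pairs)
    while queue:
        x, y = queue.popleft()
        if a.output[x] != b.output[y]:
            return False
        for sym in range(n_inputs):
            nxt = (int(a.transition[x, sym]), int(b.transition[y, sym]))
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return True
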