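"""Build CAPRI-n and look at how the five rules tile the history space.

CAPRI-n conditions on the previous m = 2n-1 rounds.  Every history profile
falls under exactly one rule: Cooperate (full cooperation last round, small
defection imbalance), Accept (take punishment for own surplus defections),
Punish (defect while a co-player owes), Recover (escape mutual defection
when exactly n-1 players just cooperated), or defect In all other cases.
"""

import numpy as np

from capri import HistoryProfile, build_capri, capri_rule, minimize, to_automaton
from capri.strategies import capri_label_codes

for n in (2, 3):
    s = build_capri(n)
    m = 2 * n - 1
    labels = capri_label_codes(np.arange(1 << (n * m), dtype=np.uint64), n, m)
    counts = {lab: int((labels == lab).sum()) for lab in "CAPRI"}
    auto = minimize(to_automaton(s))
    print(f"CAPRI-{n}: table {len(s.table)} entries, rule counts {counts}, "
          f"minimal automaton {auto.n_states} states")

print()
for hist in ["ccccc;cccdc;ccccc", "cccdc;ccccd;ccccc", "ccccd;cccdd;ccccc",
             "ddddd;ddddc;ddddc", "cdddc;ccddc;ccccc"]:
    rule, action = capri_rule(HistoryProfile.from_string(hist))
    print(f"{hist}  ->  rule {rule}, play {'c' if action == 0 else 'd'}")

# The rule counts show defection is the default posture (I dominates), while
# the automaton sizes show how much of the 2^(nm) table is behaviorally
# redundant: 64 -> 18 states for n=2, 32768 -> 1446 for n=3.
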