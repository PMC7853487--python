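"""Certify strategies against the three friendly-rivalry criteria.

Defensibility: no co-player can ever come out ahead at zero error rate
(no positive relative-payoff cycle in the game graph).  Efficiency: a
homogeneous population reaches full cooperation as the error rate vanishes.
Distinguishability: unconditional cooperators are strictly exploited.
A strategy with the first two is a friendly rival; with all three it is
called successful.
"""

from capri import build_allc, build_alld, build_capri, build_wsls, certify

for s in [build_capri(2), build_capri(3), build_alld(2), build_allc(2), build_wsls()]:
    r = certify(s)
    print(f"{s.name:10s} defensible={r.defensible!s:5s} efficient={r.efficient!s:5s} "
          f"distinguishing={r.distinguishing!s:5s} labels={sorted(r.labels)}")
    if r.defensibility_witness:
        first = r.defensibility_witness[0]
        print(f"{'':10s} witness cycle starts at {first['history']} "
              f"with joint action {first['joint']} ({len(r.defensibility_witness)} steps)")

# CAPRI-2 and CAPRI-3 pass all three criteria; AllD is a rival but not a
# partner (defensible, not efficient); AllC and WSLS are partners but not
# rivals — the witness cycle shows exactly how a co-player milks them.
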