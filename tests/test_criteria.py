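"""Certification: defensibility cycles, recurrent classes, resistances,
efficiency, distinguishability, and strategy-set classification."""

import numpy as np
import pytest

from capri.criteria import (
    certify,
    check_defensibility,
    check_distinguishability,
    check_efficiency,
    classify,
    min_error_resistance,
    recurrent_classes,
    replay_witness_gain,
)
from capri.dynamics import GameParams, StrategyProfile, analyze
from capri.strategies import (
    build_aon,
    build_allc,
    build_alld,
    build_capri,
    build_memory_one,
    build_tft,
    build_wsls,
    random_strategy,
)


# -- defensibility -----------------------------------------------------------

def test_capri_defensible(capri2, capri3):
    assert check_defensibility(capri2) == (True, None)
    assert check_defensibility(capri3) == (True, None)


def test_alld_and_tft_defensible():
    assert check_defensibility(build_alld(2))[0]
    assert check_defensibility(build_alld(3))[0]
    assert check_defensibility(build_tft())[0]


@pytest.mark.parametrize(
    "builder", [lambda: build_allc(2), build_wsls], ids=["AllC", "WSLS"]
)
def test_non_defensible_with_positive_witness(builder):
    s = builder()
    verdict, witness = check_defensibility(s)
    assert not verdict
    assert witness
    assert replay_witness_gain(s, witness) > 0


def test_loose_recovery_rule_breaks_defensibility():
    # regression guard for the recovery-rule reading: if recovery only
    # checked the newest round, a co-player could milk it forever
    for n in (2, 3):
        s = build_capri(n, strict_recovery=False)
        verdict, witness = check_defensibility(s)
        assert not verdict
        assert replay_witness_gain(s, witness) > 0


def test_defensible_strategies_never_outscored_by_random_opponents(capri2):
    # consistency between the error-free graph test and small-error payoffs
    params = GameParams(n=2, rho=1.5)
    eps = 1e-4
    rng = np.random.default_rng(21)
    worst = -np.inf
    for _ in range(1000):
        opp = random_strategy(2, 3, rng)
        res = analyze(StrategyProfile([capri2, opp]), params, eps=eps)
        worst = max(worst, res.payoffs[1] - res.payoffs[0])
    assert worst <= 10 * eps


# -- recurrent classes and resistances ---------------------------------------

def test_recurrent_classes(capri3):
    classes = recurrent_classes(capri3)
    assert sorted(map(tuple, classes)) == [(0,), ((1 << 15) - 1,)]
    assert [c for c in recurrent_classes(build_allc(2))] == [[0]]
    assert [c for c in recurrent_classes(build_alld(2))] == [[0b11]]


def test_error_resistances(capri2, capri3):
    for s, n in ((capri2, 2), (capri3, 3)):
        full_d = [(1 << (n * s.m)) - 1]
        full_c = [0]
        assert min_error_resistance(s, full_d, full_c) == n - 1
        assert min_error_resistance(s, full_c, full_d) >= n
    alld = build_alld(2)
    cls = recurrent_classes(alld)[0]
    assert min_error_resistance(alld, cls, cls) == 0


# -- efficiency --------------------------------------------------------------

def test_capri_efficient(capri2, capri3):
    for s in (capri2, capri3):
        verdict, diag = check_efficiency(s)
        assert verdict
        assert diag["resistance_coop_to_defect"] > diag["resistance_defect_to_coop"]


def test_alld_not_efficient():
    verdict, diag = check_efficiency(build_alld(2))
    assert not verdict


def test_allc_efficient():
    assert check_efficiency(build_allc(2))[0]


def test_grim_style_not_efficient():
    # defect forever unless everyone cooperated in the previous round:
    # a single error permanently destroys cooperation
    grim = build_memory_one([0, 1, 1, 1], 2)
    verdict, diag = check_efficiency(grim)
    assert not verdict


# -- distinguishability ------------------------------------------------------

def test_capri_distinguishes_allc(capri2, capri3):
    for s in (capri2, capri3):
        verdict, gap = check_distinguishability(s)
        assert verdict
        assert gap > 0.1


def test_allc_and_tft_do_not_distinguish():
    verdict, gap = check_distinguishability(build_allc(2))
    assert not verdict
    assert abs(gap) < 1e-9
    verdict, gap = check_distinguishability(build_tft())
    assert not verdict
    assert abs(gap) < 1e-6


# -- classification and full certification -----------------------------------

def test_certify_capri2_successful(capri2):
    report = certify(capri2)
    assert report.defensible and report.efficient and report.distinguishing
    assert report.friendly_rival and report.successful
    assert report.labels == {"efficient", "defensible"}
    d = report.to_dict()
    assert d["successful"] and d["defensibility_witness"] is None


def test_classify_memory_one_family(memory_one_n2):
    labels = classify(memory_one_n2)
    by_name = {s.name: s for s in memory_one_n2}
    alld = next(s for s in memory_one_n2 if np.all(s.table == 1))
    wsls = build_wsls()
    wsls_entry = next(
        s for s in memory_one_n2 if np.array_equal(s.table, wsls.table)
    )
    assert "defensible" in labels[alld.name]
    assert "efficient" in labels[wsls_entry.name]
    assert "defensible" not in labels[wsls_entry.name]


def test_capri3_exploits_short_memory_aon(capri3):
    # all-or-none strategies synchronizing over fewer than m-1 rounds are
    # repeatedly exploited
    params = GameParams(n=3, rho=2.0)
    for k in (1, 2, 3):
        aon = build_aon(k, 3, m=5)
        res = analyze(StrategyProfile([capri3, aon, aon]), params, eps=1e-4)
        assert res.payoffs[0] > res.payoffs[1] + 0.05
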