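"""Strategy zoo: the five-rule construction and the comparison strategies."""

import numpy as np
import pytest

from capri.game import COOPERATE, DEFECT, HistoryProfile
from capri.strategies import (
    _capri_label_scalar,
    build_aon,
    build_allc,
    build_alld,
    build_capri,
    build_memory_one,
    build_named,
    build_tft,
    build_wsls,
    capri_label_codes,
    capri_rule,
    enumerate_memory_one,
    is_symmetric,
    memory_one_index,
    random_strategy,
)

H = HistoryProfile.from_string


@pytest.mark.parametrize(
    "hist, rule, action",
    [
        ("ccccc;cccdc;ccccc", "C", COOPERATE),
        ("cccdc;ccccd;ccccc", "A", COOPERATE),
        ("ccccd;cccdd;ccccc", "P", DEFECT),
        ("ddddd;ddddc;ddddc", "R", COOPERATE),
        ("ccddd;ccddd;ccccc", "I", DEFECT),
        ("cdddc;ccddc;ccccc", "I", DEFECT),
    ],
)
def test_capri_rule_worked_examples(hist, rule, action):
    assert capri_rule(H(hist)) == (rule, action)


def test_capri_rule_requires_matching_memory():
    with pytest.raises(ValueError):
        capri_rule(H("cc;cc"))  # n=2 needs m=3


def test_recover_rule_permutations():
    # the lone defector in the newest round may be anyone, focal included
    assert capri_rule(H("ddddc;ddddd;ddddc")) == ("R", COOPERATE)
    assert capri_rule(H("ddddc;ddddc;ddddd")) == ("R", COOPERATE)
    # two defectors in the newest round do not trigger recovery
    assert capri_rule(H("ddddd;ddddd;ddddc"))[0] == "I"
    # strict form: an older non-all-d column blocks recovery
    assert capri_rule(H("dcddd;ddddc;ddddc"))[0] == "I"


@pytest.mark.parametrize("n", [2, 3])
def test_capri_table_sizes_and_rule_agreement(n):
    s = build_capri(n)
    m = 2 * n - 1
    assert len(s.table) == 1 << (n * m)
    # vectorized table agrees with the scalar rule on a deterministic sample
    rng = np.random.default_rng(0)
    codes = rng.integers(0, 1 << (n * m), size=500)
    for code in codes:
        label = _capri_label_scalar(int(code), n, m)
        expected = COOPERATE if label in ("C", "A", "R") else DEFECT
        assert s.table[code] == expected


def test_capri_rules_mutually_exclusive_and_exhaustive():
    for n in (2, 3):
        m = 2 * n - 1
        labels = capri_label_codes(np.arange(1 << (n * m), dtype=np.uint64), n, m)
        # the vectorized classifier assigns exactly one of the five labels
        assert set(np.unique(labels)) == {"C", "A", "P", "R", "I"}


def test_capri_endpoints():
    for n in (2, 3):
        s = build_capri(n)
        assert s.action(0) == COOPERATE  # all-cooperate history
        assert s.action(len(s.table) - 1) == DEFECT  # all-defect history


def test_capri_on_demand_matches_table():
    for n in (2, 3):
        lazy = build_capri(n, materialize=False)
        table = build_capri(n)
        rng = np.random.default_rng(1)
        for code in rng.integers(0, len(table.table), size=300):
            assert lazy.action(int(code)) == table.action(int(code))


def test_capri4_is_rule_evaluated():
    s = build_capri(4)
    assert s.table is None
    assert s.action(0) == COOPERATE
    assert s.action((1 << 28) - 1) == DEFECT
    # recovery state for n=4: all-defect history except three newest cooperators
    rows = ["ddddddd", "ddddddc", "ddddddc", "ddddddc"]
    code = 0
    m = 7
    for i, row in enumerate(rows):
        field = sum(1 << (m - 1 - k) for k, ch in enumerate(row) if ch == "d")
        code |= field << (i * m)
    assert s.action(code) == COOPERATE


def test_loose_recovery_variant_differs():
    strict = build_capri(3)
    loose = build_capri(3, strict_recovery=False)
    assert not np.array_equal(strict.table, loose.table)
    h = H("dcddd;ddddc;ddddc")  # recovery blocked only under the strict form
    assert strict.action(h) == DEFECT
    assert loose.action(h) == COOPERATE


def test_aon1_equals_wsls():
    assert np.array_equal(build_aon(1, 2, 1).table, build_wsls().table)


def test_aon_reads_only_newest_k_columns():
    s = build_aon(2, 3, m=5)
    # unanimity in the two newest rounds prescribes c regardless of older rounds
    assert s.action(H("cdcdd;cccdd;dccdd")) == COOPERATE
    assert s.action(H("ccccc;ccccc;ccccd")) == DEFECT


def test_alld_and_allc_tables():
    assert np.all(build_alld(3, 5).table == DEFECT)
    assert np.all(build_allc(3, 5).table == COOPERATE)


def test_tft_copies_coplayer():
    s = build_tft(2, 1)
    for own in (0, 1):
        for co in (0, 1):
            code = own | (co << 1)
            assert s.action(code) == co


def test_build_named_dispatch():
    assert build_named("AON-2", 3).name == "AON-2"
    assert build_named("capri", 2).name == "CAPRI-2"
    assert len(build_named("AllD", 3, 2).table) == 1 << 6
    with pytest.raises(ValueError):
        build_named("zealot", 2)


@pytest.mark.parametrize("n, count", [(2, 16), (3, 64)])
def test_enumerate_memory_one_counts(n, count, memory_one_n2):
    fam = memory_one_n2 if n == 2 else enumerate_memory_one(n)
    assert len(fam) == count
    tables = {s.table.tobytes() for s in fam}
    assert len(tables) == count  # all distinct
    assert build_allc(n).table.tobytes() in tables
    assert build_alld(n).table.tobytes() in tables
    if n == 2:
        assert build_tft().table.tobytes() in tables
        assert build_wsls().table.tobytes() in tables


def test_memory_one_index_round_trip():
    bits = (0, 1, 1, 0, 1, 0)
    s = build_memory_one(bits, 3)
    assert memory_one_index(s) == bits


def test_is_symmetric(capri3):
    assert is_symmetric(capri3)
    assert is_symmetric(build_alld(3, 2))
    # flip a single entry whose co-player swap image is a different history
    table = build_alld(3, 2).table.copy()
    code = HistoryProfile.from_rows([[0, 0], [0, 1], [0, 0]]).code
    table[code] = COOPERATE
    from capri.strategies import DeterministicStrategy

    assert not is_symmetric(DeterministicStrategy(3, 2, table=table))


def test_random_strategy_reproducible_and_fair():
    a = random_strategy(2, 3, 123)
    b = random_strategy(2, 3, 123)
    assert np.array_equal(a.table, b.table)
    c = random_strategy(2, 3, 124)
    assert not np.array_equal(a.table, c.table)
    big = random_strategy(3, 5, 5)
    assert abs(big.table.mean() - 0.5) < 0.02  # fair coin over 2^15 entries


def test_lift_reads_newest_columns(capri2):
    lifted = capri2.lift(4)
    assert len(lifted.table) == 1 << 8
    rng = np.random.default_rng(3)
    for code in rng.integers(0, 1 << 8, size=100):
        sub = 0
        for i in range(2):
            sub |= (((int(code) >> (i * 4)) & 0b111)) << (i * 3)
        assert lifted.action(int(code)) == capri2.action(sub)
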