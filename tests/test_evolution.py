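"""Moran/Fermi fixation probabilities and low-mutation abundance."""

import itertools

import numpy as np
import pytest

from capri.evolution import (
    PayoffTable,
    abundance,
    fixation_probability,
    fixation_probability_closed_form,
    group_payoffs,
    sample_mutant_fixation,
    sweep,
)
from capri.strategies import (
    build_allc,
    build_alld,
    build_capri,
    build_wsls,
    enumerate_memory_one,
    random_strategy,
)


class _FixedTable:
    """Payoff stub with prescribed entries, for algebraic identities."""

    def __init__(self, n, values):
        self.n = n
        self.values = values
        self.strategies = [None, None]

    def s(self, *idx):
        return self.values[idx]


def _pair_table(s_xx, s_xy, s_yx, s_yy):
    return _FixedTable(
        2, {(0, 0): s_xx, (0, 1): s_xy, (1, 0): s_yx, (1, 1): s_yy}
    )


# -- group payoffs ------------------------------------------------------------

def test_group_payoffs_single_mutant_pairwise():
    t = _pair_table(5.0, 1.0, 2.0, 3.0)
    s_x, s_y = group_payoffs(1, 10, 0, 1, t)
    assert s_x == pytest.approx(1.0)  # a lone mutant only meets residents


def test_group_payoffs_neutral_pairwise():
    t = _pair_table(2.0, 2.0, 2.0, 2.0)
    for j in range(1, 10):
        s_x, s_y = group_payoffs(j, 10, 0, 1, t)
        assert s_x == pytest.approx(s_y)


def test_group_payoffs_triple_matches_enumeration():
    # brute force: average x's payoff over every unordered co-player pair
    rng = np.random.default_rng(4)
    vals = {}
    for idx in itertools.product((0, 1), repeat=3):
        key = (idx[0],) + tuple(sorted(idx[1:]))
        vals.setdefault(key, float(rng.uniform(0, 3)))
    t = _FixedTable(3, vals)
    t.s = lambda x, *co: vals[(x,) + tuple(sorted(co))]
    N, j = 7, 3
    pop = [0] * j + [1] * (N - j)

    def brute(player_strategy):
        others = list(pop)
        others.remove(player_strategy)
        payoffs = [
            vals[(player_strategy,) + tuple(sorted((others[i], others[k])))]
            for i, k in itertools.combinations(range(N - 1), 2)
        ]
        return np.mean(payoffs)

    s_x, s_y = group_payoffs(j, N, 0, 1, t)
    assert s_x == pytest.approx(brute(0))
    assert s_y == pytest.approx(brute(1))


def test_group_payoffs_rejects_bad_mutant_count():
    t = _pair_table(1, 1, 1, 1)
    with pytest.raises(ValueError):
        group_payoffs(0, 10, 0, 1, t)
    with pytest.raises(ValueError):
        group_payoffs(10, 10, 0, 1, t)


# -- fixation probability -----------------------------------------------------

def test_neutral_fixation_is_one_over_N():
    t = _pair_table(1.3, 1.3, 1.3, 1.3)
    for N in (2, 5, 30):
        assert fixation_probability(0, 1, t, N, sigma=1.0) == pytest.approx(1 / N)


def test_zero_selection_is_one_over_N():
    t = _pair_table(5.0, -1.0, 2.0, 0.0)
    assert fixation_probability(0, 1, t, 17, sigma=0.0) == pytest.approx(1 / 17)


def test_closed_form_matches_product_form():
    rng = np.random.default_rng(8)
    worst = 0.0
    for _ in range(1000):
        s_xx, s_xy, s_yx, s_yy = rng.uniform(-2, 3, size=4)
        N = int(rng.integers(2, 50))
        sigma = float(rng.uniform(0, 4))
        t = _pair_table(s_xx, s_xy, s_yx, s_yy)
        p_prod = fixation_probability(0, 1, t, N, sigma)
        p_closed = fixation_probability_closed_form(s_xx, s_xy, s_yx, s_yy, N, sigma)
        worst = max(worst, abs(p_prod - p_closed))
    assert worst <= 1e-12


def test_fixation_reversed_roles_neutral():
    t = _pair_table(0.7, 0.7, 0.7, 0.7)
    assert fixation_probability(0, 1, t, 12, 2.0) == pytest.approx(1 / 12)
    assert fixation_probability(1, 0, t, 12, 2.0) == pytest.approx(1 / 12)


def test_capri2_robust_across_parameter_lattice(capri2):
    # no random mutant fixates better than neutral, for any tested
    # population size, selection strength, or benefit; the bound is exact in
    # the vanishing-error limit, so at eps = 1e-4 an O(sigma * eps) payoff
    # perturbation is allowed for
    eps = 1e-4
    rng = np.random.default_rng(100)
    for N in (2, 10, 50):
        for sigma in (0.1, 1.0, 10.0):
            for b in (1.5, 2.0, 3.0):
                phis = sample_mutant_fixation(
                    capri2, 25, seed=rng, N=N, sigma=sigma, b=b, eps=eps
                )
                assert phis.max() <= 1 / N + 10 * sigma * eps


# -- abundance ----------------------------------------------------------------

def test_abundance_symmetric_pair():
    # two behaviorally identical strategies: payoffs fully symmetric
    res = abundance(
        [build_allc(2), build_allc(2).rename("AllC2")], N=10, sigma=1.0, b=2.0
    )
    assert res.abundance == pytest.approx([0.5, 0.5])


def test_alld_beats_allc_in_abundance():
    res = abundance([build_allc(2), build_alld(2)], N=30, sigma=1.0, b=3.0)
    series = res.as_series()
    assert series["AllD"] > 0.99


def test_abundance_invariant_under_relabeling(memory_one_n2):
    subset = memory_one_n2[:6]
    res = abundance(subset, N=10, sigma=1.0, b=2.0)
    perm = [3, 1, 5, 0, 2, 4]
    res_p = abundance([subset[i] for i in perm], N=10, sigma=1.0, b=2.0)
    assert res.abundance[perm] == pytest.approx(res_p.abundance, abs=1e-12)


def test_capri2_most_abundant(capri2, memory_one_n2):
    res = abundance(memory_one_n2 + [capri2], N=30, sigma=1.0, b=3.0, eps=1e-4)
    series = res.as_series()
    assert series.idxmax() == "CAPRI-2"


def test_sample_mutants_reproducible(capri2):
    a = sample_mutant_fixation(capri2, 5, seed=3, N=10, sigma=1.0, b=2.0)
    b = sample_mutant_fixation(capri2, 5, seed=3, N=10, sigma=1.0, b=2.0)
    assert np.array_equal(a, b)


def test_random_residents_can_be_invaded():
    rng = np.random.default_rng(42)
    exceeded = False
    for _ in range(20):
        resident = random_strategy(2, 3, rng)
        phis = sample_mutant_fixation(
            resident, 20, seed=rng, N=10, sigma=1.0, b=2.0, eps=1e-4
        )
        if phis.max() > 1 / 10:
            exceeded = True
            break
    assert exceeded


def test_sweep_cells_normalized(memory_one_n2):
    df = sweep(memory_one_n2[:5], b_values=[2.0, 3.0], N_values=[5, 10], sigma=1.0)
    sums = df.groupby(["b", "N"])["abundance"].sum()
    assert np.allclose(sums.values, 1.0)
    assert len(df) == 5 * 2 * 2
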