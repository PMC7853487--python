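"""Exact joint-history chains: transition structure, stationary solvers,
long-term payoffs, and the vanishing-error signatures."""

import numpy as np
import pytest

from capri.dynamics import (
    GameParams,
    StrategyProfile,
    analyze,
    stationary,
    stationary_iad,
    stationary_power,
    transition_matrix,
)
from capri.strategies import (
    MemoryOneStochastic,
    build_allc,
    build_alld,
    build_capri,
    build_memory_one,
    random_strategy,
)


def test_rows_sum_to_one(capri2):
    M = transition_matrix(StrategyProfile.homogeneous(capri2), 1e-3)
    M = M if isinstance(M, np.ndarray) else M.toarray()
    assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)


def test_row_support_and_flip_probabilities(capri2):
    eps = 0.01
    M = transition_matrix(StrategyProfile.homogeneous(capri2), eps)
    M = M if isinstance(M, np.ndarray) else M.toarray()
    for row in M:
        nz = np.sort(row[row > 0])
        assert len(nz) == 4
        expected = np.sort(
            [(1 - eps) ** 2, eps * (1 - eps), eps * (1 - eps), eps**2]
        )
        assert np.allclose(nz, expected)


def test_eps_zero_alld_absorbing():
    prof = StrategyProfile.homogeneous(build_alld(2, 1))
    M = transition_matrix(prof, 0.0)
    M = M if isinstance(M, np.ndarray) else M.toarray()
    alld_state = 0b11
    assert M[alld_state, alld_state] == 1.0


def test_stationary_uniform_on_doubly_stochastic():
    M = np.array([[0.3, 0.7], [0.7, 0.3]])
    assert stationary(M) == pytest.approx([0.5, 0.5])
    assert stationary_power(M) == pytest.approx([0.5, 0.5])


def test_stationary_requires_distribution():
    with pytest.raises(ValueError):
        analyze(
            StrategyProfile.homogeneous(build_alld(2, 1)),
            GameParams(n=2, rho=1.5),
            eps=0.0,
        )


def test_direct_power_and_iad_agree():
    # moderately mixed chain where all three solvers are applicable
    prof = StrategyProfile.homogeneous(build_capri(2))
    M = transition_matrix(prof, 0.05, sparse=False)
    v1 = stationary(M)
    v2 = stationary_power(M, tol=1e-14)
    import scipy.sparse as sp

    v3 = stationary_iad(sp.csr_matrix(M), prof.flow_partition())
    assert np.abs(v1 - v2).max() < 1e-10
    assert np.abs(v1 - v3).max() < 1e-10


def test_allc_full_coop_probability():
    res = analyze(
        StrategyProfile.homogeneous(build_allc(2)), GameParams(n=2, rho=1.5), eps=0.1
    )
    assert res.full_coop_prob == pytest.approx(0.81, abs=1e-12)


def test_alld_payoffs_near_one():
    res = analyze(
        StrategyProfile.homogeneous(build_alld(3)), GameParams(n=3, rho=2.0), eps=1e-3
    )
    assert res.payoffs == pytest.approx([1.0, 1.0, 1.0], abs=0.01)


def test_capri2_payoffs_extrapolate_to_rho(capri2):
    params = GameParams(n=2, rho=1.5)
    prof = StrategyProfile.homogeneous(capri2)
    payoffs = [analyze(prof, params, eps=e).payoffs[0] for e in (1e-3, 1e-4, 1e-5)]
    gaps = [1.5 - p for p in payoffs]
    assert gaps[0] > gaps[1] > gaps[2] > 0
    # linear extrapolation of the last two points lands on rho
    extrap = payoffs[2] + (payoffs[2] - payoffs[1]) / 9
    assert extrap == pytest.approx(1.5, abs=1e-5)


def test_homogeneous_symmetric_profile_equal_payoffs(capri3):
    res = analyze(
        StrategyProfile.homogeneous(capri3), GameParams(n=3, rho=2.0), eps=1e-3
    )
    assert np.ptp(res.payoffs) < 1e-9


def test_payoff_feasibility_random_profiles():
    rng = np.random.default_rng(2)
    params = GameParams(n=2, rho=1.5)
    for k in range(10):
        members = [random_strategy(2, 2, rng) for _ in range(2)]
        res = analyze(StrategyProfile(members), params, eps=1e-2)
        assert res.payoffs.min() >= 0.0 - 1e-9  # min per-round pg payoff
        assert res.payoffs.max() <= 1 + params.rho / 2 + 1e-9


def test_efficiency_signature_linear_in_eps():
    for n, builder in ((2, build_capri(2)), (3, build_capri(3))):
        prof = StrategyProfile.homogeneous(builder)
        params = GameParams(n=n, rho=(1 + n) / 2)
        resid = [
            1 - analyze(prof, params, eps=e).full_coop_prob for e in (1e-3, 1e-4, 1e-5)
        ]
        ratios = [resid[0] / resid[1], resid[1] / resid[2]]
        for r in ratios:
            assert 5 < r < 20  # approximately 10x per decade


def test_capri2_vs_1110_payoff_tie(capri2):
    # the memory-one strategy cooperating except after mutual defection is
    # not exploited by the friendly rival: the payoff gap vanishes with eps
    s1110 = build_memory_one([0, 0, 1, 0], 2)
    params = GameParams(n=2, rho=1.5)
    gaps = []
    for eps in (1e-3, 1e-4):
        res = analyze(StrategyProfile([capri2, s1110]), params, eps=eps)
        gaps.append(abs(res.payoffs[0] - res.payoffs[1]))
    assert gaps[1] < gaps[0]
    assert gaps[1] < 5e-3


def test_nash_random_mutants_never_beat_rho(capri2):
    params = GameParams(n=2, rho=1.5)
    rng = np.random.default_rng(9)
    eps = 1e-4
    worst = -np.inf
    for _ in range(1000):
        mutant = random_strategy(2, 3, rng)
        res = analyze(StrategyProfile([mutant, capri2]), params, eps=eps)
        worst = max(worst, res.payoffs[0])
    assert worst <= params.rho + 10 * eps


def test_stochastic_member_chain():
    co = MemoryOneStochastic.from_quadruple(0.5, 0.5, 0.5, 0.5)
    res = analyze(
        StrategyProfile([build_allc(2), co]), GameParams(n=2, rho=1.5), eps=1e-3
    )
    # the random co-player cooperates half the time
    assert res.coop_rates[1] == pytest.approx(0.5, abs=1e-9)
    assert res.coop_rates[0] == pytest.approx(1 - 1e-3, abs=1e-9)
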