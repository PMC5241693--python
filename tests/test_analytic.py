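import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microaltruism import (
    Carrier,
    ModelParams,
    critical_bc_ratio,
    genetic_next_generation,
    iterate,
    mean_fitness,
    next_generation_proportion,
    post_interaction_proportion,
    spread_condition,
    spread_margin,
    transmission_distribution,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


def mk(b, c, ta=0.0, tb=0.0, vt=1.0, bg=0.0, cg=0.0):
    return ModelParams(b=b, c=c, T_alpha=ta, T_beta=tb, VT=vt, b_g=bg, c_g=cg)


# ---------------------------------------------------------------- one step


@pytest.mark.parametrize(
    "p, params, expected",
    [
        (0.3, mk(1, 0.1, ta=0.2, tb=0.2), 0.3),     # equal transmission: unchanged
        (0.0, mk(1, 0.1, ta=0.9, tb=0.1), 0.0),     # no discordant pairs
        (1.0, mk(1, 0.1, ta=0.9, tb=0.1), 1.0),
        (0.5, mk(3, 0.05, ta=0.4, tb=0.1), 0.575),  # 0.5 + 0.25 * 0.3
    ],
)
def test_post_interaction_proportion(p, params, expected):
    assert post_interaction_proportion(p, params) == pytest.approx(expected)


def test_post_interaction_matches_pair_enumeration():
    """p_tilde follows from pairing frequencies and the per-pair transmission
    distribution: brute-force enumeration over pair types."""
    params = mk(1, 0.1, ta=0.37, tb=0.12)
    p = 0.43
    dist = transmission_distribution(Carrier.ALPHA, Carrier.BETA, params)
    alpha_per_discordant = sum(
        pr * (int(x == Carrier.ALPHA) + int(y == Carrier.ALPHA))
        for (x, y), pr in dist.items()
    )
    # pair frequencies p^2, 2p(1-p), (1-p)^2; per-capita alpha proportion
    expected = (p**2 * 2 + 2 * p * (1 - p) * alpha_per_discordant) / 2
    assert post_interaction_proportion(p, params) == pytest.approx(expected)


@pytest.mark.parametrize(
    "p, params, expected",
    [
        (0.0, mk(3, 0.05), 1.0),
        (1.0, mk(3, 0.05), 3.95),
        (0.5, mk(2, 0.99, bg=0.2, cg=0.1), 1.1 + 0.5 * 1.01),
    ],
)
def test_mean_fitness(p, params, expected):
    assert mean_fitness(p, params) == pytest.approx(expected)


def test_absorbing_states():
    params = mk(2, 0.1, ta=0.3, tb=0.1, vt=0.8)
    assert next_generation_proportion(0.0, params) == 0.0
    assert next_generation_proportion(1.0, params) == 1.0


def test_no_horizontal_transmission_recursion_declines():
    """Without horizontal transmission and VT=1 the recursion reduces to
    p' = p (1 + p b - c) / w_bar < p: altruism cannot evolve."""
    params = mk(3, 0.05)
    p = 0.5
    p_next = next_generation_proportion(p, params)
    w = 1 + p * (params.b - params.c)
    assert p_next == pytest.approx(p * (1 + p * params.b - params.c) / w)
    assert p_next < p


def test_spread_with_horizontal_transmission():
    # b*T > c*(1-T): 10*0.1 = 1 > 0.045
    params = mk(10, 0.05, ta=0.1, tb=0.1)
    assert next_generation_proportion(0.2, params) > 0.2


@given(
    p=probs,
    c=st.floats(0.0, 0.9),
    extra=st.floats(0.0, 5.0),
    ta=probs,
    tb=probs,
    vt=probs,
)
@settings(max_examples=200, deadline=None)
def test_recursion_maps_unit_interval_to_itself(p, c, extra, ta, tb, vt):
    params = mk(c + extra, c, ta=ta, tb=tb, vt=vt)
    p_next = next_generation_proportion(p, params)
    assert 0.0 <= p_next <= 1.0


# ------------------------------------------------------- spread condition


@given(
    p=st.floats(0.01, 0.99),
    c=st.floats(0.01, 0.9),
    extra=st.floats(0.0, 5.0),
    ta=probs,
    tb=probs,
    vt=probs,
)
@settings(max_examples=200, deadline=None)
def test_spread_condition_matches_recursion_sign(p, c, extra, ta, tb, vt):
    """The closed-form margin has the sign of p' - p (they differ by the
    positive factor p(1-p))."""
    params = mk(c + extra, c, ta=ta, tb=tb, vt=vt)
    delta = next_generation_proportion(p, params) - p
    margin = spread_margin(params, p)
    assert delta == pytest.approx(p * (1 - p) * margin, abs=1e-12)


def test_condition_independent_of_p_when_vt_is_one():
    """With perfect vertical transmission the invasion condition does not
    depend on p, so spreading implies spread to fixation."""
    params = mk(2, 0.05, ta=0.07, tb=0.21)
    results = {spread_condition(params, p) for p in np.linspace(0.001, 0.999, 41)}
    assert len(results) == 1


def test_no_spread_when_alpha_never_transmits():
    for tb in (0.0, 0.3):
        for vt in (0.25, 1.0):
            params = mk(50, 0.05, ta=0.0, tb=tb, vt=vt)
            assert not spread_condition(params, 0.5)


@pytest.mark.parametrize("T", [0.001, 0.01, 0.1, 0.5])
@pytest.mark.parametrize("vt", [0.25, 0.5, 1.0])
@pytest.mark.parametrize("p", [0.01, 0.5, 0.99])
def test_equal_transmission_threshold_for_any_vt(T, vt, p):
    """With T_alpha = T_beta = T the spread condition is b/c > (1-T)/T for
    every VT > 0 and every interior p."""
    c = 0.05
    bc_star = (1 - T) / T
    assert spread_condition(mk(c * bc_star * (1 + 1e-6), c, ta=T, tb=T, vt=vt), p)
    assert not spread_condition(mk(c * bc_star * (1 - 1e-6), c, ta=T, tb=T, vt=vt), p)


# ------------------------------------------------------ critical b/c ratio


@pytest.mark.parametrize("T, expected", [(0.1, 9.0), (0.01, 99.0), (0.001, 999.0)])
def test_critical_ratio_equal_transmission(T, expected):
    assert critical_bc_ratio(T, T, c=0.05) == pytest.approx(expected, rel=1e-12)


def test_critical_ratio_infinite_without_alpha_transmission():
    assert math.isinf(critical_bc_ratio(0.0, 0.2, c=0.05))
    assert math.isinf(critical_bc_ratio(0.0, 0.0, c=0.05, VT=0.5))


def test_critical_ratio_agrees_with_bisection_on_spread_condition():
    """Closed-form threshold vs. direct bisection of the spread condition in
    the rare-invader limit."""
    cases = [
        (0.1, 0.1, 0.05, 1.0),
        (0.2, 0.05, 0.05, 1.0),
        (0.05, 0.2, 0.2, 1.0),
        (0.1, 0.1, 0.01, 0.5),
        (0.05, 0.2, 0.05, 0.75),
    ]
    for ta, tb, c, vt in cases:
        expected = critical_bc_ratio(ta, tb, c, vt)
        lo, hi = 1e-9, 1e7
        holds_hi = spread_condition(mk(hi * c, c, ta=ta, tb=tb, vt=vt), 1e-12)
        if not holds_hi:
            assert math.isinf(expected)
            continue
        if spread_condition(mk(lo * c, c, ta=ta, tb=tb, vt=vt), 1e-12):
            # spreads for every positive benefit: threshold reported as 0
            assert expected == 0.0
            continue
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if spread_condition(mk(mid * c, c, ta=ta, tb=tb, vt=vt), 1e-12):
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(expected, rel=1e-6)


def test_critical_ratio_monotone_in_alpha_transmission():
    values = [critical_bc_ratio(ta, 0.1, c=0.05, VT=0.75) for ta in (0.02, 0.05, 0.1, 0.3)]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_baseline_altruism_enters_threshold():
    """With VT=1 and a baseline, invasion needs
    b T_a > c (1 - T_b) + (1 + b_g - c_g)(T_b - T_a)."""
    ta, tb, c, bg, cg = 0.05, 0.2, 0.05, 0.4, 0.1
    B = 1 + bg - cg
    expected = (c * (1 - tb) + B * (tb - ta)) / (ta * c)
    assert critical_bc_ratio(ta, tb, c, 1.0, bg, cg) == pytest.approx(expected)


# ------------------------------------------------------- genetic control


def test_genetic_altruism_always_declines():
    for p in (0.01, 0.3, 0.7, 0.99):
        assert genetic_next_generation(p, 2.0, 0.1) < p
    assert genetic_next_generation(0.0, 2.0, 0.1) == 0.0
    assert genetic_next_generation(1.0, 2.0, 0.1) == 1.0


def test_genetic_neutral_limit():
    p = 0.4
    assert genetic_next_generation(p, 1e-9, 1e-10) == pytest.approx(p, abs=1e-9)


# ---------------------------------------------------------------- iterate


def test_iterate_reaches_fixation_from_rarity():
    """Above the invasion threshold with VT=1 the proportion climbs to 1
    even from a 5% start."""
    params = mk(1.0, 0.05, ta=0.1, tb=0.1)  # b/c = 20 > 9
    traj = iterate(0.05, params, 10_000)
    assert traj.final_p > 1 - 1e-6


def test_iterate_monotone_decline_without_transmission():
    traj = iterate(0.05, mk(3, 0.05), 500)
    assert np.all(np.diff(traj.p) <= 0)
    assert traj.final_p < 0.05


def test_imperfect_vertical_transmission_slows_but_does_not_stop_spread():
    """Same fixed point for VT=0.5 and VT=1 above threshold, but the slower
    vertical route needs strictly more generations to pass p=0.5."""
    full = iterate(0.05, mk(1.0, 0.05, ta=0.1, tb=0.1, vt=1.0), 20_000)
    half = iterate(0.05, mk(1.0, 0.05, ta=0.1, tb=0.1, vt=0.5), 20_000)
    assert full.final_p == pytest.approx(1.0, abs=1e-9)
    assert half.final_p == pytest.approx(1.0, abs=1e-9)
    cross_full = int(np.argmax(full.p > 0.5))
    cross_half = int(np.argmax(half.p > 0.5))
    assert cross_half > cross_full


def test_iterate_genetic_mode():
    traj = iterate(0.3, None, 2000, genetic=(2.0, 0.1))
    assert traj.final_p < 1e-3
    assert np.all(np.diff(traj.p) <= 0)


# --------------------------------------------------------- helping bias


@given(p=st.floats(0.0, 1.0), ta=probs, tb=probs)
@settings(max_examples=100, deadline=None)
def test_helping_bias_identity(p, ta, tb):
    """The probability that an alpha-host's partner carries alpha after the
    interaction is p + (1-p) T_alpha >= p: help is preferentially directed
    towards future altruists."""
    params = mk(1, 0.1, ta=ta, tb=tb)
    dist = transmission_distribution(Carrier.ALPHA, Carrier.BETA, params)
    beta_partner_becomes_alpha = sum(
        pr for (_, post_j), pr in dist.items() if post_j == Carrier.ALPHA
    )
    prob = p * 1.0 + (1 - p) * beta_partner_becomes_alpha
    assert prob == pytest.approx(p + (1 - p) * ta)
    assert prob >= p - 1e-12
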