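"""Markov payoff engine: kernel structure, closed forms, Monte-Carlo agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import altpd
from altpd import (
    GameParameters,
    build_transition_matrix,
    game_payoff,
    initial_distribution,
    pair_payoffs,
    simulate_match,
    simulate_payoffs,
)
from altpd.game import MARK_ACTUAL, simulate_mark_chain

ALL = altpd.enumerate_strategies()


@settings(max_examples=40, derandomize=True)
@given(
    i=st.integers(0, 25),
    j=st.integers(0, 25),
    eps=st.floats(0.0, 0.499, allow_nan=False),
)
def test_transition_rows_are_stochastic(i, j, eps):
    T = build_transition_matrix(ALL[i], ALL[j], eps)
    assert np.all(T >= 0)
    np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)


def test_epsilon_validation(named):
    with pytest.raises(ValueError):
        build_transition_matrix(named["TFT"], named["TFT"], 0.5)
    with pytest.raises(ValueError):
        initial_distribution(named["TFT"], named["TFT"], -0.1)
    with pytest.raises(ValueError):
        GameParameters(3, 1, 0.6, 100)
    with pytest.raises(ValueError):
        GameParameters(1, 2, 0.05, 100)  # cost above benefit


def test_noiseless_alld_pair_is_absorbing(named):
    T = build_transition_matrix(named["ALLD"], named["ALLD"], 0.0)
    dd = 4 * 2 + 2  # joint state (d, d)
    assert T[dd, dd] == 1.0


def test_initial_distribution_examples(named):
    v = initial_distribution(named["ALLC"], named["ALLC"], 0.0)
    assert v[0] == 1.0  # unit mass on (c, c)
    eps = 0.1
    v = initial_distribution(named["ALLD"], named["ALLD"], eps)
    dd, dds, dsd, dsds = 4 * 2 + 2, 4 * 2 + 3, 4 * 3 + 2, 4 * 3 + 3
    np.testing.assert_allclose(
        [v[dd], v[dds], v[dsd], v[dsds]],
        [(1 - eps) ** 2, eps * (1 - eps), eps * (1 - eps), eps**2],
    )
    for a in ("TFT", "sForgiver", "Grim"):
        v = initial_distribution(named[a], named["WSLS"], 0.3)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("eps", [0.01, 0.05, 0.2, 0.45])
@pytest.mark.parametrize(
    "row, col",
    [("ALLC", "ALLC"), ("ALLC", "ALLD"), ("ALLD", "ALLC"), ("ALLD", "ALLD")],
)
def test_unconditional_pair_closed_forms(named, row, col, eps):
    """Per move, an unconditional strategy cooperates with probability eps or
    1-eps; the expected payoff has an exact closed form."""
    b, c, n = 3.0, 1.0, 100
    coop = {"ALLC": 1 - eps, "ALLD": eps}
    expected = n * (b * coop[col] - c * coop[row])
    got = game_payoff(named[row], named[col], GameParameters(b, c, eps, n))
    assert got == pytest.approx(expected, abs=1e-9)


def test_error_free_mutual_cooperation(named):
    params = GameParameters(3, 1, 0.0, 100)
    assert game_payoff(named["ALLC"], named["ALLC"], params) == pytest.approx(200.0)


def test_mutual_cooperation_payoff_decreases_with_noise(named):
    values = [
        game_payoff(named["ALLC"], named["ALLC"], GameParameters(3, 1, e, 100))
        for e in np.linspace(0.0, 0.49, 12)
    ]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_first_mover_averaging_is_mean_of_single_orders(named, reference_params):
    for a, b in [("Forgiver", "ALLD"), ("TFT", "Grim"), ("WSLS", "sALLC")]:
        p_first, _ = pair_payoffs(named[a], named[b], reference_params)
        _, p_second = pair_payoffs(named[b], named[a], reference_params)
        avg = game_payoff(named[a], named[b], reference_params)
        assert avg == pytest.approx(0.5 * (p_first + p_second), abs=1e-12)


def test_transition_matrix_matches_empirical_frequencies(named):
    """Kernel rows agree with move-level simulation within 4 binomial SEs."""
    eps = 0.05
    T = build_transition_matrix(named["Forgiver"], named["ALLD"], eps)
    rng = np.random.default_rng(7)
    chains = simulate_mark_chain(named["Forgiver"], named["ALLD"], eps,
                                 n_rounds=100, n_chains=10_000, rng=rng)
    counts = np.zeros((16, 16))
    src = chains[:, :-1].ravel()
    dst = chains[:, 1:].ravel()
    np.add.at(counts, (src, dst), 1)
    row_n = counts.sum(axis=1)
    for i in np.flatnonzero(row_n >= 1000):
        freq = counts[i] / row_n[i]
        se = np.sqrt(np.clip(T[i] * (1 - T[i]), 1e-12, None) / row_n[i])
        assert np.all(np.abs(freq - T[i]) <= 4 * se + 1e-12)


@pytest.mark.parametrize(
    "a, b",
    [("ALLD", "Forgiver"), ("TFT", "WSLS"), ("Grim", "sALLC"),
     ("Alternator", "Forgiver"), ("sForgiver", "ALLC")],
)
def test_monte_carlo_agrees_with_markov_engine(named, reference_params, a, b):
    """Mean simulated payoff within 4 standard errors of the exact value."""
    rng = np.random.default_rng(sum(map(ord, a + b)))
    pa, _ = simulate_payoffs(named[a], named[b], reference_params, 100_000, rng)
    _, pa2 = simulate_payoffs(named[b], named[a], reference_params, 100_000, rng)
    sample = 0.5 * (pa + pa2)
    exact = game_payoff(named[a], named[b], reference_params)
    se = sample.std(ddof=1) / np.sqrt(sample.size)
    assert abs(sample.mean() - exact) <= 4 * se


def test_forgiver_recovers_within_three_rounds(named):
    """After one forced error, two Forgivers restore mutual cooperation fast."""
    params = GameParameters(3, 1, 0.0, 30)
    res = simulate_match(named["Forgiver"], named["Forgiver"], params,
                         forced_errors=[(10, 0)])
    rounds = list(zip(res.moves_first, res.moves_second))
    assert rounds[9] != ("C", "C")
    assert all(r == ("C", "C") for r in rounds[12:])


@pytest.mark.parametrize("name", ["TFT", "WSLS"])
def test_tft_wsls_never_recover_from_a_single_error(named, name):
    params = GameParameters(3, 1, 0.0, 60)
    res = simulate_match(named[name], named[name], params, forced_errors=[(10, 1)])
    rounds = list(zip(res.moves_first, res.moves_second))
    assert all(r != ("C", "C") for r in rounds[10:])


def test_grim_never_returns_to_cooperation(named):
    params = GameParameters(3, 1, 0.0, 60)
    res = simulate_match(named["Grim"], named["Grim"], params, forced_errors=[(5, 0)])
    # every move after the error is a defection by both players
    assert set(res.moves_first[5:]) == {"D"}
    assert set(res.moves_second[5:]) == {"D"}


def test_forced_errors_require_zero_noise(named):
    params = GameParameters(3, 1, 0.05, 10)
    with pytest.raises(ValueError):
        simulate_match(named["TFT"], named["TFT"], params, forced_errors=[(1, 0)])


def test_simulated_match_is_reproducible_and_consistent(named, reference_params):
    r1 = simulate_match(named["WSLS"], named["Grim"], reference_params, seed=5)
    r2 = simulate_match(named["WSLS"], named["Grim"], reference_params, seed=5)
    assert r1 == r2
    # payoffs recomputable from the actual moves
    b, c = reference_params.benefit, reference_params.cost
    pf = b * r1.moves_second.count("C") - c * r1.moves_first.count("C")
    assert r1.payoff_first == pytest.approx(pf)


def test_blind_first_round_convention_differs(named, reference_params):
    """The alternative first-round convention is available behind a switch."""
    responds = game_payoff(named["sTFT"], named["TFT"], reference_params)
    blind = game_payoff(named["sTFT"], named["TFT"], reference_params,
                        second_mover_responds=False)
    assert responds != pytest.approx(blind, abs=1e-6)
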